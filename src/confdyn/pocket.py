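"""RNA-binding pocket definition, cross-system minimal pocket, and
population-weighted channel-volume estimation.

The pocket is the set of protein residues with any heavy atom within a
cutoff (default 6 A) of the bound RNA; intersecting pockets across systems
in a common residue space yields the minimal conserved pocket.  Channel
volume is estimated by probe-accessible grid counting bounded by the convex
hull of the pocket heavy atoms, and averaged over cluster representatives
weighted by their populations.  The estimator (hull + grid + probe) and its
parameters are recorded in every result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import Delaunay, cKDTree

from .core import EnsembleModel
from .errors import EmptyInputError, ParameterError, SelectionError

#: Bondi van der Waals radii (A) used by the volume estimator.
VDW_RADII = {"H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "F": 1.47, "CL": 1.75, "SE": 1.90}
VDW_DEFAULT = 1.70


class EmptyPocketError(EmptyInputError):
    """Raised when the pocket rule selects no residues."""

    empty = True


@dataclass
class PocketDefinition:
    residues: set[int]
    source: str = "distance-to-RNA"
    cutoff: float | None = None


@dataclass
class VolumeResult:
    volumes: list[float]            # per representative, A^3
    weights: list[float]            # renormalized cluster populations
    weighted_mean: float
    grid_spacing: float
    probe_radius: float
    algorithm: str = "convex-hull bounded probe-accessible grid count"


def define_pocket(ensemble: EnsembleModel, cutoff: float = 6.0,
                  rna_chain: str | None = None,
                  frame: int = 0) -> PocketDefinition:
    """Protein residues with any heavy atom within `cutoff` of any RNA
    heavy atom (in the given frame)."""
    rna_chain = rna_chain or ensemble.rna_chain
    if rna_chain is None:
        raise SelectionError("ensemble has no RNA chain")
    rna_idx = ensemble.atom_indices(chain=rna_chain, heavy_only=True)
    if rna_idx.size == 0:
        raise SelectionError(f"no atoms in RNA chain {rna_chain!r}")
    prot_idx = np.array([
        i for i in range(ensemble.n_atoms)
        if ensemble.atoms[i].chain_id != rna_chain
        and not ensemble.atoms[i].is_hydrogen
    ])
    coords = ensemble.frames[frame]
    residues: set[int] = set()
    if cutoff > 0 and prot_idx.size:
        tree = cKDTree(coords[rna_idx])
        dists, _ = tree.query(coords[prot_idx], k=1)
        for i, d in zip(prot_idx, dists):
            if d <= cutoff:
                residues.add(ensemble.atoms[i].residue_index)
    if not residues:
        raise EmptyPocketError(
            f"no protein residue within {cutoff} A of the RNA"
        )
    return PocketDefinition(residues=residues, source="distance-to-RNA",
                            cutoff=cutoff)


def minimal_pocket(pockets: dict[str, PocketDefinition],
                   correspondence: dict[str, dict[int, int]]
                   ) -> dict[str, PocketDefinition]:
    """Intersect pockets across systems in a common residue space.

    `correspondence[label]` maps each system's residue indices to common
    indices.  Unmapped pocket residues are excluded with a warning.  The
    intersection is mapped back per system; an empty intersection is
    flagged via EmptyPocketError.
    """
    common_sets = {}
    for label, pocket in pockets.items():
        mapping = correspondence[label]
        unmapped = sorted(r for r in pocket.residues if r not in mapping)
        if unmapped:
            warnings.warn(
                f"{label}: excluding unmapped pocket residues {unmapped}"
            )
        common_sets[label] = {mapping[r] for r in pocket.residues
                              if r in mapping}
    core = set.intersection(*common_sets.values()) if common_sets else set()
    if not core:
        raise EmptyPocketError("minimal pocket is empty across systems")
    out = {}
    for label, pocket in pockets.items():
        inverse = {c: r for r, c in correspondence[label].items()}
        out[label] = PocketDefinition(
            residues={inverse[c] for c in core if c in inverse},
            source="minimal-intersection", cutoff=pocket.cutoff,
        )
    return out


def _frame_volume(coords: np.ndarray, elements: list[str],
                  pocket_atom_idx: np.ndarray, grid: float,
                  probe: float) -> float:
    pocket_pts = coords[pocket_atom_idx]
    hull = Delaunay(pocket_pts)
    lo = pocket_pts.min(axis=0)
    hi = pocket_pts.max(axis=0)
    axes = [np.arange(lo[d], hi[d] + grid, grid) for d in range(3)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(), gz.ravel()], axis=1)
    inside = hull.find_simplex(pts) >= 0
    pts = pts[inside]
    if pts.shape[0] == 0:
        return 0.0
    free = np.ones(pts.shape[0], dtype=bool)
    elems = np.array([e.upper() for e in elements])
    for elem in np.unique(elems):
        idx = np.where(elems == elem)[0]
        radius = probe + VDW_RADII.get(elem, VDW_DEFAULT)
        tree = cKDTree(coords[idx])
        d, _ = tree.query(pts, k=1, distance_upper_bound=radius + 1e-12)
        free &= ~np.isfinite(d) | (d > radius)
    return float(free.sum()) * grid ** 3


def channel_volume(ensemble: EnsembleModel, pocket: PocketDefinition,
                   representatives: list[tuple[int, float]] | None = None,
                   grid: float = 0.5, probe: float = 1.4) -> VolumeResult:
    """Probe-accessible volume inside the convex hull of the pocket heavy
    atoms, weighted over cluster representatives.

    `representatives` are (frame_index, population) pairs, e.g. from
    cluster_frames; weights are renormalized over the supplied frames.
    Counted grid points lie inside the hull and farther than
    probe + vdW radius from every (protein) heavy atom.
    """
    if grid <= 0 or probe < 0:
        raise ParameterError("grid must be > 0 and probe >= 0")
    if not pocket.residues:
        raise EmptyPocketError("pocket definition is empty")
    if representatives is None:
        representatives = [(0, 1.0)]
    pocket_idx = ensemble.atom_indices(residues=pocket.residues,
                                       heavy_only=True)
    if pocket_idx.size < 4:
        raise SelectionError("pocket needs >= 4 heavy atoms for a hull")
    heavy_idx = np.array([i for i in range(ensemble.n_atoms)
                          if not ensemble.atoms[i].is_hydrogen
                          and (ensemble.rna_chain is None or
                               ensemble.atoms[i].chain_id !=
                               ensemble.rna_chain)])
    elements = [ensemble.atoms[i].element for i in heavy_idx]
    total_w = sum(w for _, w in representatives)
    if total_w <= 0:
        raise ParameterError("representative weights must sum > 0")
    weights = [w / total_w for _, w in representatives]
    pocket_local = np.searchsorted(heavy_idx,
                                   np.intersect1d(pocket_idx, heavy_idx))
    volumes = [
        _frame_volume(ensemble.frames[f][heavy_idx], elements,
                      pocket_local, grid, probe)
        for f, _ in representatives
    ]
    mean = float(np.dot(weights, volumes))
    return VolumeResult(volumes=volumes, weights=weights, weighted_mean=mean,
                        grid_spacing=grid, probe_radius=probe)
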