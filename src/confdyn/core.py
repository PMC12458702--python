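"""Structure/ensemble data model, PDB I/O, superposition metrics and
RMSD-based conformational clustering.

The central container is :class:`EnsembleModel`: a list of atoms with
per-frame coordinates, an optional domain partition and an optional bound
nucleic-acid chain.  Residues are indexed 0-based and contiguous internally;
author (PDB) numbering is kept only as display metadata, since the systems
being compared (e.g. protein paralogs) generally use different author
numbering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.transform import Rotation
from scipy.spatial.distance import squareform

from .errors import (
    DegenerateGeometryError,
    EmptyInputError,
    ParameterError,
    ParseError,
    SelectionError,
)

# Standard atomic masses (u) for the elements that occur in protein/RNA/water
# systems; anything else falls back to unit mass (flagged in output metadata).
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974,
    "S": 32.06, "SE": 78.971, "NA": 22.990, "K": 39.098, "MG": 24.305,
    "CA": 40.078, "ZN": 65.38, "CL": 35.45, "F": 18.998,
}


@dataclass
class AtomRecord:
    """One atom with its static metadata; coordinates live in the ensemble."""

    atom_id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    position: np.ndarray  # reference coordinates, A
    partial_charge: float | None = None
    lj_sigma: float | None = None
    lj_epsilon: float | None = None
    author_resid: int | None = None
    icode: str = ""

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not np.all(np.isfinite(self.position)):
            raise ParseError(f"atom {self.atom_id}: non-finite position")
        if self.residue_index < 0:
            raise ParseError(f"atom {self.atom_id}: negative residue index")

    @property
    def mass(self) -> float | None:
        return ATOMIC_MASSES.get(self.element.upper())

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"


@dataclass
class DomainPartition:
    """Named, non-overlapping residue ranges (e.g. N/L1/PAZ/L2/MID/PIWI).

    Ranges are inclusive 0-based internal residue index pairs.
    """

    domains: list[tuple[str, list[tuple[int, int]]]]

    def __post_init__(self) -> None:
        names = [name for name, _ in self.domains]
        if len(set(names)) != len(names):
            raise ParameterError("domain names must be unique")
        seen: set[int] = set()
        for name, ranges in self.domains:
            for lo, hi in ranges:
                if lo > hi or lo < 0:
                    raise ParameterError(f"domain {name}: bad range ({lo},{hi})")
                block = set(range(lo, hi + 1))
                if block & seen:
                    raise ParameterError(f"domain {name}: overlapping ranges")
                seen |= block

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.domains]

    def residues(self, name: str) -> list[int]:
        for dname, ranges in self.domains:
            if dname == name:
                return [i for lo, hi in ranges for i in range(lo, hi + 1)]
        raise SelectionError(f"unknown domain {name!r}")

    def domain_of(self, residue_index: int) -> str | None:
        for dname, ranges in self.domains:
            for lo, hi in ranges:
                if lo <= residue_index <= hi:
                    return dname
        return None

    def validate_against(self, n_residues: int) -> None:
        top = max(hi for _, ranges in self.domains for _, hi in ranges)
        if top >= n_residues:
            raise SelectionError(
                f"partition names residue {top} but structure has {n_residues}"
            )


@dataclass
class EnsembleModel:
    """A reference structure plus frames; the substrate of every stage."""

    atoms: list[AtomRecord]
    frames: np.ndarray  # (n_frames, n_atoms, 3), A
    frame_interval: float = 1.0  # time units per frame, declared by producer
    label: str = ""
    partition: DomainPartition | None = None
    rna_chain: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ParameterError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise EmptyInputError("ensemble needs at least one frame")
        if self.frames.shape[1] != len(self.atoms):
            raise ParameterError(
                f"frame atom count {self.frames.shape[1]} != len(atoms) "
                f"{len(self.atoms)}"
            )
        if self.partition is not None:
            self.partition.validate_against(self.n_residues)

    # -- basic queries -----------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_residues(self) -> int:
        return max(a.residue_index for a in self.atoms) + 1 if self.atoms else 0

    def atom_indices(self, residues: Iterable[int] | None = None,
                     name: str | None = None,
                     heavy_only: bool = False,
                     chain: str | None = None) -> np.ndarray:
        rset = None if residues is None else set(residues)
        idx = [
            i for i, a in enumerate(self.atoms)
            if (rset is None or a.residue_index in rset)
            and (name is None or a.name == name)
            and (not heavy_only or not a.is_hydrogen)
            and (chain is None or a.chain_id == chain)
        ]
        return np.asarray(idx, dtype=int)

    def ca_indices(self, residues: Iterable[int] | None = None) -> np.ndarray:
        idx = self.atom_indices(residues=residues, name="CA")
        if idx.size == 0:
            raise SelectionError("selection contains no CA atoms")
        return idx

    def masses(self, atom_idx: np.ndarray) -> tuple[np.ndarray, bool]:
        """Atomic masses for the given atoms; unit masses where unknown.

        Returns (masses, all_known).
        """
        m = np.array([self.atoms[i].mass or 1.0 for i in atom_idx])
        known = all(self.atoms[i].mass is not None for i in atom_idx)
        return m, known

    def with_frames(self, frames: np.ndarray, **meta) -> "EnsembleModel":
        out = replace(self, frames=np.asarray(frames, dtype=float))
        out.metadata = {**self.metadata, **meta}
        return out

    def concat(self, other: "EnsembleModel") -> "EnsembleModel":
        if other.n_atoms != self.n_atoms:
            raise ParameterError("cannot concatenate: atom counts differ")
        return self.with_frames(np.concatenate([self.frames, other.frames]))


@dataclass
class ClusterResult:
    """Agglomerative-clustering output over trajectory frames."""

    assignments: np.ndarray  # frame -> cluster id (0 = most populated)
    representatives: list[tuple[int, float]]  # (frame_index, population)

    def __post_init__(self) -> None:
        total = sum(w for _, w in self.representatives)
        if abs(total - 1.0) > 1e-9:
            raise ParameterError("cluster populations must sum to 1")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _prevalidate_pdb(path: str) -> None:
    """Cheap line-level PDB sanity scan.

    Raises ParseError naming the offending line, and checks that every MODEL
    contains the same number of atoms.
    """
    counts: list[int] = []
    current = 0
    in_model = False
    any_atom = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec in ("ATOM", "HETATM"):
                any_atom = True
                if len(line.rstrip("\n")) < 54:
                    raise ParseError(f"{path}:{lineno}: truncated {rec} record")
                try:
                    float(line[30:38]); float(line[38:46]); float(line[46:54])
                except ValueError as exc:
                    raise ParseError(
                        f"{path}:{lineno}: unparsable coordinates"
                    ) from exc
                current += 1
            elif rec == "MODEL":
                in_model = True
                current = 0
            elif rec == "ENDMDL":
                counts.append(current)
                current = 0
    if in_model is False and current:
        counts.append(current)
    if not any_atom:
        raise EmptyInputError(f"{path}: no ATOM/HETATM records")
    if len(set(c for c in counts if c)) > 1:
        raise ParseError(
            f"{path}: models have mismatched atom counts {sorted(set(counts))}"
        )


def _guess_element(name: str) -> str:
    name = name.strip()
    if not name:
        return "X"
    if name[0].isdigit():
        name = name.lstrip("0123456789")
    two = name[:2].upper()
    if two in ("CL", "BR", "NA", "MG", "ZN", "FE", "SE") and len(name) <= 2:
        return two.capitalize()
    return name[0].upper()


def read_structure(path: str, format: str = "pdb") -> EnsembleModel:
    """Read a (possibly multi-model) structure file into an ensemble.

    Multi-model PDB files become multi-frame ensembles.  Atom order follows
    the file; insertion codes and author residue numbers are preserved as
    metadata.
    """
    if format != "pdb":
        raise ParameterError(f"unsupported format {format!r}")
    _prevalidate_pdb(path)

    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(path)
    if u.atoms.n_atoms == 0:
        raise EmptyInputError(f"{path}: zero atoms")

    try:
        elements = [str(e) for e in u.atoms.elements]
    except Exception:
        elements = [_guess_element(n) for n in u.atoms.names]
    try:
        icodes = [str(i) for i in u.atoms.icodes]
    except Exception:
        icodes = [""] * u.atoms.n_atoms
    try:
        chains = [str(c) for c in u.atoms.chainIDs]
    except Exception:
        chains = [str(s) for s in u.atoms.segids]

    # contiguous 0-based internal residue indexing in file order
    res_index_of: dict[tuple, int] = {}
    res_idx = np.empty(u.atoms.n_atoms, dtype=int)
    for i, atom in enumerate(u.atoms):
        key = (chains[i], int(atom.resid), icodes[i])
        if key not in res_index_of:
            res_index_of[key] = len(res_index_of)
        res_idx[i] = res_index_of[key]

    frames = np.array([u.atoms.positions.copy() for _ in u.trajectory],
                      dtype=float)
    atoms = [
        AtomRecord(
            atom_id=int(u.atoms.ids[i]) if hasattr(u.atoms, "ids") else i + 1,
            name=str(u.atoms.names[i]),
            element=(elements[i] or _guess_element(u.atoms.names[i])).strip()
            or _guess_element(u.atoms.names[i]),
            residue_index=int(res_idx[i]),
            residue_name=str(u.atoms.resnames[i]),
            chain_id=chains[i],
            position=frames[0, i],
            author_resid=int(u.atoms.resids[i]),
            icode=icodes[i],
        )
        for i in range(u.atoms.n_atoms)
    ]
    return EnsembleModel(atoms=atoms, frames=frames,
                         metadata={"source": str(path)})


def write_structure(ensemble: EnsembleModel, path: str) -> None:
    """Write the ensemble as a (multi-model) PDB v3.3 file."""
    multi = ensemble.n_frames > 1
    with open(path, "w") as fh:
        for f in range(ensemble.n_frames):
            if multi:
                fh.write(f"MODEL     {f + 1:4d}\n")
            for i, a in enumerate(ensemble.atoms):
                x, y, z = ensemble.frames[f, i]
                name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
                resid = a.author_resid if a.author_resid is not None \
                    else a.residue_index + 1
                fh.write(
                    f"ATOM  {(i % 99999) + 1:5d} {name:<4s}{'':1s}"
                    f"{a.residue_name:<4s}{a.chain_id[:1] or 'A':1s}"
                    f"{resid % 10000:4d}{a.icode[:1]:1s}   "
                    f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                    f"          {a.element[:2]:>2s}\n"
                )
            if multi:
                fh.write("ENDMDL\n")
        fh.write("END\n")


def read_parameter_table(path: str):
    """Read a plain atom-parameter table: atom_id,charge,sigma,epsilon."""
    import pandas as pd

    table = pd.read_csv(path)
    required = {"atom_id", "charge", "sigma", "epsilon"}
    if not required <= set(table.columns):
        raise ParseError(
            f"{path}: parameter table needs columns {sorted(required)}"
        )
    return table


def attach_parameters(ensemble: EnsembleModel, table) -> EnsembleModel:
    """Attach charges and LJ parameters to atoms by atom_id (in place)."""
    by_id = table.set_index("atom_id")
    missing = [a.atom_id for a in ensemble.atoms if a.atom_id not in by_id.index]
    if missing:
        raise ParameterError(
            f"parameter table missing atoms: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    for a in ensemble.atoms:
        row = by_id.loc[a.atom_id]
        a.partial_charge = float(row["charge"])
        a.lj_sigma = float(row["sigma"])
        a.lj_epsilon = float(row["epsilon"])
    return ensemble


# ---------------------------------------------------------------------------
# Superposition metrics
# ---------------------------------------------------------------------------

def _check_noncollinear(coords: np.ndarray) -> None:
    if coords.shape[0] < 3:
        raise DegenerateGeometryError("need at least 3 atoms to superpose")
    centered = coords - coords.mean(axis=0)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[1] <= 1e-10 * max(s[0], 1.0):
        raise DegenerateGeometryError("selected atoms are collinear")


def superpose(mobile: np.ndarray, reference: np.ndarray,
              selection: np.ndarray | None = None
              ) -> tuple[np.ndarray, float]:
    """Least-squares (Kabsch) rigid superposition of `mobile` onto `reference`.

    The fit is computed on `selection` (atom indices into both frames; all
    atoms if None) and applied to the whole mobile frame.  Returns the
    transformed frame and the RMSD over the selection.  The rotation is
    proper (det = +1).
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    sel = np.arange(mobile.shape[0]) if selection is None else np.asarray(selection)
    mob = mobile[sel]
    ref = reference[sel]
    _check_noncollinear(mob)
    mob_c = mob.mean(axis=0)
    ref_c = ref.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref - ref_c, mob - mob_c)
    moved = rot.apply(mobile - mob_c) + ref_c
    rmsd_val = float(np.sqrt(np.mean(np.sum((moved[sel] - ref) ** 2, axis=1))))
    return moved, rmsd_val


def rmsd(a: np.ndarray, b: np.ndarray,
         selection: np.ndarray | None = None) -> float:
    """Minimum least-squares RMSD between two frames after superposition."""
    return superpose(a, b, selection)[1]


def rmsf(ensemble: EnsembleModel, selection: Sequence[int] | None = None,
         fit: bool = True) -> np.ndarray:
    """Per-residue Cα root-mean-square fluctuation about the mean structure.

    With `fit`, frames are superposed onto the ensemble mean (two-pass:
    align to frame 0, compute the mean, re-align to it) before averaging.
    """
    if ensemble.n_frames < 2:
        raise EmptyInputError("RMSF needs at least 2 frames")
    idx = ensemble.ca_indices(selection)
    coords = ensemble.frames[:, idx, :]
    if fit:
        ref = coords[0]
        aligned = np.array([superpose(c, ref)[0] for c in coords])
        mean = aligned.mean(axis=0)
        aligned = np.array([superpose(c, mean)[0] for c in aligned])
        coords = aligned
    mean = coords.mean(axis=0)
    return np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=2), axis=0))


def radius_of_gyration(ensemble_or_frame, selection=None,
                       frame: int = 0) -> float:
    """Mass-weighted radius of gyration of one frame (unit masses if
    elements are unknown; that fallback is recorded in ensemble metadata)."""
    if isinstance(ensemble_or_frame, EnsembleModel):
        ens = ensemble_or_frame
        idx = (ens.atom_indices(residues=selection)
               if selection is not None else np.arange(ens.n_atoms))
        if idx.size == 0:
            raise SelectionError("empty selection")
        coords = ens.frames[frame, idx, :]
        masses, known = ens.masses(idx)
        if not known:
            ens.metadata["rg_unit_masses"] = True
    else:
        coords = np.asarray(ensemble_or_frame, dtype=float)
        if selection is not None:
            coords = coords[np.asarray(selection)]
        if coords.shape[0] == 0:
            raise SelectionError("empty selection")
        masses = np.ones(coords.shape[0])
    com = np.average(coords, axis=0, weights=masses)
    return float(np.sqrt(np.average(np.sum((coords - com) ** 2, axis=1),
                                    weights=masses)))


# ---------------------------------------------------------------------------
# Frame clustering
# ---------------------------------------------------------------------------

def pairwise_rmsd_matrix(ensemble: EnsembleModel,
                         selection: Sequence[int] | None = None) -> np.ndarray:
    """All-vs-all superposed Cα RMSD between frames (batched Kabsch).

    rmsd_ij^2 = (|X_i|^2 + |X_j|^2 - 2 sum_k d_k sigma_k) / n_atoms with the
    singular values of the cross-covariance and the proper-rotation sign
    correction; agrees with superpose() pair by pair.
    """
    idx = ensemble.ca_indices(selection)
    coords = ensemble.frames[:, idx, :].astype(float)
    coords = coords - coords.mean(axis=1, keepdims=True)
    n_frames, n_atoms = coords.shape[0], coords.shape[1]
    sq = np.einsum("fai,fai->f", coords, coords)
    mat = np.zeros((n_frames, n_frames))
    iu, ju = np.triu_indices(n_frames, k=1)
    chunk = 4096
    for start in range(0, iu.size, chunk):
        ii = iu[start:start + chunk]
        jj = ju[start:start + chunk]
        H = np.einsum("pai,paj->pij", coords[ii], coords[jj])
        U, S, Vt = np.linalg.svd(H)
        sign = np.sign(np.linalg.det(np.matmul(U, Vt)))
        trace = S[:, 0] + S[:, 1] + sign * S[:, 2]
        msd = np.maximum(sq[ii] + sq[jj] - 2.0 * trace, 0.0) / n_atoms
        mat[ii, jj] = mat[jj, ii] = np.sqrt(msd)
    return mat


def cluster_frames(ensemble: EnsembleModel,
                   selection: Sequence[int] | None = None,
                   epsilon: float = 3.0,
                   linkage: str = "average") -> ClusterResult:
    """Average-linkage agglomerative clustering of frames on pairwise
    superposed Cα RMSD; merging stops once the minimum inter-cluster
    average distance exceeds `epsilon`.

    Cluster representatives minimise the sum of within-cluster distances
    (ties broken by lowest frame index); clusters are ordered by population.
    """
    if epsilon <= 0:
        raise ParameterError("epsilon must be positive")
    if linkage != "average":
        raise ParameterError("only average linkage is supported")
    if ensemble.n_frames < 2:
        raise EmptyInputError("clustering needs at least 2 frames")
    dist = pairwise_rmsd_matrix(ensemble, selection)
    link = hierarchy.linkage(squareform(dist, checks=False), method="average")
    raw = hierarchy.fcluster(link, t=epsilon, criterion="distance")

    labels = np.unique(raw)
    reps = {}
    pops = {}
    n = ensemble.n_frames
    for lab in labels:
        members = np.where(raw == lab)[0]
        within = dist[np.ix_(members, members)].sum(axis=1)
        reps[lab] = int(members[np.argmin(within)])  # argmin -> lowest index tie-break
        pops[lab] = len(members) / n
    # order clusters by population desc, then by representative frame index
    order = sorted(labels, key=lambda lab: (-pops[lab], reps[lab]))
    relabel = {lab: k for k, lab in enumerate(order)}
    assignments = np.array([relabel[lab] for lab in raw])
    representatives = [(reps[lab], pops[lab]) for lab in order]
    return ClusterResult(assignments=assignments, representatives=representatives)
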