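"""Pairwise residue-residue nonbonded energy matrices (EDM), eigenvector
stability profiles, electrostatic nuclei, and domain-level / protein-RNA
interaction-energy aggregation.

E_ij = E_ij^el + E_ij^vdW + G_ij^solv summed over atom pairs within a
distance cutoff.  The electrostatic term uses the Amber Coulomb constant
332.0637 kcal*A/(mol*e^2); the van der Waals term is 12-6 Lennard-Jones
with Lorentz-Berthelot mixing.  The solvation term defaults to zero; a
distance-dependent-dielectric mode (eps(r) = r/A) folds simple screening
into the electrostatic term.  Diagonalizing the EDM yields the first
eigenvector (largest |eigenvalue|), whose energy-weighted per-residue
profile |lambda_1| * v_i^2 highlights the strongest couplings; residues
whose profile passes a small threshold form the "electrostatic nuclei"
stability hubs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import DomainPartition, EnsembleModel
from .errors import ParameterError, SelectionError

COULOMB_KCAL = 332.0637  # kcal*A/(mol*e^2), Amber convention


@dataclass
class EDMResult:
    """Energy decomposition matrix with its eigen summary."""

    matrix: np.ndarray                 # symmetric residue x residue, kcal/mol
    electrostatic: np.ndarray | None = None
    vdw: np.ndarray | None = None
    eigenvalues: np.ndarray | None = None   # descending by |lambda|
    first_eigenvector: np.ndarray | None = None
    profile: np.ndarray | None = None       # |lambda_1| * v_i^2
    solvation_mode: str = "none"
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if not np.allclose(m, m.T, atol=1e-9):
            raise ParameterError("EDM matrix must be symmetric")
        self.matrix = m


@dataclass
class NucleiSet:
    """Stability-hub residues retained by the profile threshold."""

    residues: set[int]
    threshold: float
    intradomain_interaction_counts: dict[str, int]


def _atom_parameters(ensemble: EnsembleModel, atom_idx: np.ndarray):
    missing = [ensemble.atoms[i].atom_id for i in atom_idx
               if ensemble.atoms[i].partial_charge is None
               or ensemble.atoms[i].lj_sigma is None
               or ensemble.atoms[i].lj_epsilon is None]
    if missing:
        raise ParameterError(
            f"missing charge/LJ parameters for atoms: {missing[:10]}"
            + ("..." if len(missing) > 10 else "")
        )
    q = np.array([ensemble.atoms[i].partial_charge for i in atom_idx])
    sig = np.array([ensemble.atoms[i].lj_sigma for i in atom_idx])
    eps = np.array([ensemble.atoms[i].lj_epsilon for i in atom_idx])
    res = np.array([ensemble.atoms[i].residue_index for i in atom_idx])
    return q, sig, eps, res


def _pairwise_components(ensemble: EnsembleModel, frame: int,
                         cutoff: float, solvation: str,
                         min_seq_sep: int,
                         atom_idx: np.ndarray | None = None):
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if solvation not in ("none", "ddd"):
        raise ParameterError(f"unknown solvation mode {solvation!r}")
    if atom_idx is None:
        atom_idx = np.arange(ensemble.n_atoms)
    q, sig, eps, res = _atom_parameters(ensemble, atom_idx)
    coords = ensemble.frames[frame, atom_idx, :]
    n_res = ensemble.n_residues
    el = np.zeros((n_res, n_res))
    vdw = np.zeros((n_res, n_res))

    tree = cKDTree(coords)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if pairs.size:
        a, b = pairs[:, 0], pairs[:, 1]
        keep = np.abs(res[a] - res[b]) >= min_seq_sep
        a, b = a[keep], b[keep]
        r = np.linalg.norm(coords[a] - coords[b], axis=1)
        denom = r * r if solvation == "ddd" else r
        e_el = COULOMB_KCAL * q[a] * q[b] / denom
        s_ab = 0.5 * (sig[a] + sig[b])
        e_ab = np.sqrt(eps[a] * eps[b])
        sr6 = (s_ab / r) ** 6
        e_vdw = 4.0 * e_ab * (sr6 * sr6 - sr6)
        ra, rb = res[a], res[b]
        np.add.at(el, (ra, rb), e_el)
        np.add.at(el, (rb, ra), e_el)
        np.add.at(vdw, (ra, rb), e_vdw)
        np.add.at(vdw, (rb, ra), e_vdw)
    return el, vdw


def pairwise_energy(ensemble: EnsembleModel, frame: int = 0,
                    cutoff: float = 10.0, solvation: str = "none",
                    min_seq_sep: int = 2,
                    selection: Sequence[int] | None = None) -> EDMResult:
    """Residue-pair nonbonded energy matrix on one frame.

    Sequence-adjacent pairs (|i-j| < min_seq_sep) are excluded: their
    energies are dominated by covalent terms this model omits.
    """
    atom_idx = (ensemble.atom_indices(residues=selection)
                if selection is not None else None)
    el, vdw = _pairwise_components(ensemble, frame, cutoff, solvation,
                                   min_seq_sep, atom_idx)
    return EDMResult(matrix=el + vdw, electrostatic=el, vdw=vdw,
                     solvation_mode=solvation)


def edm_eigen(matrix_or_result, profile_kind: str = "energy_weighted"
              ) -> EDMResult:
    """Eigen-decomposition of the EDM and the per-residue stability profile.

    The first eigenvector belongs to the eigenvalue of largest magnitude
    (it recapitulates most of the nonbonded energy); its sign is fixed so
    the component sum is nonnegative.  profile_i = |lambda_1| * v_i^2
    (nonnegative energy-weighted participation) by default, or |v_i| with
    profile_kind="abs".
    """
    if isinstance(matrix_or_result, EDMResult):
        result = matrix_or_result
    else:
        result = EDMResult(matrix=np.asarray(matrix_or_result, dtype=float))
    vals, vecs = np.linalg.eigh(result.matrix)
    order = np.argsort(-np.abs(vals), kind="stable")
    vals = vals[order]
    vecs = vecs[:, order]
    v1 = vecs[:, 0].copy()
    if v1.sum() < 0:
        v1 *= -1.0
    if vals.size > 1 and abs(abs(vals[0]) - abs(vals[1])) < 1e-9:
        result.warnings.append(
            "leading eigenvalue degenerate within 1e-9; "
            "first eigenvector not unique"
        )
    result.eigenvalues = vals
    result.first_eigenvector = v1
    if profile_kind == "energy_weighted":
        result.profile = np.abs(vals[0]) * v1 ** 2
    elif profile_kind == "abs":
        result.profile = np.abs(v1)
    else:
        raise ParameterError(f"unknown profile kind {profile_kind!r}")
    return result


def electrostatic_nuclei(edm: EDMResult, partition: DomainPartition,
                         threshold: float = 0.005) -> NucleiSet:
    """Residues whose profile value is >= threshold (inclusive), with
    per-domain counts of interacting retained pairs (|E_ij| > 0 within the
    same domain)."""
    if threshold < 0:
        raise ParameterError("threshold must be nonnegative")
    if edm.profile is None:
        raise ParameterError("run edm_eigen first")
    retained = {int(i) for i in np.where(edm.profile >= threshold)[0]}
    counts: dict[str, int] = {}
    for name in partition.names:
        members = sorted(set(partition.residues(name)) & retained)
        c = 0
        for x, i in enumerate(members):
            for j in members[x + 1:]:
                if abs(edm.matrix[i, j]) > 0.0:
                    c += 1
        counts[name] = c
    return NucleiSet(residues=retained, threshold=threshold,
                     intradomain_interaction_counts=counts)


def interdomain_energy(ensemble: EnsembleModel,
                       partition: DomainPartition | None = None,
                       cutoff: float = 10.0, solvation: str = "none",
                       min_seq_sep: int = 2,
                       frames: Sequence[int] | None = None) -> pd.DataFrame:
    """Frame-averaged nonbonded interaction energies between domain pairs.

    Returns a table with electrostatic, vdW and total (= el + vdW)
    kcal/mol per unordered domain pair, averaged over the given frames.
    """
    partition = partition or ensemble.partition
    if partition is None:
        raise SelectionError("no domain partition available")
    frames = list(range(ensemble.n_frames)) if frames is None else list(frames)
    names = partition.names
    dom_res = {n: np.asarray(partition.residues(n)) for n in names}
    acc_el = {}
    acc_vdw = {}
    for f in frames:
        el, vdw = _pairwise_components(ensemble, f, cutoff, solvation,
                                       min_seq_sep)
        for x, na in enumerate(names):
            for nb in names[x + 1:]:
                block = np.ix_(dom_res[na], dom_res[nb])
                key = (na, nb)
                acc_el[key] = acc_el.get(key, 0.0) + el[block].sum()
                acc_vdw[key] = acc_vdw.get(key, 0.0) + vdw[block].sum()
    rows = []
    for (na, nb), e in acc_el.items():
        e_mean = e / len(frames)
        v_mean = acc_vdw[(na, nb)] / len(frames)
        if e_mean == 0.0 and v_mean == 0.0:
            continue  # no atom pair of this domain pair inside the cutoff
        rows.append({"group_a": na, "group_b": nb, "electrostatic": e_mean,
                     "vdw": v_mean, "total": e_mean + v_mean,
                     "n_frames": len(frames)})
    return pd.DataFrame(rows,
                        columns=["group_a", "group_b", "electrostatic",
                                 "vdw", "total", "n_frames"])


def protein_rna_interface(ensemble: EnsembleModel,
                          rna_chain: str | None = None,
                          contact_cutoff: float = 4.5,
                          cutoff: float = 10.0, solvation: str = "none",
                          frames: Sequence[int] | None = None
                          ) -> tuple[pd.DataFrame, np.ndarray]:
    """Protein-domain x RNA interaction energies and per-frame heavy-atom
    contact counts (pairs within contact_cutoff)."""
    rna_chain = rna_chain or ensemble.rna_chain
    if rna_chain is None:
        raise SelectionError("ensemble has no RNA chain")
    rna_atoms = ensemble.atom_indices(chain=rna_chain, heavy_only=True)
    if rna_atoms.size == 0:
        raise SelectionError(f"no atoms in RNA chain {rna_chain!r}")
    prot_atoms = np.array([
        i for i in range(ensemble.n_atoms)
        if ensemble.atoms[i].chain_id != rna_chain
        and not ensemble.atoms[i].is_hydrogen
    ])
    frames = list(range(ensemble.n_frames)) if frames is None else list(frames)
    rna_res = sorted({ensemble.atoms[i].residue_index for i in rna_atoms})
    partition = ensemble.partition
    groups: dict[str, np.ndarray]
    if partition is not None:
        groups = {n: np.asarray(partition.residues(n))
                  for n in partition.names}
    else:
        groups = {"protein": np.asarray(sorted(
            {ensemble.atoms[i].residue_index for i in prot_atoms}))}

    acc_el = {n: 0.0 for n in groups}
    acc_vdw = {n: 0.0 for n in groups}
    contacts = np.zeros(len(frames), dtype=int)
    for fi, f in enumerate(frames):
        el, vdw = _pairwise_components(ensemble, f, cutoff, solvation,
                                       min_seq_sep=0)
        for n, res in groups.items():
            block = np.ix_(res, rna_res)
            acc_el[n] += el[block].sum()
            acc_vdw[n] += vdw[block].sum()
        ptree = cKDTree(ensemble.frames[f, prot_atoms, :])
        rtree = cKDTree(ensemble.frames[f, rna_atoms, :])
        contacts[fi] = int(ptree.count_neighbors(rtree, contact_cutoff))
    rows = []
    for n in groups:
        e = acc_el[n] / len(frames)
        v = acc_vdw[n] / len(frames)
        rows.append({"group_a": n, "group_b": f"RNA({rna_chain})",
                     "electrostatic": e, "vdw": v, "total": e + v,
                     "n_frames": len(frames)})
    return pd.DataFrame(rows), contacts
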