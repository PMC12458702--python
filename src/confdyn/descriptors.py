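"""Geometric determinants, pooled standardized PCA and Calinski-Harabasz
selection of the discriminative PC pair.

Thirteen per-frame descriptors summarize the multi-domain geometry: eight
centre-of-mass (COM) distances and five COM angles between domains (and the
composite lobes NPAZ = N+PAZ and MIDPIWI = MID+PIWI, plus a helix-7
sub-selection).  Descriptors from several labeled ensembles are pooled,
mean-centred and scaled to unit variance, and decomposed by PCA.  The first
two PCs are excluded (they carry the dominant common-mode conformational
shifts); among the remaining PC pairs whose combined explained variance is
at least 15%, the pair with the highest Calinski-Harabasz score on its 2-D
projection separates the labels best, and the descriptors with the highest
absolute loadings on that pair are the key discriminative features.

The COM "angle between domain X and Y" is defined as the angle at the
whole-selection COM subtended by COM_X and COM_Y (the angle construction is
a package choice; see docs/methods.md) and is configurable via PairSpec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import DomainPartition, EnsembleModel
from .errors import (
    DegenerateGeometryError,
    ParameterError,
    SelectionError,
)

#: Canonical descriptor order: 8 COM distances (A) then 5 COM angles (deg).
DESCRIPTOR_NAMES = (
    "d_PAZ_PIWI", "d_PAZ_N", "d_PIWI_N", "d_PAZ_MID", "d_NPAZ_MIDPIWI",
    "d_PIWI_L2", "d_PAZ_helix7", "d_L1_L2",
    "a_PAZ_PIWI", "a_PAZ_N", "a_PIWI_N", "a_PAZ_MID", "a_NPAZ_MIDPIWI",
)

#: Composite lobe definitions (members silently restricted to the domains
#: actually present in a partition).
COMPOSITE_GROUPS = {
    "NPAZ": ("N", "PAZ"),
    "MIDPIWI": ("MID", "PIWI"),
}


def resolve_group_domains(group: str, domain_names: list[str]) -> list[str]:
    """Domain names making up a descriptor group (composites expanded)."""
    if group in COMPOSITE_GROUPS:
        members = [d for d in COMPOSITE_GROUPS[group] if d in domain_names]
        if not members:
            raise SelectionError(f"composite group {group} matches no domain")
        return members
    if group in domain_names:
        return [group]
    raise SelectionError(f"unknown descriptor group {group!r}")


@dataclass
class PairSpec:
    """Resolves descriptor groups to residue selections.

    `extra_selections` supplies sub-domain selections such as helix7 (a
    user-supplied residue range for real proteins; synthetic fixtures default
    to the middle third of L2).
    """

    descriptors: tuple[str, ...] = DESCRIPTOR_NAMES
    extra_selections: dict[str, list[int]] = field(default_factory=dict)

    def group_residues(self, group: str,
                       partition: DomainPartition) -> list[int]:
        if group in self.extra_selections:
            sel = list(self.extra_selections[group])
            if not sel:
                raise SelectionError(f"extra selection {group!r} is empty")
            return sel
        members = resolve_group_domains(group, partition.names)
        return [r for m in members for r in partition.residues(m)]


def default_pair_spec(partition: DomainPartition) -> PairSpec:
    """PairSpec with helix7 defaulting to the middle third of L2."""
    extras = {}
    if "L2" in partition.names:
        l2 = partition.residues("L2")
        third = max(1, len(l2) // 3)
        extras["helix7"] = l2[third:2 * third] or l2[:1]
    return PairSpec(extra_selections=extras)


@dataclass
class DescriptorMatrix:
    """frames x 13 descriptor values with per-frame ensemble labels."""

    values: np.ndarray
    labels: np.ndarray
    descriptor_names: tuple[str, ...] = DESCRIPTOR_NAMES

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.shape[1] != len(self.descriptor_names):
            raise ParameterError("descriptor column count mismatch")
        ang = [k for k, n in enumerate(self.descriptor_names)
               if n.startswith("a_")]
        dst = [k for k, n in enumerate(self.descriptor_names)
               if n.startswith("d_")]
        if ang and not np.all((self.values[:, ang] >= 0.0)
                              & (self.values[:, ang] <= 180.0)):
            raise ParameterError("angles must lie in [0, 180] degrees")
        if dst and not np.all(self.values[:, dst] > 0.0):
            raise ParameterError("distances must be positive")


def compute_descriptors(ensemble: EnsembleModel,
                        partition: DomainPartition | None = None,
                        pair_spec: PairSpec | None = None) -> DescriptorMatrix:
    """Per-frame COM distances and angles for the configured descriptors.

    COM is the unweighted Cα centroid of a group; the angle vertex is the
    COM of all (protein) Cα atoms.
    """
    partition = partition or ensemble.partition
    if partition is None:
        raise SelectionError("no domain partition available")
    pair_spec = pair_spec or default_pair_spec(partition)

    protein_res = [r for name in partition.names
                   for r in partition.residues(name)]
    all_ca = ensemble.ca_indices(protein_res)
    vertex = ensemble.frames[:, all_ca, :].mean(axis=1)  # (F, 3)

    coms: dict[str, np.ndarray] = {}

    def com(group: str) -> np.ndarray:
        if group not in coms:
            res = pair_spec.group_residues(group, partition)
            idx = ensemble.ca_indices(res)
            coms[group] = ensemble.frames[:, idx, :].mean(axis=1)
        return coms[group]

    cols = []
    for name in pair_spec.descriptors:
        kind, ga, gb = name.split("_", 2)
        a, b = com(ga), com(gb)
        if kind == "d":
            cols.append(np.linalg.norm(a - b, axis=1))
        elif kind == "a":
            va = a - vertex
            vb = b - vertex
            na = np.linalg.norm(va, axis=1)
            nb = np.linalg.norm(vb, axis=1)
            if np.any(na < 1e-9) or np.any(nb < 1e-9):
                raise DegenerateGeometryError(
                    f"{name}: a domain COM coincides with the angle vertex"
                )
            cosang = np.clip(np.sum(va * vb, axis=1) / (na * nb), -1.0, 1.0)
            cols.append(np.degrees(np.arccos(cosang)))
        else:
            raise SelectionError(f"unknown descriptor kind in {name!r}")
    values = np.stack(cols, axis=1)
    labels = np.full(ensemble.n_frames, ensemble.label, dtype=object)
    return DescriptorMatrix(values=values, labels=labels,
                            descriptor_names=tuple(pair_spec.descriptors))


@dataclass
class PCASelection:
    """Pooled-PCA result plus (after select_discriminative) the CH ranking."""

    explained_variance: np.ndarray          # per-PC variance fractions
    coefficients: np.ndarray                # (n_descriptors, n_pcs) loadings
    descriptor_names: tuple[str, ...]
    scores: np.ndarray                      # (n_frames, n_pcs) projections
    labels: np.ndarray
    mean: np.ndarray
    scale: np.ndarray
    candidate_pairs: list[tuple[int, int, float, float]] = field(
        default_factory=list)  # (pc_a, pc_b, combined variance, CH); 1-based
    top_pair: tuple[int, int] | None = None
    top_descriptors: list[tuple[str, float]] = field(default_factory=list)
    no_qualifying_pair: bool = False


def fit_pca(matrices: list[DescriptorMatrix]) -> PCASelection:
    """Standardized PCA on the pooled multi-ensemble descriptor data.

    Standardization uses the pooled mean/SD; PCs are ordered by decreasing
    variance and signed so each PC's largest-|loading| coefficient is
    positive.
    """
    from sklearn.decomposition import PCA

    if len(matrices) < 2:
        raise ParameterError("pooled PCA needs at least 2 ensembles")
    names = matrices[0].descriptor_names
    for m in matrices[1:]:
        if m.descriptor_names != names:
            raise ParameterError("descriptor sets differ between ensembles")
    data = np.vstack([m.values for m in matrices])
    labels = np.concatenate([m.labels for m in matrices])
    mean = data.mean(axis=0)
    scale = data.std(axis=0, ddof=0)
    dead = np.where(scale == 0.0)[0]
    if dead.size:
        raise ParameterError(
            f"zero-variance descriptor(s): {[names[k] for k in dead]}"
        )
    z = (data - mean) / scale
    pca = PCA(n_components=len(names), svd_solver="full")
    scores = pca.fit_transform(z)
    load = pca.components_.T.copy()        # (n_desc, n_pcs)
    for k in range(load.shape[1]):
        j = int(np.argmax(np.abs(load[:, k])))
        if load[j, k] < 0:
            load[:, k] *= -1.0
            scores[:, k] *= -1.0
    return PCASelection(
        explained_variance=pca.explained_variance_ratio_,
        coefficients=load, descriptor_names=names, scores=scores,
        labels=labels, mean=mean, scale=scale,
    )


def calinski_harabasz(points: np.ndarray, labels: np.ndarray) -> float:
    """CH = [B/(k-1)] / [W/(n-k)] on a (typically 2-D) projection.

    B is the between-group and W the within-group sum of squares; a perfect
    separation (W = 0) returns +infinity.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    labels = np.asarray(labels)
    uniq, inv, counts = np.unique(labels, return_inverse=True,
                                  return_counts=True)
    if uniq.size < 2:
        raise ParameterError("CH needs at least 2 labels")
    if np.any(counts < 2):
        raise ParameterError("CH needs at least 2 points per label")
    n, k = points.shape[0], uniq.size
    grand = points.mean(axis=0)
    sums = np.zeros((k, points.shape[1]))
    np.add.at(sums, inv, points)
    means = sums / counts[:, None]
    between = float(np.sum(counts * np.sum((means - grand) ** 2, axis=1)))
    total = float(np.sum((points - grand) ** 2))
    within = total - between
    if within <= 0.0:
        return np.inf
    return (between / (k - 1)) / (within / (n - k))


def permutation_null_pvalue(points: np.ndarray, labels: np.ndarray,
                            n_permutations: int = 200,
                            rng: np.random.Generator | int | None = None
                            ) -> tuple[float, float, np.ndarray]:
    """Permutation p-value of the observed CH against label-shuffled nulls.

    Returns (observed CH, p-value, null CH values).  p is the fraction of
    permutations (including the observation) with CH >= observed.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    observed = calinski_harabasz(points, labels)
    null = np.array([
        calinski_harabasz(points, rng.permutation(labels))
        for _ in range(n_permutations)
    ])
    p = (1.0 + np.sum(null >= observed)) / (n_permutations + 1.0)
    return observed, float(p), null


def select_discriminative(pca: PCASelection,
                          labels: np.ndarray | None = None,
                          min_pair_variance: float = 0.15,
                          exclude_first: int = 2) -> PCASelection:
    """Rank PC pairs (excluding PC1-2) by CH and pick the top descriptors.

    Candidate pairs are unordered pairs from PC3..PCn whose combined
    explained-variance fraction is at least `min_pair_variance`; the pair
    with the highest CH on its 2-D projection wins, and descriptors are
    ranked by max(|loading on PC_a|, |loading on PC_b|).  If no pair
    qualifies the result is flagged `no_qualifying_pair` (never a silent
    fallback).
    """
    labels = pca.labels if labels is None else np.asarray(labels)
    evr = pca.explained_variance
    n_pcs = evr.size
    candidates = []
    for i in range(exclude_first, n_pcs):
        for j in range(i + 1, n_pcs):
            combined = float(evr[i] + evr[j])
            if combined >= min_pair_variance:
                ch = calinski_harabasz(pca.scores[:, [i, j]], labels)
                candidates.append((i + 1, j + 1, combined, ch))
    pca.candidate_pairs = candidates
    if not candidates:
        pca.no_qualifying_pair = True
        pca.top_pair = None
        pca.top_descriptors = []
        return pca
    best = max(candidates, key=lambda c: (c[3], -c[0], -c[1]))
    pca.top_pair = (best[0], best[1])
    ia, ib = best[0] - 1, best[1] - 1
    weight = np.maximum(np.abs(pca.coefficients[:, ia]),
                        np.abs(pca.coefficients[:, ib]))
    order = np.argsort(-weight, kind="stable")
    pca.top_descriptors = [(pca.descriptor_names[k], float(weight[k]))
                           for k in order]
    return pca
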