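"""Survival probability of water molecules in named internal regions.

A water resides in a region when its oxygen is within the inclusion radius
(default 4 A) of any anchor atom.  The survival probability
P(tau) = (1/T_n) * sum_t N(t, tau) / N(t) is the fraction of waters present
at time t that remain *continuously* present through t + tau, averaged over
time origins; the trajectory is split into fixed-length windows (after an
equilibration skip) and P is averaged across windows.  All time parameters
are in frames here; physical defaults (20 ns windows, 100 ns skip,
tau 0.1-1 ns) convert through the ensemble's frame_interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import EnsembleModel
from .errors import EmptyInputError, ParameterError, SelectionError

WATER_RESNAMES = ("HOH", "WAT", "TIP3", "SOL")


@dataclass
class RegionDefinition:
    """A named region anchored on explicit atoms (side-chain / backbone /
    Cβ selections resolve to atom indices via region_from_selections)."""

    name: str
    anchor_atom_indices: list[int]
    inclusion_radius: float = 4.0

    def __post_init__(self) -> None:
        if not self.anchor_atom_indices:
            raise ParameterError("region needs at least one anchor atom")
        if self.inclusion_radius <= 0:
            raise ParameterError("inclusion radius must be positive")


BACKBONE_NAMES = {"N", "CA", "C", "O", "OXT"}


def region_from_selections(ensemble: EnsembleModel, name: str,
                           side_chain_residues: Sequence[int] = (),
                           backbone_o_residues: Sequence[int] = (),
                           backbone_residues: Sequence[int] = (),
                           cbeta_residues: Sequence[int] = (),
                           inclusion_radius: float = 4.0
                           ) -> RegionDefinition:
    """Build a region from per-residue anchor selections (the style used
    for internal hydration pockets: side-chain atoms of some residues,
    backbone oxygens or whole backbones of others, a Cβ here and there)."""
    anchors: list[int] = []
    for i, a in enumerate(ensemble.atoms):
        r = a.residue_index
        if r in side_chain_residues and a.name not in BACKBONE_NAMES \
                and not a.is_hydrogen:
            anchors.append(i)
        if r in backbone_o_residues and a.name == "O":
            anchors.append(i)
        if r in backbone_residues and a.name in BACKBONE_NAMES:
            anchors.append(i)
        if r in cbeta_residues and a.name == "CB":
            anchors.append(i)
    return RegionDefinition(name=name, anchor_atom_indices=sorted(set(anchors)),
                            inclusion_radius=inclusion_radius)


def occupancy_trace(ensemble: EnsembleModel, region: RegionDefinition,
                    water_resnames: Sequence[str] = WATER_RESNAMES
                    ) -> list[frozenset[int]]:
    """Per-frame set of water residue ids whose oxygen lies within the
    inclusion radius (inclusive) of any anchor atom."""
    water_idx = np.array([
        i for i, a in enumerate(ensemble.atoms)
        if a.residue_name in water_resnames and a.element.upper() == "O"
    ])
    if water_idx.size == 0:
        raise EmptyInputError("no water oxygens found")
    anchors = np.asarray(region.anchor_atom_indices, dtype=int)
    if anchors.max() >= ensemble.n_atoms:
        raise SelectionError("region anchors outside the structure")
    water_ids = np.array([ensemble.atoms[i].residue_index
                          for i in water_idx])
    out: list[frozenset[int]] = []
    chunk = max(1, 2_000_000 // max(1, water_idx.size * anchors.size))
    for start in range(0, ensemble.n_frames, chunk):
        wat = ensemble.frames[start:start + chunk][:, water_idx, :]
        anc = ensemble.frames[start:start + chunk][:, anchors, :]
        d2 = np.min(np.sum((wat[:, :, None, :] - anc[:, None, :, :]) ** 2,
                           axis=3), axis=2)
        for row in d2:
            out.append(frozenset(
                water_ids[row <= region.inclusion_radius ** 2 + 1e-12]))
    return out


@dataclass
class SurvivalCurve:
    taus: np.ndarray                   # frames
    values: np.ndarray                 # P(tau) in [0, 1]
    stderr: np.ndarray
    n_windows: int
    equilibration_skipped: int
    label: str = ""

    def __post_init__(self) -> None:
        self.taus = np.asarray(self.taus)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ParameterError("P(tau) must lie in [0, 1]")
        if np.any(np.diff(self.values) > 1e-12):
            raise ParameterError("P(tau) must be non-increasing")
        if self.taus.size and self.taus[0] == 0 \
                and abs(self.values[0] - 1.0) > 1e-12:
            raise ParameterError("P(0) must equal 1")

    def auc(self) -> float:
        """Area under P(tau) over the tau grid (trapezoid), a scalar
        residence summary."""
        return float(np.trapezoid(self.values, self.taus))


def survival_probability(traces: list[frozenset[int]],
                         taus: Sequence[int],
                         window_length: int,
                         equilibration_skip: int = 0,
                         label: str = "") -> SurvivalCurve:
    """Windowed continuous-presence survival estimator.

    Within each window, origins t are those with t + max(tau) inside the
    window (a common origin set for all lags, which guarantees a monotone
    curve); N(t, tau) counts waters present at t and at every frame through
    t + tau; origins with N(t) = 0 are skipped.  P is averaged across
    windows; stderr is the across-window SD / sqrt(n_windows).
    """
    taus = np.asarray(sorted(taus), dtype=int)
    if np.any(taus < 0):
        raise ParameterError("taus must be nonnegative")
    if taus.size == 0:
        raise ParameterError("need at least one tau")
    if taus.max() >= window_length:
        raise ParameterError("tau must be smaller than the window length")
    n_frames = len(traces)
    if n_frames < equilibration_skip + window_length:
        raise ParameterError("trajectory shorter than skip + one window")

    ids = sorted(set().union(*traces)) if traces else []
    id_pos = {w: k for k, w in enumerate(ids)}
    presence = np.zeros((n_frames, len(ids)), dtype=bool)
    for t, s in enumerate(traces):
        for w in s:
            presence[t, id_pos[w]] = True

    max_tau = int(taus.max())
    per_window = []
    start = equilibration_skip
    while start + window_length <= n_frames:
        block = presence[start:start + window_length]
        T = block.shape[0]
        # run[t, w] = length of the consecutive-presence run starting at t
        run = np.zeros((T, block.shape[1]), dtype=int)
        run[T - 1] = block[T - 1].astype(int)
        for t in range(T - 2, -1, -1):
            run[t] = np.where(block[t], run[t + 1] + 1, 0)
        origins = np.arange(0, T - max_tau)
        vals = np.full(taus.size, np.nan)
        n_t = block[origins].sum(axis=1)
        valid = n_t > 0
        if valid.any():
            for k, tau in enumerate(taus):
                surv = (run[origins] >= tau + 1).sum(axis=1)
                vals[k] = np.mean(surv[valid] / n_t[valid])
        per_window.append(vals)
        start += window_length
    per_window = np.array(per_window)
    with np.errstate(invalid="ignore"):
        values = np.nanmean(per_window, axis=0)
        counts = np.sum(~np.isnan(per_window), axis=0)
        sd = np.nanstd(per_window, axis=0, ddof=0)
    stderr = np.where(counts > 0, sd / np.sqrt(np.maximum(counts, 1)), np.nan)
    values = np.nan_to_num(values, nan=0.0)
    return SurvivalCurve(taus=taus, values=values, stderr=stderr,
                         n_windows=per_window.shape[0],
                         equilibration_skipped=equilibration_skip,
                         label=label)


def compare_conditions(curves: dict[str, SurvivalCurve]) -> dict:
    """Per-tau differences between labeled curves plus an AUC summary.

    Returns {"auc": {label: value}, "differences": {(a, b): P_a - P_b}}.
    """
    labels = list(curves)
    if len(labels) < 2:
        raise ParameterError("need at least two conditions")
    ref = curves[labels[0]].taus
    for lab in labels[1:]:
        if not np.array_equal(curves[lab].taus, ref):
            raise ParameterError("tau grids differ between conditions")
    auc = {lab: curves[lab].auc() for lab in labels}
    diffs = {}
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            diffs[(a, b)] = curves[a].values - curves[b].values
    return {"auc": auc, "differences": diffs, "taus": ref}
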