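"""Residue-pair distance-fluctuation (DF) maps.

DF_ij is the time-averaged mean-square fluctuation of the Cα-Cα distance
r_ij:  DF_ij = <(r_ij - <r_ij>)^2> = <r_ij^2> - <r_ij>^2.  Low values mark
dynamically coordinated residue pairs, high values flexible ones; the
bound-minus-apo difference maps where internal coordination changes on
ligand binding.  No superposition is applied: pairwise distances are
invariant under rigid motion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .core import DomainPartition, EnsembleModel
from .errors import EmptyInputError, ParameterError, SelectionError


@dataclass
class DFMatrix:
    """Symmetric residue x residue time-averaged distance-fluctuation map (A^2)."""

    values: np.ndarray
    selection: list[int]
    n_frames: int

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ParameterError("DF matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ParameterError("DF matrix must be symmetric")
        if np.any(np.diag(v) != 0.0):
            raise ParameterError("DF diagonal must be exactly zero")
        if np.any(v < 0):
            raise ParameterError("DF values must be nonnegative")
        self.values = v


def compute_df(ensemble: EnsembleModel,
               selection: Sequence[int] | None = None,
               equilibration_skip: int = 0,
               chunk: int = 256) -> DFMatrix:
    """DF matrix over all frames (after an optional equilibration skip).

    One-pass accumulation of sum(r) and sum(r^2) in frame chunks with Kahan
    compensation; agrees with a two-pass evaluation to well below 1e-8 A^2
    at desk scale.
    """
    if ensemble.n_frames - equilibration_skip < 2:
        raise EmptyInputError("DF needs at least 2 frames after the skip")
    idx = ensemble.ca_indices(selection)
    residues = [ensemble.atoms[i].residue_index for i in idx]
    n = idx.size
    m = n * (n - 1) // 2
    s1 = np.zeros(m)
    s2 = np.zeros(m)
    c1 = np.zeros(m)
    c2 = np.zeros(m)
    n_frames = 0
    for start in range(equilibration_skip, ensemble.n_frames, chunk):
        block = ensemble.frames[start:start + chunk, idx, :]
        for frame in block:
            r = pdist(frame)
            for acc, comp, val in ((s1, c1, r), (s2, c2, r * r)):
                y = val - comp
                t = acc + y
                comp[:] = (t - acc) - y
                acc[:] = t
        n_frames += block.shape[0]
    mean = s1 / n_frames
    df = s2 / n_frames - mean * mean
    df = np.maximum(df, 0.0)  # clamp fp negatives of order -1e-16
    mat = squareform(df)
    return DFMatrix(values=mat, selection=residues, n_frames=n_frames)


def df_block_summary(df: DFMatrix, partition: DomainPartition):
    """Domain x domain mean DF table; entry (A, B) averages DF_ij over
    i in A, j in B, i != j."""
    import pandas as pd

    pos_of = {res: k for k, res in enumerate(df.selection)}
    names = partition.names
    members = {}
    for name in names:
        sel = [pos_of[r] for r in partition.residues(name) if r in pos_of]
        if len(sel) < 1:
            raise SelectionError(f"domain {name} has no selected residues")
        members[name] = np.asarray(sel)
    table = np.zeros((len(names), len(names)))
    for a, na in enumerate(names):
        for b, nb in enumerate(names):
            block = df.values[np.ix_(members[na], members[nb])]
            if a == b:
                k = members[na].size
                if k < 2:
                    table[a, b] = 0.0
                    continue
                table[a, b] = block.sum() / (k * (k - 1))
            else:
                table[a, b] = block.mean()
    return pd.DataFrame(table, index=names, columns=names)


def df_difference(df_bound: DFMatrix, df_apo: DFMatrix) -> np.ndarray:
    """Elementwise bound - apo DF (signed, A^2)."""
    if df_bound.values.shape != df_apo.values.shape:
        raise ParameterError("DF matrices have mismatched shapes")
    if df_bound.selection != df_apo.selection:
        raise ParameterError("DF matrices computed on different selections")
    return df_bound.values - df_apo.values
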