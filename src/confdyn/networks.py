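"""Hydrogen-bond / salt-bridge detection, persistence filtering,
equivalent-atom averaging and intra-/inter-domain classification.

Persistence is the fraction of trajectory frames in which an interaction is
formed.  Interactions persisting in at least 5% of frames are retained;
those present in more than 20% of frames are flagged as the most meaningful
ones.  Bonds mediated by chemically equivalent side-chain atoms (Asp
OD1/OD2, Glu OE1/OE2, Arg NH1/NH2, Phe/Tyr ring pairs) are merged, with the
merged persistence the arithmetic mean of the members and the merged trace
their frame-wise OR (kept for classification only).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import DomainPartition, EnsembleModel
from .errors import EmptyInputError, ParameterError

_DATA = importlib.resources.files("confdyn") / "data"


def _load_table(name: str) -> pd.DataFrame:
    with importlib.resources.as_file(_DATA / name) as path:
        return pd.read_csv(path)


@dataclass
class BondEvent:
    """One interaction with its per-frame occupancy trace."""

    kind: str                      # "hbond" | "saltbridge"
    res_a: int                     # donor / cation residue (internal index)
    atom_a: str
    res_b: int                     # acceptor / anion residue
    atom_b: str
    trace: np.ndarray              # per-frame boolean occupancy
    persistence: float | None = None
    domain_a: str | None = None
    domain_b: str | None = None
    classification: str | None = None   # "intra" | "inter"
    flagged: bool = False
    merged_atoms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.trace = np.asarray(self.trace, dtype=bool)
        if self.trace.size == 0:
            raise EmptyInputError("bond event has an empty trace")
        if self.persistence is None:
            self.persistence = float(self.trace.mean())

    def classify(self, partition: DomainPartition) -> "BondEvent":
        self.domain_a = partition.domain_of(self.res_a)
        self.domain_b = partition.domain_of(self.res_b)
        self.classification = ("intra" if self.domain_a == self.domain_b
                               and self.domain_a is not None else "inter")
        return self


@dataclass
class PersistenceTable:
    """Equivalence-averaged bonds after the retain/flag thresholds."""

    bonds: list[BondEvent]
    retain_threshold: float = 0.05
    flag_threshold: float = 0.20

    def to_dataframe(self) -> pd.DataFrame:
        rows = [{
            "kind": b.kind, "res_a": b.res_a, "atom_a": b.atom_a,
            "domain_a": b.domain_a, "res_b": b.res_b, "atom_b": b.atom_b,
            "domain_b": b.domain_b, "classification": b.classification,
            "persistence": b.persistence, "flagged": b.flagged,
        } for b in self.bonds]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Detection
# ---------------------------------------------------------------------------

def _role_atoms(ensemble: EnsembleModel, table: pd.DataFrame,
                role: str) -> np.ndarray:
    wanted = table[table["role"] == role]
    generic = set(wanted.loc[wanted["residue"] == "*", "atom"])
    specific = {(r, a) for r, a in zip(wanted["residue"], wanted["atom"])
                if r != "*"}
    idx = [i for i, at in enumerate(ensemble.atoms)
           if at.name in generic or (at.residue_name, at.name) in specific]
    return np.asarray(idx, dtype=int)


def _attached_hydrogens(ensemble: EnsembleModel,
                        donor_idx: np.ndarray) -> dict[int, list[int]]:
    """Hydrogens covalently attached to each donor heavy atom, identified
    geometrically (within 1.3 A in the reference frame, same residue)."""
    h_idx = np.array([i for i, a in enumerate(ensemble.atoms)
                      if a.is_hydrogen], dtype=int)
    attached: dict[int, list[int]] = {int(d): [] for d in donor_idx}
    if h_idx.size == 0:
        return attached
    ref = ensemble.frames[0]
    tree = cKDTree(ref[h_idx])
    for d in donor_idx:
        near = tree.query_ball_point(ref[d], 1.3)
        for k in near:
            h = int(h_idx[k])
            if ensemble.atoms[h].residue_index == \
                    ensemble.atoms[d].residue_index:
                attached[int(d)].append(h)
    return attached


def detect_hbonds(ensemble: EnsembleModel, d_cut: float = 3.0,
                  angle_cut: float = 160.0,
                  donor_table: pd.DataFrame | None = None
                  ) -> list[BondEvent]:
    """Geometric hydrogen bonds: donor-acceptor heavy-atom distance <= d_cut
    and D-H...A angle >= angle_cut (the best attached hydrogen counts).

    Donors/acceptors come from the bundled chemistry table (N/O chemistry);
    structures without explicit hydrogens need a donor table mapping heavy
    donors to hydrogen positions.
    """
    chem = donor_table if donor_table is not None \
        else _load_table("hbond_chemistry.csv")
    donors = _role_atoms(ensemble, chem, "donor")
    acceptors = _role_atoms(ensemble, chem, "acceptor")
    if donors.size == 0 or acceptors.size == 0:
        return []
    hydrogens = _attached_hydrogens(ensemble, donors)
    live_donors = np.array([d for d in donors if hydrogens[int(d)]],
                           dtype=int)
    if live_donors.size == 0:
        raise EmptyInputError(
            "no donor hydrogens found: add explicit hydrogens within 1.3 A "
            "of donor heavy atoms, or pass a donor_table with hydrogen "
            "positions"
        )
    res_of = np.array([a.residue_index for a in ensemble.atoms])
    traces: dict[tuple[int, int], np.ndarray] = {}
    n_frames = ensemble.n_frames
    for f in range(n_frames):
        coords = ensemble.frames[f]
        dtree = cKDTree(coords[live_donors])
        atree = cKDTree(coords[acceptors])
        for di, ais in enumerate(dtree.query_ball_tree(atree, d_cut)):
            d = int(live_donors[di])
            for ai in ais:
                a = int(acceptors[ai])
                if res_of[d] == res_of[a]:
                    continue
                best = 0.0
                for h in hydrogens[d]:
                    v1 = coords[d] - coords[h]
                    v2 = coords[a] - coords[h]
                    cosang = np.dot(v1, v2) / (
                        np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                    best = max(best, ang)
                if best >= angle_cut:
                    key = (d, a)
                    if key not in traces:
                        traces[key] = np.zeros(n_frames, dtype=bool)
                    traces[key][f] = True
    events = [
        BondEvent(kind="hbond", res_a=int(res_of[d]),
                  atom_a=ensemble.atoms[d].name, res_b=int(res_of[a]),
                  atom_b=ensemble.atoms[a].name, trace=tr)
        for (d, a), tr in sorted(traces.items())
    ]
    return events


def detect_saltbridges(ensemble: EnsembleModel, d_cut: float = 4.0
                       ) -> list[BondEvent]:
    """Salt bridges at residue-pair level: present in a frame iff any
    basic-N to acidic-O distance is <= d_cut (inclusive)."""
    chem = _load_table("saltbridge_chemistry.csv")
    basic = _role_atoms(ensemble, chem, "basic")
    acidic = _role_atoms(ensemble, chem, "acidic")
    if basic.size == 0 or acidic.size == 0:
        return []
    res_of = np.array([a.residue_index for a in ensemble.atoms])
    n_frames = ensemble.n_frames
    traces: dict[tuple[int, int], np.ndarray] = {}
    atom_pair: dict[tuple[int, int], tuple[str, str]] = {}
    for f in range(n_frames):
        coords = ensemble.frames[f]
        btree = cKDTree(coords[basic])
        atree = cKDTree(coords[acidic])
        for bi, ais in enumerate(btree.query_ball_tree(atree, d_cut)):
            b = int(basic[bi])
            for ai in ais:
                a = int(acidic[ai])
                if res_of[b] == res_of[a]:
                    continue
                key = (int(res_of[b]), int(res_of[a]))
                if key not in traces:
                    traces[key] = np.zeros(n_frames, dtype=bool)
                    atom_pair[key] = (ensemble.atoms[b].name,
                                      ensemble.atoms[a].name)
                traces[key][f] = True
    return [
        BondEvent(kind="saltbridge", res_a=rb, atom_a=atom_pair[(rb, ra)][0],
                  res_b=ra, atom_b=atom_pair[(rb, ra)][1], trace=tr)
        for (rb, ra), tr in sorted(traces.items())
    ]


# ---------------------------------------------------------------------------
# Persistence rules
# ---------------------------------------------------------------------------

def average_equivalent(events: list[BondEvent],
                       table: pd.DataFrame | None = None) -> list[BondEvent]:
    """Merge events identical up to a within-class equivalent-atom swap.

    The merged persistence is the arithmetic mean of the merged events'
    persistences; the merged trace is the frame-wise OR (used only for
    classification).  Idempotent: merged class labels are not in the table.
    """
    table = table if table is not None else _load_table("equivalent_atoms.csv")
    class_of = {(r, a): c for r, a, c in
                zip(table["residue"], table["atom"], table["class"])}

    def canon(event: BondEvent, atom: str) -> str:
        # residue names are not carried on events; equivalence classes are
        # keyed by atom name (unique across the bundled residue chemistry)
        for (_, a), c in class_of.items():
            if a == atom:
                return c
        return atom

    groups: dict[tuple, list[BondEvent]] = {}
    for e in events:
        key = (e.kind, e.res_a, canon(e, e.atom_a), e.res_b,
               canon(e, e.atom_b))
        groups.setdefault(key, []).append(e)
    merged = []
    for (kind, ra, ca, rb, cb), members in groups.items():
        if len(members) == 1:
            merged.append(members[0])
            continue
        trace = np.zeros_like(members[0].trace)
        for m in members:
            trace = trace | m.trace
        persistence = float(np.mean([m.persistence for m in members]))
        merged.append(BondEvent(
            kind=kind, res_a=ra, atom_a=ca, res_b=rb, atom_b=cb,
            trace=trace, persistence=persistence,
            merged_atoms=tuple(sorted(
                {m.atom_a for m in members} | {m.atom_b for m in members})),
        ))
    merged.sort(key=lambda e: (e.kind, e.res_a, e.res_b, e.atom_a, e.atom_b))
    return merged


def persistence_filter(events: list[BondEvent], retain: float = 0.05,
                       flag: float = 0.20,
                       equivalence_table: pd.DataFrame | None = None
                       ) -> PersistenceTable:
    """Equivalence-average, then drop bonds persisting < retain ("at least
    5% of the simulation time" is inclusive) and flag those persisting
    > flag (">20% of trajectory frames" is strict)."""
    if not 0.0 <= retain <= 1.0 or not 0.0 <= flag <= 1.0:
        raise ParameterError("thresholds must lie in [0, 1]")
    lengths = {e.trace.size for e in events}
    if len(lengths) > 1:
        raise ParameterError("bond traces have mismatched lengths")
    averaged = average_equivalent(events, table=equivalence_table)
    kept = []
    for e in averaged:
        if e.persistence >= retain - 1e-12:
            e.flagged = e.persistence > flag
            kept.append(e)
    return PersistenceTable(bonds=kept, retain_threshold=retain,
                            flag_threshold=flag)


def count_intradomain_hbonds(ensemble: EnsembleModel,
                             partition: DomainPartition | None = None,
                             d_cut: float = 3.0, angle_cut: float = 160.0
                             ) -> dict[str, tuple[float, float]]:
    """Per-domain mean +/- SD (over frames) of the number of hydrogen bonds
    whose donor and acceptor residues share the domain."""
    partition = partition or ensemble.partition
    if partition is None:
        raise ParameterError("no domain partition available")
    events = detect_hbonds(ensemble, d_cut=d_cut, angle_cut=angle_cut)
    counts = {name: np.zeros(ensemble.n_frames) for name in partition.names}
    for e in events:
        e.classify(partition)
        if e.classification == "intra" and e.domain_a in counts:
            counts[e.domain_a] += e.trace
    return {name: (float(c.mean()), float(c.std(ddof=0)))
            for name, c in counts.items()}
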