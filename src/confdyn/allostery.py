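"""Contact-topology networks, Markov hit/commute times, commute-weighted
shortest communication pathways and hotspot conservation.

The Cα contact topology is encoded by a Kirchhoff (graph Laplacian) matrix
as in a Gaussian network model.  A discrete random walk with transition
matrix P = D^-1 A gives first-passage (hit) times H(i->j); the commute time
C(i, j) = H(i->j) + H(j->i) serves as an allosteric communication distance
and weights the contact edges.  Loopless k-shortest paths between residue
sets, ranked by total commute time, are the communication pathways;
residues recurring in the top pathways across cluster representatives are
the communication hotspots.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import networkx as nx
import numpy as np

from .core import EnsembleModel
from .errors import ConfdynError, ParameterError, SelectionError


@dataclass
class ContactNetwork:
    kirchhoff: np.ndarray           # Gamma: degree on diagonal, -1 contacts
    cutoff: float
    nodes: list[int]                # residue indices, aligned with matrix

    def __post_init__(self) -> None:
        g = np.asarray(self.kirchhoff, dtype=float)
        if np.any(np.abs(g.sum(axis=1)) > 1e-9):
            raise ParameterError("Kirchhoff rows must sum to zero")
        off = g[~np.eye(g.shape[0], dtype=bool)]
        if not np.all(np.isin(off, (0.0, -1.0))):
            raise ParameterError("off-diagonal entries must be 0 or -1")
        self.kirchhoff = g

    @property
    def adjacency(self) -> np.ndarray:
        return -(self.kirchhoff - np.diag(np.diag(self.kirchhoff)))


@dataclass
class CommuteGraph:
    hit_times: np.ndarray           # H[i, j] = expected steps i -> j
    commute_times: np.ndarray       # C = H + H.T
    edges: list[tuple[int, int, float]]  # contact pairs weighted by C
    nodes: list[int]


@dataclass
class PathwaySet:
    pathways: list[tuple[list[int], float]]  # (node sequence, total commute)
    source_set: set[int]
    target_set: set[int]
    k: int
    hotspot_residues: list[tuple[int, int]] = field(default_factory=list)


def build_network(ensemble_or_coords, selection: Sequence[int] | None = None,
                  cutoff: float = 10.0, frame: int = 0) -> ContactNetwork:
    """Cα contact Kirchhoff matrix: contact iff Cα-Cα distance <= cutoff.

    Raises on a disconnected graph (naming the components), since the
    Markov machinery downstream requires connectivity.
    """
    if cutoff <= 0:
        raise ParameterError("cutoff must be positive")
    if isinstance(ensemble_or_coords, EnsembleModel):
        idx = ensemble_or_coords.ca_indices(selection)
        coords = ensemble_or_coords.frames[frame, idx, :]
        nodes = [ensemble_or_coords.atoms[i].residue_index for i in idx]
    else:
        coords = np.asarray(ensemble_or_coords, dtype=float)
        nodes = list(range(coords.shape[0]))
    n = coords.shape[0]
    if n < 2:
        raise SelectionError("need at least 2 residues")
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt(np.sum(diff * diff, axis=2))
    adj = (dist <= cutoff) & ~np.eye(n, dtype=bool)
    kirchhoff = np.diag(adj.sum(axis=1)).astype(float) - adj.astype(float)
    g = nx.from_numpy_array(adj.astype(int))
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        named = [sorted(nodes[i] for i in c) for c in comps]
        raise ConfdynError(
            f"contact graph is disconnected at cutoff {cutoff} A; "
            f"components: {[c[:5] for c in named]}"
        )
    return ContactNetwork(kirchhoff=kirchhoff, cutoff=cutoff, nodes=nodes)


def markov_times(network: ContactNetwork) -> CommuteGraph:
    """Hit and commute times of the unbiased random walk P = D^-1 A.

    H(i->j) solves the first-passage system h_j = 0,
    h_i = 1 + sum_k P_ik h_k (one dense solve per target)."""
    adj = network.adjacency
    deg = adj.sum(axis=1)
    n = adj.shape[0]
    P = adj / deg[:, None]
    H = np.zeros((n, n))
    eye = np.eye(n - 1)
    for j in range(n):
        keep = np.array([i for i in range(n) if i != j])
        A = eye - P[np.ix_(keep, keep)]
        try:
            h = np.linalg.solve(A, np.ones(n - 1))
        except np.linalg.LinAlgError as exc:  # pragma: no cover
            raise ConfdynError(
                f"singular first-passage system for target {j}"
            ) from exc
        H[keep, j] = h
    C = H + H.T
    edges = [(i, j, float(C[i, j]))
             for i in range(n) for j in range(i + 1, n) if adj[i, j]]
    return CommuteGraph(hit_times=H, commute_times=C, edges=edges,
                        nodes=network.nodes)


def _graph_from_commute(cg: CommuteGraph) -> nx.Graph:
    g = nx.Graph()
    g.add_nodes_from(range(len(cg.nodes)))
    for i, j, w in cg.edges:
        g.add_edge(i, j, weight=w)
    return g


def shortest_pathways(cg: CommuteGraph, source_set: Sequence[int],
                      target_set: Sequence[int], k: int = 15) -> PathwaySet:
    """Globally k shortest loopless commute-weighted paths from any source
    to any target (node ids are positions in cg.nodes).

    Per source-target pair the top k loopless paths are enumerated (Yen),
    then merged and ranked by (total commute time, node sequence) for a
    deterministic order.  Fewer than k simple paths is not an error.
    """
    source = set(int(s) for s in source_set)
    target = set(int(t) for t in target_set)
    if not source or not target:
        raise ParameterError("source and target sets must be nonempty")
    if source & target:
        raise ParameterError("source and target sets overlap")
    if k < 1:
        raise ParameterError("k must be >= 1")
    g = _graph_from_commute(cg)

    def weigh(path: list[int]) -> float:
        return float(sum(g[a][b]["weight"]
                         for a, b in zip(path[:-1], path[1:])))

    # lazy k-way merge over per-pair Yen generators: each generator yields
    # loopless paths in non-decreasing weight, so popping the global heap k
    # times gives the global top-k while expanding only what is needed
    import heapq

    heap: list[tuple[float, tuple[int, ...], int, object]] = []
    gens = []
    for s, t in product(sorted(source), sorted(target)):
        gen = nx.shortest_simple_paths(g, s, t, weight="weight")
        try:
            path = next(gen)
        except nx.NetworkXNoPath:  # pragma: no cover - graph is connected
            continue
        gens.append(gen)
        heapq.heappush(heap, (weigh(path), tuple(path), len(gens) - 1, gen))

    def drain_ties(wmin: float, drained: dict[int, float]) -> None:
        # Yen yields non-decreasing weights, but the lexicographically
        # smallest path at the current weight level may not be generated
        # yet: pull every generator sitting at wmin past that level first
        for entry in list(heap):
            w, _, gid, gen = entry
            if w != wmin or drained.get(gid) == wmin:
                continue
            drained[gid] = wmin
            while True:
                try:
                    nxt = next(gen)
                except StopIteration:
                    break
                wn = weigh(nxt)
                heapq.heappush(heap, (wn, tuple(nxt), gid, gen))
                if wn > wmin:
                    break

    top: list[tuple[list[int], float]] = []
    exhausted: dict[int, float] = {}
    while heap and len(top) < k:
        drain_ties(heap[0][0], exhausted)
        w, path, gid, gen = heapq.heappop(heap)
        top.append((list(path), w))
        if exhausted.get(gid) != w:
            try:
                nxt = next(gen)
            except StopIteration:
                continue
            heapq.heappush(heap, (weigh(nxt), tuple(nxt), gid, gen))
    return PathwaySet(pathways=top, source_set=source, target_set=target,
                      k=k)


def hotspot_conservation(pathway_sets: dict[str, list[PathwaySet]],
                         top_n: int = 15,
                         populations: dict[str, list[float]] | None = None
                         ) -> dict:
    """Hotspot ranking per condition and the cross-condition overlap.

    A residue's score is the number of top-k pathways (across the
    condition's representatives) containing it, endpoints excluded.
    Returns per-condition ranked hotspots (top_n), pairwise overlap sizes
    of the hotspot sets, and mean total commute time of the pathways as a
    communication-efficiency summary.
    """
    if not pathway_sets or any(not v for v in pathway_sets.values()):
        raise ParameterError("each condition needs at least one pathway set")
    if populations is not None:
        for cond, pops in populations.items():
            if sum(pops) < 0.8:
                raise ParameterError(
                    f"{cond}: representatives cover {sum(pops):.2f} < 0.80 "
                    "of the population"
                )
    hotspots = {}
    efficiency = {}
    for cond, sets in pathway_sets.items():
        scores: dict[int, int] = {}
        weights = []
        for ps in sets:
            for path, w in ps.pathways:
                weights.append(w)
                for node in path[1:-1]:
                    scores[node] = scores.get(node, 0) + 1
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        hotspots[cond] = ranked[:top_n]
        efficiency[cond] = float(np.mean(weights)) if weights else np.nan
        for ps in sets:
            ps.hotspot_residues = ranked[:top_n]
    overlap = {}
    conds = list(pathway_sets)
    for i, a in enumerate(conds):
        for b in conds[i + 1:]:
            sa = {r for r, _ in hotspots[a]}
            sb = {r for r, _ in hotspots[b]}
            overlap[(a, b)] = len(sa & sb)
    return {"hotspots": hotspots, "overlap": overlap,
            "efficiency": efficiency, "top_n": top_n}
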