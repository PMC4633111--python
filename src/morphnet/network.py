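"""Binarization, graph metrics, degree-preserving null models, hubs.

Similarity matrices are binarized at a sparsity threshold S (fraction of
realized edges over all possible pairs), then standard binary undirected
graph metrics are computed: clustering coefficient Cp, characteristic
path length Lp, betweenness B_i, global/local efficiency, and the
small-world ratios gamma = Cp/Cp_rand, lambda = Lp/Lp_rand,
sigma = gamma/lambda against an ensemble of degree-preserving rewired
reference graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import shortest_path

from morphnet.similarity import SimilarityMatrix

DEFAULT_N_RANDOM = 100
DEFAULT_SWAPS_PER_EDGE = 10

#: names of the global metrics, in reporting order
GLOBAL_METRIC_NAMES = ("Cp", "Lp", "gamma", "lambda", "sigma", "Eg", "Eloc", "meanBet")


class DisconnectedGraphWarning(UserWarning):
    """Some node pairs are unreachable; Lp averaged over reachable pairs."""


class RewiringStallWarning(UserWarning):
    """Edge rewiring achieved fewer swaps than requested."""


@dataclass
class AdjacencyMatrix:
    """Binary symmetric adjacency with zero diagonal at sparsity S."""

    a: np.ndarray
    sparsity: float
    region_ids: list[int] = field(default_factory=list)
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a)
        if self.a.ndim != 2 or self.a.shape[0] != self.a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(self.a, self.a.T):
            raise ValueError("adjacency must be symmetric")
        if np.diag(self.a).any():
            raise ValueError("adjacency diagonal must be zero")
        if not np.isin(self.a, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        self.a = self.a.astype(np.int8)
        if not self.region_ids:
            self.region_ids = list(range(self.a.shape[0]))

    @property
    def n_nodes(self) -> int:
        return self.a.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.a.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.a.sum(axis=1).astype(int)

    def to_graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.a)
        g.add_nodes_from(range(self.n_nodes))
        return g

    def edge_list(self) -> list[tuple[int, int]]:
        iu = np.triu_indices(self.n_nodes, k=1)
        mask = self.a[iu] == 1
        return list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))


@dataclass
class NodalMetrics:
    """Per-node centrality values for one binarized network."""

    betweenness: np.ndarray          # raw B_i
    normalized_betweenness: np.ndarray  # b_i = B_i / meanBet (NaN if meanBet == 0)
    degree: np.ndarray
    clustering: np.ndarray
    mean_betweenness: float


@dataclass
class GlobalMetrics:
    """Whole-network metrics including null-normalized small-world ratios."""

    Cp: float
    Lp: float
    Eg: float
    Eloc: float
    meanBet: float
    Cp_rand: float
    Lp_rand: float
    gamma: float
    lambda_: float
    sigma: float
    n_random: int
    connected: bool = True

    def as_dict(self) -> dict[str, float]:
        return {
            "Cp": self.Cp,
            "Lp": self.Lp,
            "gamma": self.gamma,
            "lambda": self.lambda_,
            "sigma": self.sigma,
            "Eg": self.Eg,
            "Eloc": self.Eloc,
            "meanBet": self.meanBet,
        }


@dataclass
class ProfileScores:
    """Cross-subject similarity/uniqueness of betweenness profiles."""

    similarity_raw: np.ndarray   # in [-1, 1]
    uniqueness_raw: np.ndarray   # in [0, 2]
    similarity: np.ndarray       # rescaled to [0, 1]
    uniqueness: np.ndarray       # rescaled to [0, 1]
    n_subjects: int


def binarize_by_sparsity(
    similarity: SimilarityMatrix | np.ndarray,
    sparsity: float,
    region_ids: Sequence[int] | None = None,
    subject_id: str = "",
) -> AdjacencyMatrix:
    """Keep the top ``round(S * R(R-1)/2)`` strongest pairs as edges.

    The threshold is subject-specific by construction: every subject's
    network ends up with the identical edge count at a given S.  Ties at
    the cutoff are broken by lexicographic (i, j) pair order so results
    are deterministic.
    """
    if isinstance(similarity, SimilarityMatrix):
        entries = similarity.entries
        region_ids = similarity.region_ids
        subject_id = subject_id or similarity.subject_id
    else:
        entries = np.asarray(similarity, dtype=float)
    if not 0 < sparsity < 1:
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    r = entries.shape[0]
    n_pairs = r * (r - 1) // 2
    k = int(round(sparsity * n_pairs))
    if k <= 0:
        raise ValueError(f"sparsity {sparsity} keeps 0 edges; degenerate network")
    if k >= n_pairs:
        raise ValueError(f"sparsity {sparsity} keeps all {n_pairs} pairs; degenerate network")
    iu = np.triu_indices(r, k=1)
    vals = entries[iu]
    if not np.isfinite(vals).all():
        raise ValueError("off-diagonal similarity values must be finite")
    # stable sort on -value keeps lexicographic (i, j) order among ties
    order = np.argsort(-vals, kind="stable")[:k]
    a = np.zeros((r, r), dtype=np.int8)
    a[iu[0][order], iu[1][order]] = 1
    a |= a.T
    return AdjacencyMatrix(
        a=a,
        sparsity=sparsity,
        region_ids=list(region_ids) if region_ids is not None else [],
        subject_id=subject_id,
    )


def _as_adjacency(adj: AdjacencyMatrix | np.ndarray) -> np.ndarray:
    if isinstance(adj, AdjacencyMatrix):
        return adj.a
    return AdjacencyMatrix(a=np.asarray(adj), sparsity=0.5).a


def _distance_matrix(a: np.ndarray) -> np.ndarray:
    return shortest_path(csr_array(a.astype(np.int8)), method="D", unweighted=True)


def clustering_coefficient(adj: AdjacencyMatrix | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering (neighbor pairs that are themselves linked) and mean Cp.

    Nodes with degree < 2 contribute 0.
    """
    a = _as_adjacency(adj).astype(np.int64)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    possible = deg * (deg - 1) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        cc = np.where(possible > 0, triangles / possible, 0.0)
    return cc, float(cc.mean())


def characteristic_path_length(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean shortest-path distance over all reachable unordered pairs.

    Emits DisconnectedGraphWarning if any pair is unreachable (the mean
    is then over reachable pairs only).  Raises for an edgeless graph.
    """
    a = _as_adjacency(adj)
    if a.sum() == 0:
        raise ValueError("graph has no edges; path length undefined")
    d = _distance_matrix(a)
    iu = np.triu_indices(a.shape[0], k=1)
    dv = d[iu]
    finite = np.isfinite(dv)
    if not finite.all():
        warnings.warn(
            f"graph is disconnected: {int((~finite).sum())} of {dv.size} pairs unreachable; "
            "Lp averaged over reachable pairs",
            DisconnectedGraphWarning,
            stacklevel=2,
        )
    return float(dv[finite].mean())


def betweenness_normalized(adj: AdjacencyMatrix | np.ndarray) -> NodalMetrics:
    """Betweenness B_i (fractional shortest-path counting, endpoints
    excluded) and b_i = B_i / meanBet; b_i is NaN when meanBet is 0."""
    a = _as_adjacency(adj)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=False)
    b = np.array([bc[i] for i in range(a.shape[0])], dtype=float)
    mean_bet = float(b.mean())
    if mean_bet > 0:
        b_norm = b / mean_bet
    else:
        b_norm = np.full_like(b, np.nan)
    cc, _ = clustering_coefficient(a)
    return NodalMetrics(
        betweenness=b,
        normalized_betweenness=b_norm,
        degree=a.sum(axis=1).astype(int),
        clustering=cc,
        mean_betweenness=mean_bet,
    )


def global_efficiency(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean inverse shortest-path length over all pairs (1/inf = 0)."""
    a = _as_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        return 0.0
    d = _distance_matrix(a)
    iu = np.triu_indices(n, k=1)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d[iu]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def local_efficiency(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean over nodes of the global efficiency of each node's
    neighbor-induced subgraph (0 for nodes with < 2 neighbors)."""
    a = _as_adjacency(adj)
    effs = np.zeros(a.shape[0])
    for i in range(a.shape[0]):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        effs[i] = global_efficiency(a[np.ix_(nb, nb)])
    return float(effs.mean())


def maslov_random_reference(
    adj: AdjacencyMatrix | np.ndarray,
    seed: int | np.random.Generator = 0,
    n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> AdjacencyMatrix:
    """Degree-preserving random rewiring (repeated double-edge swaps).

    Attempts ``n_swaps_per_edge * n_edges`` swaps; each picks two edges
    (a, b), (c, d) with four distinct endpoints and replaces them with
    (a, d), (c, b) when neither new edge already exists.  The degree
    sequence, edge count and node count are preserved exactly.  Warns if
    no swap could be applied.
    """
    a = _as_adjacency(adj).copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu = np.triu_indices(a.shape[0], k=1)
    mask = a[iu] == 1
    edges = list(zip(iu[0][mask].tolist(), iu[1][mask].tolist()))
    m = len(edges)
    if m < 2:
        raise ValueError("need at least 2 edges to rewire")
    edge_set = set(edges)
    attempts = n_swaps_per_edge * m
    picks = rng.integers(0, m, size=(attempts, 2))
    flips = rng.random(attempts) < 0.5
    successes = 0
    for t in range(attempts):
        e1, e2 = picks[t]
        if e1 == e2:
            continue
        a1, b1 = edges[e1]
        c1, d1 = edges[e2]
        if flips[t]:
            c1, d1 = d1, c1
        if len({a1, b1, c1, d1}) < 4:
            continue
        new1 = (a1, d1) if a1 < d1 else (d1, a1)
        new2 = (c1, b1) if c1 < b1 else (b1, c1)
        if new1 in edge_set or new2 in edge_set:
            continue
        edge_set.discard(edges[e1])
        edge_set.discard(edges[e2])
        edge_set.add(new1)
        edge_set.add(new2)
        edges[e1] = new1
        edges[e2] = new2
        successes += 1
    if successes == 0 and attempts > 0:
        warnings.warn(
            f"rewiring achieved 0 of {attempts} attempted swaps (rigid graph?)",
            RewiringStallWarning,
            stacklevel=2,
        )
    out = np.zeros_like(a)
    idx = np.array(list(edge_set), dtype=int)
    out[idx[:, 0], idx[:, 1]] = 1
    out |= out.T
    sparsity = adj.sparsity if isinstance(adj, AdjacencyMatrix) else m / (
        a.shape[0] * (a.shape[0] - 1) / 2
    )
    region_ids = adj.region_ids if isinstance(adj, AdjacencyMatrix) else None
    return AdjacencyMatrix(
        a=out,
        sparsity=float(sparsity),
        region_ids=list(region_ids) if region_ids else [],
    )


def small_world_metrics(
    adj: AdjacencyMatrix | np.ndarray,
    n_random: int = DEFAULT_N_RANDOM,
    seed: int = 0,
    n_swaps_per_edge: int = DEFAULT_SWAPS_PER_EDGE,
) -> GlobalMetrics:
    """All global metrics plus gamma/lambda/sigma against a rewired ensemble.

    ``Cp_rand`` and ``Lp_rand`` are means over ``n_random`` degree-
    preserving references generated with per-replicate child seeds of
    ``seed``.
    """
    if n_random < 1:
        raise ValueError("n_random must be >= 1")
    a = _as_adjacency(adj)
    cp = clustering_coefficient(a)[1]
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", DisconnectedGraphWarning)
        lp = characteristic_path_length(a)
        connected = not any(issubclass(w.category, DisconnectedGraphWarning) for w in caught)
    if not connected:
        warnings.warn(
            "input graph is disconnected; Lp uses reachable pairs",
            DisconnectedGraphWarning,
            stacklevel=2,
        )
    eg = global_efficiency(a)
    eloc = local_efficiency(a)
    nodal = betweenness_normalized(a)
    child_seeds = np.random.SeedSequence(seed).spawn(n_random)
    cp_rands = np.empty(n_random)
    lp_rands = np.empty(n_random)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DisconnectedGraphWarning)
        warnings.simplefilter("ignore", RewiringStallWarning)
        for i, cs in enumerate(child_seeds):
            ref = maslov_random_reference(
                a, seed=np.random.default_rng(cs), n_swaps_per_edge=n_swaps_per_edge
            )
            cp_rands[i] = clustering_coefficient(ref.a)[1]
            lp_rands[i] = characteristic_path_length(ref.a)
    cp_rand = float(cp_rands.mean())
    lp_rand = float(lp_rands.mean())
    if lp_rand <= 0:
        raise ArithmeticError("null ensemble produced non-positive Lp_rand")
    lam = lp / lp_rand
    if cp_rand > 0:
        gamma = cp / cp_rand
    else:
        # triangle-free null ensemble (tiny/sparse graphs): gamma undefined
        warnings.warn(
            "null ensemble has zero clustering; gamma and sigma undefined",
            UserWarning,
            stacklevel=2,
        )
        gamma = np.nan
    return GlobalMetrics(
        Cp=cp,
        Lp=lp,
        Eg=eg,
        Eloc=eloc,
        meanBet=nodal.mean_betweenness,
        Cp_rand=cp_rand,
        Lp_rand=lp_rand,
        gamma=gamma,
        lambda_=lam,
        sigma=gamma / lam,
        n_random=n_random,
        connected=connected,
    )


def identify_hubs(
    normalized_betweenness: np.ndarray,
    region_ids: Sequence[int] | None = None,
) -> tuple[list[int], np.ndarray, float]:
    """Hubs: nodes whose cross-subject mean b_i exceeds mean + 1 sample SD.

    Parameters
    ----------
    normalized_betweenness
        Array of shape (n_subjects, n_nodes) of b_i values (a single
        profile may be passed as shape (n_nodes,)).

    Returns (hub indices into region order, per-node mean b, threshold).
    """
    b = np.atleast_2d(np.asarray(normalized_betweenness, dtype=float))
    if b.shape[1] < 2:
        raise ValueError("hub identification needs more than one node")
    mean_b = b.mean(axis=0)
    sd = float(np.std(mean_b, ddof=1))
    # zero SD (all nodes equal) leaves threshold = mean, so no node exceeds it
    threshold = float(mean_b.mean()) + sd
    hub_idx = np.flatnonzero(mean_b > threshold)
    if region_ids is not None:
        hubs = [int(region_ids[i]) for i in hub_idx]
    else:
        hubs = hub_idx.tolist()
    return hubs, mean_b, threshold


def profile_similarity_uniqueness(profiles: np.ndarray) -> ProfileScores:
    """Cross-subject similarity/uniqueness of betweenness profiles.

    For subject m: raw similarity = mean Pearson correlation of that
    subject's node profile with every other subject's; raw uniqueness =
    1 - max correlation with others.  Raw scores span [-1, 1] and [0, 2]
    and are rescaled to [0, 1] as (s + 1)/2 and u/2.
    """
    p = np.asarray(profiles, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("need at least 2 equal-length profiles")
    sds = p.std(axis=1)
    for m in np.flatnonzero(sds == 0):
        raise ValueError(f"profile of subject index {m} has zero variance")
    corr = np.corrcoef(p)
    n = p.shape[0]
    off = corr[~np.eye(n, dtype=bool)].reshape(n, n - 1)
    sim_raw = off.mean(axis=1)
    uniq_raw = 1.0 - off.max(axis=1)
    return ProfileScores(
        similarity_raw=sim_raw,
        uniqueness_raw=uniq_raw,
        similarity=(sim_raw + 1.0) / 2.0,
        uniqueness=uniq_raw / 2.0,
        n_subjects=n,
    )
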