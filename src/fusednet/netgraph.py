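"""Network construction and graph-theoretic characterization.

A PLI connectivity matrix is binarized at a threshold chosen so that the
resulting graph keeps a mean degree above 2 ln K (K = 68 nodes) and a
small-world index above 1; edges whose PLI differs between the two task
conditions (paired t-test, Benjamini-Hochberg FDR at q = 0.05 across the
K(K-1)/2 = 2278 edges) are retained; and the surviving graph is summarized
by unnormalized shortest-path betweenness centrality, network density
D = 2M / (K(K-1)), and the small-world index sigma relative to
degree-preserving rewired surrogates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BinaryNetwork",
    "EdgeStats",
    "NodeMetrics",
    "NetworkSummary",
    "ThresholdSelectionError",
    "binarize",
    "select_threshold",
    "paired_edge_ttest",
    "significant_network",
    "betweenness",
    "density",
    "small_world_sigma",
    "network_summary",
]


@dataclass(frozen=True)
class BinaryNetwork:
    """Undirected simple graph as a boolean adjacency matrix."""

    adjacency: np.ndarray
    threshold: float | None = None

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency, dtype=bool)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric (undirected)")
        if np.any(np.diag(a)):
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "adjacency", a)

    @property
    def K(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def to_networkx(self) -> nx.Graph:
        return nx.from_numpy_array(self.adjacency.astype(int))


def _pli_values(pli) -> np.ndarray:
    from .roiconn import PLIMatrix

    return pli.values if isinstance(pli, PLIMatrix) else np.asarray(pli, dtype=float)


def binarize(pli, threshold: float) -> BinaryNetwork:
    """Edge wherever the off-diagonal PLI value is >= threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    v = _pli_values(pli)
    adj = v >= threshold
    np.fill_diagonal(adj, False)
    adj = adj & adj.T
    return BinaryNetwork(adjacency=adj, threshold=float(threshold))


class ThresholdSelectionError(RuntimeError):
    """No grid threshold satisfied both network criteria; carries the
    per-threshold diagnostics table in ``.diagnostics``."""

    def __init__(self, message: str, diagnostics: pd.DataFrame):
        super().__init__(message)
        self.diagnostics = diagnostics


def select_threshold(
    group_mean_pli,
    grid: np.ndarray | None = None,
    n_random: int = 20,
    seed: int = 0,
) -> float:
    """Largest grid threshold whose binarized graph has mean degree
    > 2 ln K and small-world index > 1, both evaluated on the group-mean
    PLI matrix.

    The grid defaults to 0.01 ... 0.99 in steps of 0.01 and is scanned from
    the top; the degree criterion is checked first (cheap) and the
    small-world index only for degree-passing candidates.
    """
    v = _pli_values(group_mean_pli)
    K = v.shape[0]
    if grid is None:
        grid = np.round(np.arange(1, 100) * 0.01, 2)
    degree_target = 2.0 * np.log(K)
    rows = []
    for thr in sorted(np.asarray(grid, dtype=float), reverse=True):
        net = binarize(v, thr)
        mean_degree = 2.0 * net.n_edges / K
        deg_ok = mean_degree > degree_target
        sigma = None
        sw_ok = False
        note = ""
        if deg_ok:
            try:
                sigma = small_world_sigma(net, n_random=n_random, seed=seed)
                sw_ok = sigma > 1.0
            except (ValueError, RuntimeError) as exc:
                note = str(exc)
        rows.append(
            {
                "threshold": thr,
                "mean_degree": mean_degree,
                "degree_ok": deg_ok,
                "sigma": sigma,
                "small_world_ok": sw_ok,
                "note": note,
            }
        )
        if deg_ok and sw_ok:
            return float(thr)
    diag = pd.DataFrame(rows)
    raise ThresholdSelectionError(
        f"no threshold satisfied mean degree > {degree_target:.2f} and sigma > 1; "
        f"diagnostics:\n{diag.to_string(index=False)}",
        diag,
    )


@dataclass(frozen=True)
class EdgeStats:
    """Edge-wise paired t-test with BH-FDR across all K(K-1)/2 edges."""

    t: np.ndarray  # per edge, condensed upper-triangle order
    p: np.ndarray  # two-sided
    q_threshold: float
    dof: int
    significant: np.ndarray  # boolean per edge (BH-rejected)
    K: int
    zero_variance: np.ndarray = field(default=None)  # type: ignore[assignment]

    def _to_matrix(self, vec: np.ndarray, fill=0.0) -> np.ndarray:
        out = np.full((self.K, self.K), fill, dtype=vec.dtype)
        iu = np.triu_indices(self.K, k=1)
        out[iu] = vec
        out.T[iu] = vec
        return out

    def significant_matrix(self) -> np.ndarray:
        return self._to_matrix(self.significant, fill=False)

    def t_matrix(self) -> np.ndarray:
        return self._to_matrix(self.t)

    def p_matrix(self) -> np.ndarray:
        return self._to_matrix(self.p, fill=1.0)


def _stack_triu(matrices, K: int) -> np.ndarray:
    iu = np.triu_indices(K, k=1)
    return np.stack([_pli_values(m)[iu] for m in matrices])


def paired_edge_ttest(pli_cond_a, pli_cond_b, q: float = 0.05) -> EdgeStats:
    """Two-sided paired t-test on every edge's PLI across subjects,
    Benjamini-Hochberg corrected at level ``q``.

    ``pli_cond_a`` / ``pli_cond_b`` are same-length sequences of per-subject
    PLI matrices (matched order).  Edges with zero within-pair variance get
    t = 0, p = 1 and are flagged in ``zero_variance``.
    """
    if len(pli_cond_a) != len(pli_cond_b):
        raise ValueError("conditions must have the same subjects")
    n = len(pli_cond_a)
    if n < 3:
        raise ValueError("need at least 3 subjects for a paired t-test")
    K = _pli_values(pli_cond_a[0]).shape[0]
    a = _stack_triu(pli_cond_a, K)  # (n, E)
    b = _stack_triu(pli_cond_b, K)
    diff = a - b
    sd = diff.std(axis=0, ddof=1)
    zero_var = sd == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(zero_var, 0.0, diff.mean(axis=0) / (sd / np.sqrt(n)))
    dof = n - 1
    p = np.where(zero_var, 1.0, 2.0 * stats.t.sf(np.abs(t), df=dof))
    reject, _, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return EdgeStats(
        t=t, p=p, q_threshold=q, dof=dof, significant=reject, K=K,
        zero_variance=zero_var,
    )


def significant_network(binary: BinaryNetwork, edge_stats: EdgeStats) -> BinaryNetwork:
    """Keep the edges that are both above threshold and condition-different
    (elementwise conjunction)."""
    if binary.K != edge_stats.K:
        raise ValueError("network and edge statistics disagree on node count")
    adj = binary.adjacency & edge_stats.significant_matrix()
    return BinaryNetwork(adjacency=adj, threshold=binary.threshold)


@dataclass(frozen=True)
class NodeMetrics:
    """Per-node betweenness (unnormalized) and degree."""

    betweenness: np.ndarray
    degree: np.ndarray


def betweenness(net: BinaryNetwork) -> NodeMetrics:
    """Unnormalized shortest-path betweenness over unordered node pairs,
    B_i = sum over pairs {m, n} (m != i != n) of r_mn(i) / r_mn, where r_mn
    counts shortest m-n paths and r_mn(i) those passing through i.  Pairs in
    different components contribute 0.  Computed with Brandes' algorithm."""
    g = net.to_networkx()
    bc = nx.betweenness_centrality(g, normalized=False)
    deg = net.adjacency.sum(axis=0).astype(int)
    return NodeMetrics(
        betweenness=np.array([bc[i] for i in range(net.K)]), degree=deg
    )


def density(net: BinaryNetwork) -> float:
    """Network density D = 2M / (K(K-1))."""
    if net.K < 2:
        raise ValueError("density needs at least 2 nodes")
    return 2.0 * net.n_edges / (net.K * (net.K - 1))


def _mean_shortest_path(g: nx.Graph) -> float:
    """Mean shortest-path length over connected (reachable) node pairs."""
    total = 0.0
    count = 0
    for _, lengths in nx.all_pairs_shortest_path_length(g):
        for d in lengths.values():
            if d > 0:
                total += d
                count += 1
    if count == 0:
        raise ValueError("graph has no connected pairs")
    return total / count


def small_world_sigma(
    net: BinaryNetwork | nx.Graph,
    n_random: int = 20,
    seed: int = 0,
    swap_factor: int = 10,
) -> float:
    """Small-world index sigma = (C / C_rand) / (L / L_rand).

    C is the mean local clustering coefficient and L the mean shortest path
    over connected pairs, both on the largest connected component; C_rand and
    L_rand are means over ``n_random`` degree-preserving edge-rewired
    surrogates (``swap_factor * M`` swap attempts each, seeded).
    """
    g = net.to_networkx() if isinstance(net, BinaryNetwork) else net.copy()
    if g.number_of_nodes() == 0 or g.number_of_edges() == 0:
        raise ValueError("empty graph: small-world index undefined")
    comp = max(nx.connected_components(g), key=len)
    g = g.subgraph(comp).copy()
    m = g.number_of_edges()
    n = g.number_of_nodes()
    if m < n:
        raise ValueError(f"graph too sparse to rewire ({m} edges, {n} nodes)")
    if m == n * (n - 1) // 2:
        # complete graph: rewiring is a no-op, C = C_rand = 1, L = L_rand = 1
        return 1.0
    C = nx.average_clustering(g)
    L = _mean_shortest_path(g)
    rng = np.random.SeedSequence(seed).generate_state(n_random)
    c_rand, l_rand = [], []
    for s_i in rng:
        h = g.copy()
        try:
            nx.double_edge_swap(h, nswap=swap_factor * m,
                                max_tries=100 * swap_factor * m, seed=int(s_i))
        except nx.NetworkXException as exc:
            raise ValueError(f"degree-preserving rewiring failed: {exc}") from exc
        c_rand.append(nx.average_clustering(h))
        l_rand.append(_mean_shortest_path(h))
    c_bar = float(np.mean(c_rand))
    l_bar = float(np.mean(l_rand))
    if c_bar == 0 or L == 0:
        raise ValueError("degenerate surrogate statistics (zero clustering or path length)")
    return (C / c_bar) / (L / l_bar)


@dataclass(frozen=True)
class NetworkSummary:
    """Whole-network summary: density, edge count, mean degree, sigma."""

    density: float
    M_edges: int
    mean_degree: float
    small_world_sigma: float | None
    sigma_seed: int
    n_random: int
    sigma_note: str = ""


def network_summary(
    net: BinaryNetwork, n_random: int = 20, seed: int = 0
) -> NetworkSummary:
    """Density, mean degree and (where computable) the small-world index."""
    sigma = None
    note = ""
    try:
        sigma = small_world_sigma(net, n_random=n_random, seed=seed)
    except ValueError as exc:
        note = str(exc)
    return NetworkSummary(
        density=density(net),
        M_edges=net.n_edges,
        mean_degree=2.0 * net.n_edges / net.K,
        small_world_sigma=sigma,
        sigma_seed=seed,
        n_random=n_random,
        sigma_note=note,
    )
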