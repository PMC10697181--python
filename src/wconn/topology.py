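"""Weighted graph measures and their null-model normalization.

Conventions (the weighted-graph literature offers several; these are fixed
here and documented in the methods note):

* weights are max-normalized to (0, 1] before any transform, so the
  weight-to-length map L_ij = -log(W_ij) yields nonnegative lengths and the
  strongest edge has length zero; absent edges are infinitely long;
* clustering is the Onnela geometric-mean triangle intensity on the
  max-normalized weights (reduces to the binary triangle fraction when all
  weights are equal);
* betweenness and closeness run on the -log length graph;
* eigenvector centrality is the principal eigenvector of W by power
  iteration (tolerance 1e-10, at most 10^4 iterations);
* rich-club degree k always uses the binary map, and the weighted
  coefficient divides the weight inside the >k subgraph by the sum of the
  equally many strongest weights anywhere in the network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import csgraph_from_dense, dijkstra

from .core import ConsistencyError, WeightedConnectome
from .nulls import NullEnsemble

__all__ = [
    "weighted_clustering",
    "weight_to_length",
    "char_path_length",
    "SmallWorldReport",
    "small_worldness",
    "HubnessTable",
    "betweenness_closeness",
    "centrality_panel",
    "hubness_scores",
    "hubness_distance",
    "rich_club_binary",
    "rich_club_weighted",
    "RichClubCurve",
    "normalize_rich_club",
]

logger = logging.getLogger(__name__)


def weighted_clustering(net: WeightedConnectome) -> np.ndarray:
    """Per-node Onnela clustering coefficient on max-normalized weights.

    C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3),
    with w' = W / max(W).  Nodes with degree < 2 get 0.
    """
    w = net.matrix
    if np.any(w < 0):
        raise ConsistencyError("clustering requires nonnegative weights")
    mx = w.max()
    if mx == 0:
        return np.zeros(net.n_nodes)
    cbrt = np.cbrt(w / mx)
    num = np.diagonal(cbrt @ cbrt @ cbrt)
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(denom > 0, num / np.where(denom > 0, denom, 1), 0.0)


def weight_to_length(net: WeightedConnectome, normalize: bool = True) -> np.ndarray:
    """L_ij = -log(W_ij); absent edges become +inf.

    With ``normalize`` (default) weights are first divided by the maximum so
    they lie in (0, 1] and the strongest edge has length zero; pass
    ``normalize=False`` for weights already on that scale.  A network whose
    nonzero weights are all equal would map every edge to length zero; the
    continuous-limit semantics there is the hop count, so unit lengths are
    substituted (and logged).
    """
    w = net.matrix
    if np.any(w < 0):
        raise ConsistencyError("weight-to-length transform requires nonnegative weights")
    mx = w.max()
    if mx == 0:
        raise ConsistencyError("empty network has no length transform")
    nz = w > 0
    if normalize:
        wn = w / mx
    else:
        if mx > 1:
            raise ConsistencyError("normalize=False requires weights in (0, 1]")
        wn = w
    out = np.full_like(w, np.inf)
    out[nz] = -np.log(wn[nz])
    np.fill_diagonal(out, 0.0)
    off_nz = nz & ~np.eye(len(w), dtype=bool)
    if off_nz.any() and np.all(out[off_nz] == 0):
        logger.info("uniform-weight network: using hop-count path lengths")
        out[off_nz] = 1.0
    return out


def _shortest_paths(lengths: np.ndarray) -> np.ndarray:
    # inf marks absent edges; csgraph_from_dense keeps genuine zero-length
    # edges (the max-weight edge) that plain sparsification would drop
    g = lengths.copy()
    np.fill_diagonal(g, np.inf)
    graph = csgraph_from_dense(g, null_value=np.inf)
    return dijkstra(graph, directed=False)


def char_path_length(net: WeightedConnectome, normalize: bool = True):
    """Characteristic path length on the -log length graph.

    Mean shortest-path distance over reachable ordered pairs (self-pairs
    excluded).  Returns ``(L, n_unreachable_pairs)``; a fully disconnected
    network is an error, partial disconnection is computed on reachable
    pairs and flagged via the count.
    """
    dist = _shortest_paths(weight_to_length(net, normalize=normalize))
    n = dist.shape[0]
    off = ~np.eye(n, dtype=bool)
    reachable = np.isfinite(dist) & off
    n_unreachable = int((off & ~np.isfinite(dist)).sum())
    if reachable.sum() == 0:
        raise ConsistencyError("fully disconnected network: no reachable pairs")
    if n_unreachable:
        logger.warning("char_path_length: %d unreachable ordered pairs", n_unreachable)
    return float(dist[reachable].mean()), n_unreachable


@dataclass
class SmallWorldReport:
    """Null-normalized clustering, path length and their quotient S."""

    C: float  # mean over nodes of (c_i / null-mean c_i)
    L: float  # L / null-mean L
    S: float
    n_nulls: int
    seed: int | None
    excluded_nodes: int = 0

    def __post_init__(self):
        if not (np.isfinite(self.C) and np.isfinite(self.L) and self.S > 0):
            raise ConsistencyError("small-world components must be finite and S > 0")


def small_worldness(
    net: WeightedConnectome,
    n_nulls: int = 50,
    seed: int = 0,
    nulls: NullEnsemble | None = None,
    swaps_per_edge: int = 100,
) -> SmallWorldReport:
    """Normalized small-worldness S = (C/C_null) / (L/L_null).

    Clustering is normalized within node against the null-ensemble mean for
    that node, then averaged across nodes; path length is normalized by the
    null-mean path length.  ``nulls`` may be precomputed (degree- and
    strength-preserving); otherwise an ensemble is generated.
    """
    from .nulls import generate_null_ensemble

    if nulls is None:
        nulls = generate_null_ensemble(
            net, n_nulls=n_nulls, kind="weighted", swaps_per_edge=swaps_per_edge, seed=seed
        )
    c_obs = weighted_clustering(net)
    l_obs, _ = char_path_length(net)
    c_null = np.mean([weighted_clustering(s) for s in nulls.surrogates], axis=0)
    l_null = float(np.mean([char_path_length(s)[0] for s in nulls.surrogates]))
    ok = c_null > 0
    excluded = int((~ok).sum())
    if excluded:
        logger.warning("small_worldness: excluding %d nodes with zero null clustering", excluded)
    C = float(np.mean(c_obs[ok] / c_null[ok]))
    L = l_obs / l_null
    return SmallWorldReport(
        C=C, L=L, S=C / L, n_nulls=len(nulls), seed=seed, excluded_nodes=excluded
    )


# ---------------------------------------------------------------------------
# centralities and hubness
# ---------------------------------------------------------------------------


@dataclass
class HubnessTable:
    """Per-node centrality panel and the 0-5 composite hubness score."""

    strength: np.ndarray
    betweenness: np.ndarray
    closeness: np.ndarray
    eigenvector: np.ndarray
    clustering: np.ndarray
    score: np.ndarray | None = None
    weight_name: str = "binary"

    @property
    def n_nodes(self) -> int:
        return len(self.strength)


def _power_iteration(w: np.ndarray, tol: float = 1e-10, max_iter: int = 10_000) -> np.ndarray:
    n = w.shape[0]
    # small positive diagonal shift keeps the dominant eigenvalue unique on
    # bipartite graphs (spectrum symmetric about 0) without changing the
    # principal eigenvector
    shift = 0.05 * w.sum(axis=1).max()
    ws = w + shift * np.eye(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for it in range(max_iter):
        nv = ws @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            raise ConsistencyError("eigenvector centrality undefined on empty network")
        nv = nv / norm
        if np.abs(nv - v).max() < tol:
            return np.abs(nv)
        v = nv
    raise ConsistencyError(f"eigenvector centrality did not converge in {max_iter} iterations")


def betweenness_closeness(lengths: np.ndarray):
    """Unnormalized betweenness and closeness on an edge-length matrix.

    ``lengths`` uses +inf for absent edges.  Shortest-path counting is only
    well defined when equal-length path ties are generic; a zero-length edge
    (the max-weight edge under the -log transform) makes ties structural and
    the counts there follow the Dijkstra settle order.
    """
    n = lengths.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    iu, ju = np.where(np.triu(np.isfinite(lengths), 1))
    g.add_weighted_edges_from(
        ((int(i), int(j), float(lengths[i, j])) for i, j in zip(iu, ju)), weight="length"
    )
    btw = nx.betweenness_centrality(g, weight="length", normalized=False)
    clo = nx.closeness_centrality(g, distance="length")
    return (
        np.array([btw[i] for i in range(n)]),
        np.array([clo[i] for i in range(n)]),
    )


def centrality_panel(net: WeightedConnectome) -> HubnessTable:
    """Strength, betweenness, closeness, eigenvector centrality, clustering.

    Betweenness (unnormalized pair counts) and closeness run on the -log
    length graph; eigenvector centrality is the nonnegative principal
    eigenvector of W (unit norm).
    """
    w = net.matrix
    lengths = weight_to_length(net)
    np.fill_diagonal(lengths, np.inf)
    btw, clo = betweenness_closeness(lengths)
    return HubnessTable(
        strength=w.sum(axis=1),
        betweenness=btw,
        closeness=clo,
        eigenvector=_power_iteration(w),
        clustering=weighted_clustering(net),
        weight_name=net.weight_name,
    )


def _top_set(values: np.ndarray, m: int, largest: bool) -> np.ndarray:
    """Indices of the m largest (or smallest) values; ties break by node index."""
    n = len(values)
    key = -values if largest else values
    order = np.lexsort((np.arange(n), key))
    return order[:m]


def hubness_scores(panel: HubnessTable) -> HubnessTable:
    """0-5 composite: +1 for top-20% strength/betweenness/closeness/eigenvector,
    +1 for bottom-20% clustering; rank ties break deterministically by node index."""
    n = panel.n_nodes
    m = int(np.ceil(0.2 * n))
    score = np.zeros(n, dtype=int)
    for vals in (panel.strength, panel.betweenness, panel.closeness, panel.eigenvector):
        score[_top_set(np.asarray(vals, dtype=float), m, largest=True)] += 1
    score[_top_set(np.asarray(panel.clustering, dtype=float), m, largest=False)] += 1
    return HubnessTable(
        strength=panel.strength,
        betweenness=panel.betweenness,
        closeness=panel.closeness,
        eigenvector=panel.eigenvector,
        clustering=panel.clustering,
        score=score,
        weight_name=panel.weight_name,
    )


def hubness_distance(tables: dict) -> tuple:
    """Euclidean distance between nodal hubness vectors for each pair of weightings.

    Returns ``(names, matrix)``.
    """
    names = list(tables)
    n_nodes = {name: t.n_nodes for name, t in tables.items()}
    if len(set(n_nodes.values())) != 1:
        raise ConsistencyError(f"hubness tables disagree on node count: {n_nodes}")
    vecs = []
    for name in names:
        t = tables[name]
        if t.score is None:
            raise ConsistencyError(f"hubness table {name!r} has no scores")
        vecs.append(np.asarray(t.score, dtype=float))
    vecs = np.stack(vecs)
    diff = vecs[:, None, :] - vecs[None, :, :]
    return names, np.sqrt((diff**2).sum(axis=2))


# ---------------------------------------------------------------------------
# rich club
# ---------------------------------------------------------------------------


@dataclass
class RichClubCurve:
    k: np.ndarray
    phi: np.ndarray
    phi_null: np.ndarray | None = None
    phi_norm: np.ndarray | None = None
    detected: list = field(default_factory=list)  # [(k_lo, k_hi)] with phi_norm > 1


def _raw_rich_club(w: np.ndarray, weighted: bool) -> RichClubCurve:
    binary = w != 0
    degree = binary.sum(axis=1)
    kmax = int(degree.max())
    ks = np.arange(1, kmax)
    phi = np.full(len(ks), np.nan)
    if weighted:
        all_w = np.sort(w[np.triu(binary, 1)])[::-1]
        cum = np.concatenate([[0.0], np.cumsum(all_w)])
    for t, k in enumerate(ks):
        nodes = degree > k
        n_sub = int(nodes.sum())
        if n_sub < 2:
            continue
        sub = w[np.ix_(nodes, nodes)]
        e_sub = int(np.count_nonzero(np.triu(sub, 1)))
        if weighted:
            if e_sub == 0:
                phi[t] = 0.0
            else:
                phi[t] = np.triu(sub, 1).sum() / cum[e_sub]
        else:
            phi[t] = 2.0 * e_sub / (n_sub * (n_sub - 1))
    return RichClubCurve(k=ks, phi=phi)


def rich_club_binary(net: WeightedConnectome) -> RichClubCurve:
    """Binary rich-club coefficient phi(k) = 2 E_>k / (N_>k (N_>k - 1))."""
    return _raw_rich_club((net.matrix != 0).astype(float), weighted=False)


def rich_club_weighted(net: WeightedConnectome) -> RichClubCurve:
    """Weighted rich-club coefficient.

    phi_w(k) = (weight inside the subgraph of nodes with degree > k) /
    (sum of the equally many strongest edge weights in the whole network).
    Degree is taken from the binary map.  NaN where fewer than two nodes
    exceed k.
    """
    return _raw_rich_club(net.matrix, weighted=True)


def normalize_rich_club(raw: RichClubCurve, nulls: NullEnsemble, weighted: bool = True) -> RichClubCurve:
    """phi_norm(k) = phi(k) / mean over nulls of phi_null(k).

    Detection: maximal contiguous k intervals with phi_norm strictly > 1.
    NaNs propagate; a zero null mean yields NaN at that k (logged).
    """
    null_curves = []
    for s in nulls.surrogates:
        c = _raw_rich_club(s.matrix if weighted else (s.matrix != 0).astype(float), weighted)
        row = np.full(len(raw.k), np.nan)
        n_common = min(len(c.phi), len(row))
        row[:n_common] = c.phi[:n_common]
        null_curves.append(row)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN k levels
        phi_null = np.nanmean(np.stack(null_curves), axis=0)
    zero_null = np.isfinite(phi_null) & (phi_null == 0)
    if zero_null.any():
        logger.warning("normalize_rich_club: zero null mean at %d k levels", int(zero_null.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        phi_norm = np.where(zero_null, np.nan, raw.phi / np.where(phi_null == 0, 1, phi_null))
    detected = []
    # strict > 1 criterion, with a 1e-9 guard so ratios that are exactly 1
    # up to float rounding (e.g. the whole-graph club) never register
    above = np.isfinite(phi_norm) & (phi_norm > 1 + 1e-9)
    start = None
    for t, flag in enumerate(above):
        if flag and start is None:
            start = t
        elif not flag and start is not None:
            detected.append((int(raw.k[start]), int(raw.k[t - 1])))
            start = None
    if start is not None:
        detected.append((int(raw.k[start]), int(raw.k[len(above) - 1])))
    return RichClubCurve(
        k=raw.k, phi=raw.phi, phi_null=phi_null, phi_norm=phi_norm, detected=detected
    )
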