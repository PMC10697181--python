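"""Degree-preserving and degree-and-strength-preserving surrogate networks.

Binary surrogates follow Maslov-Sneppen double-edge swaps; every surrogate
keeps the original degree sequence exactly (integer equality).  Weighted
surrogates place the original weight multiset on a rewired topology and
approximate the original strength sequence by simulated annealing over
weight swaps, so the weight multiset is preserved exactly and the strength
sequence approximately.  The hot loops are numba-compiled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .core import ConsistencyError, WeightedConnectome

__all__ = [
    "AnnealParams",
    "NullEnsemble",
    "rewire_degree_preserving",
    "match_strength_sequence",
    "generate_null_ensemble",
]


@dataclass(frozen=True)
class AnnealParams:
    """Simulated-annealing schedule for strength matching.

    T0 is expressed as a fraction of the initial energy; cooling is
    geometric per sweep (one sweep = |E| proposals); the best-so-far state
    is returned, with early stop when it stagnates for ``patience`` sweeps.
    """

    t0_frac: float = 1e-3
    cooling: float = 0.99
    max_sweeps: int = 10_000
    patience: int = 100


@dataclass
class NullEnsemble:
    """Rewired surrogates with provenance for topology normalization."""

    kind: str  # "binary-degree" | "weighted-degree-strength"
    surrogates: list  # list of WeightedConnectome
    seed: int
    swaps: list = field(default_factory=list)  # accepted swaps per surrogate
    traces: list = field(default_factory=list)  # annealing energy per sweep

    def __post_init__(self):
        if self.kind not in ("binary-degree", "weighted-degree-strength"):
            raise ConsistencyError(f"unknown null kind {self.kind!r}")

    def __len__(self) -> int:
        return len(self.surrogates)


@njit(cache=True)
def _rewire_kernel(edges, adj, n_attempts, seed):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_edges = edges.shape[0]
    accepted = 0
    for _ in range(n_attempts):
        e1 = np.random.randint(n_edges)
        e2 = np.random.randint(n_edges)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if np.random.randint(2) == 1:
            c, d = d, c
        # propose (a, d) and (c, b)
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, d] or adj[c, b]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, d] = True
        adj[d, a] = True
        adj[c, b] = True
        adj[b, c] = True
        edges[e1, 0] = a
        edges[e1, 1] = d
        edges[e2, 0] = c
        edges[e2, 1] = b
        accepted += 1
    return accepted


@njit(cache=True)
def _anneal_kernel(
    edges, w, target, n_nodes, t0, cooling, max_sweeps, patience, seed
):  # pragma: no cover - jitted
    np.random.seed(seed)
    n_edges = edges.shape[0]
    s = np.zeros(n_nodes)
    for e in range(n_edges):
        s[edges[e, 0]] += w[e]
        s[edges[e, 1]] += w[e]
    energy = 0.0
    for i in range(n_nodes):
        diff = s[i] - target[i]
        energy += diff * diff
    best_w = w.copy()
    best_e = energy
    trace = np.empty(max_sweeps)
    t = t0
    stagnant = 0
    n_sweeps = 0
    for sweep in range(max_sweeps):
        for _ in range(n_edges):
            e1 = np.random.randint(n_edges)
            e2 = np.random.randint(n_edges)
            if e1 == e2:
                continue
            dw = w[e2] - w[e1]
            if dw == 0.0:
                continue
            a1, b1 = edges[e1, 0], edges[e1, 1]
            a2, b2 = edges[e2, 0], edges[e2, 1]
            # net strength change: +dw on e1's endpoints, -dw on e2's,
            # accumulated per unique node so shared endpoints are exact
            nodes = np.empty(4, dtype=np.int64)
            deltas = np.zeros(4)
            nodes[0], deltas[0] = a1, dw
            nodes[1], deltas[1] = b1, dw
            nodes[2], deltas[2] = a2, -dw
            nodes[3], deltas[3] = b2, -dw
            de = 0.0
            for k in range(4):
                node = nodes[k]
                if node < 0:
                    continue
                delta = deltas[k]
                for k2 in range(k + 1, 4):
                    if nodes[k2] == node:
                        delta += deltas[k2]
                        nodes[k2] = -1
                if delta == 0.0:
                    continue
                diff_old = s[node] - target[node]
                diff_new = diff_old + delta
                de += diff_new * diff_new - diff_old * diff_old
            accept = de < 0.0
            if not accept and t > 0.0:
                if np.random.random() < np.exp(-de / t):
                    accept = True
            if accept:
                tmp = w[e1]
                w[e1] = w[e2]
                w[e2] = tmp
                s[a1] += dw
                s[b1] += dw
                s[a2] -= dw
                s[b2] -= dw
                energy += de
        trace[sweep] = energy
        n_sweeps = sweep + 1
        if energy < best_e - 1e-12:
            best_e = energy
            best_w[:] = w
            stagnant = 0
        else:
            stagnant += 1
        if stagnant > patience:
            break
        t *= cooling
    return best_w, best_e, trace[:n_sweeps]


def _edge_list(binary: np.ndarray) -> np.ndarray:
    iu, ju = np.where(np.triu(binary, 1))
    return np.column_stack([iu, ju]).astype(np.int64)


def _matrix_from_edges(edges: np.ndarray, weights: np.ndarray, n: int) -> np.ndarray:
    m = np.zeros((n, n))
    m[edges[:, 0], edges[:, 1]] = weights
    m += m.T
    return m


def rewire_degree_preserving(
    net: WeightedConnectome, swaps_per_edge: int = 100, seed: int = 0
) -> WeightedConnectome:
    """Maslov-Sneppen rewiring of the binary map of ``net``.

    Attempts ``swaps_per_edge * |E|`` double-edge swaps, rejecting any that
    would create a self-loop or multi-edge.  The degree sequence is exactly
    preserved.  If no swap was admissible the input map is returned with a
    warning.
    """
    binary = net.binary()
    edges = _edge_list(binary)
    if len(edges) < 2:
        raise ConsistencyError("need at least 2 edges to rewire")
    adj = binary.copy()
    n_attempts = int(swaps_per_edge) * len(edges)
    accepted = _rewire_kernel(edges, adj, n_attempts, int(seed) % (2**32))
    if accepted == 0:
        warnings.warn("no admissible swap found; returning the input topology", stacklevel=2)
    out = WeightedConnectome("binary", net.subject_id, adj.astype(float))
    out._swaps_accepted = accepted  # provenance for NullEnsemble
    return out


def match_strength_sequence(
    topology: WeightedConnectome,
    weights: np.ndarray,
    target_strengths: np.ndarray,
    anneal: AnnealParams = AnnealParams(),
    seed: int = 0,
    weight_name: str = "COMMIT",
):
    """Place a weight multiset on a binary topology, annealing toward target strengths.

    Energy is sum_i (s_i - s_i^target)^2 over nodes; proposals swap the
    weights of two edges; acceptance is Metropolis with geometric cooling.
    The weight multiset is unchanged by construction.  Returns
    ``(WeightedConnectome, trace)`` where trace is the energy per sweep.
    """
    binary = topology.binary()
    edges = _edge_list(binary)
    weights = np.asarray(weights, dtype=float).copy()
    target = np.asarray(target_strengths, dtype=float)
    n = topology.n_nodes
    if len(weights) != len(edges):
        raise ConsistencyError("weight multiset size must equal the edge count")
    if target.shape != (n,):
        raise ConsistencyError("target strengths must be one scalar per node")
    if np.ptp(weights) == 0:
        # energy is invariant to placement; nothing to anneal
        mat = _matrix_from_edges(edges, weights, n)
        s = mat.sum(axis=1)
        e0 = float(((s - target) ** 2).sum())
        return (
            WeightedConnectome(weight_name, topology.subject_id, mat),
            np.array([e0]),
        )
    # initial placement: as given
    s0 = np.zeros(n)
    np.add.at(s0, edges[:, 0], weights)
    np.add.at(s0, edges[:, 1], weights)
    e0 = float(((s0 - target) ** 2).sum())
    if e0 == 0.0:
        mat = _matrix_from_edges(edges, weights, n)
        return WeightedConnectome(weight_name, topology.subject_id, mat), np.array([0.0])
    t0 = anneal.t0_frac * e0
    best_w, _, trace = _anneal_kernel(
        edges,
        weights,
        target,
        n,
        t0,
        anneal.cooling,
        int(anneal.max_sweeps),
        int(anneal.patience),
        int(seed) % (2**32),
    )
    mat = _matrix_from_edges(edges, best_w, n)
    return WeightedConnectome(weight_name, topology.subject_id, mat), trace


def generate_null_ensemble(
    net: WeightedConnectome,
    n_nulls: int = 50,
    kind: str = "weighted",
    swaps_per_edge: int = 100,
    anneal: AnnealParams = AnnealParams(),
    seed: int = 0,
) -> NullEnsemble:
    """Independent degree-(and strength-)preserving surrogates of ``net``.

    ``kind`` is "binary" (degree-preserving rewiring only) or "weighted"
    (rewire, then place the original weight multiset by annealing toward
    the original strength sequence).  Child seeds derive from ``seed``.
    """
    if kind not in ("binary", "weighted"):
        raise ValueError("kind must be 'binary' or 'weighted'")
    iu, ju = np.where(np.triu(net.matrix, 1))
    orig_weights = net.matrix[iu, ju]
    target = net.matrix.sum(axis=1)
    ss = np.random.SeedSequence(seed)
    children = ss.generate_state(2 * n_nulls)
    surrogates, swaps, traces = [], [], []
    for k in range(n_nulls):
        rewired = rewire_degree_preserving(
            net, swaps_per_edge=swaps_per_edge, seed=int(children[2 * k])
        )
        swaps.append(getattr(rewired, "_swaps_accepted", 0))
        if kind == "binary":
            surrogates.append(rewired)
            traces.append(np.empty(0))
        else:
            surrogate, trace = match_strength_sequence(
                rewired,
                orig_weights,
                target,
                anneal=anneal,
                seed=int(children[2 * k + 1]),
                weight_name=net.weight_name if net.weight_name != "binary" else "COMMIT",
            )
            surrogates.append(surrogate)
            traces.append(trace)
    return NullEnsemble(
        kind="binary-degree" if kind == "binary" else "weighted-degree-strength",
        surrogates=surrogates,
        seed=seed,
        swaps=swaps,
        traces=traces,
    )
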