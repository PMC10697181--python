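"""Edgewise statistics: quartile dispersion, length binning, module
summaries, length residualization, Spearman correlation, permutation tests.

Quantiles everywhere use linear interpolation between order statistics
(numpy's default, "type 7").  Zero-valued edges are treated as absent and
excluded from every dispersion sample.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .core import (
    ConsistencyError,
    EdgeVector,
    Parcellation,
    SubjectEnsemble,
    TRANSMODAL_MODULES,
    UNIMODAL_MODULES,
    WeightedConnectome,
    edge_vectorize,
)

__all__ = [
    "cqd",
    "intra_subject_cqd",
    "inter_subject_cqd",
    "node_mean_inter_cqd",
    "BinScheme",
    "make_bins",
    "binned_statistic",
    "module_edge_summary",
    "residualize_on_length",
    "spearman",
    "PermutationResult",
    "permutation_pvalue",
]


def cqd(values) -> float:
    """Quartile coefficient of dispersion, (Q3 - Q1) / (Q3 + Q1).

    Robust relative-variability measure; invariant to positive rescaling
    and <= 1 for nonnegative data.  Returns NaN when Q3 + Q1 == 0.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 2:
        return float("nan")
    q1, q3 = np.quantile(values, [0.25, 0.75])
    denom = q3 + q1
    if denom == 0:
        return float("nan")
    return float((q3 - q1) / denom)


def intra_subject_cqd(ensemble: SubjectEnsemble, mask: WeightedConnectome) -> np.ndarray:
    """CQD across each subject's nonzero masked edge weights (one value per subject)."""
    out = np.empty(len(ensemble))
    for s, net in enumerate(ensemble.subjects):
        vals = edge_vectorize(net, mask).values
        out[s] = cqd(vals[vals != 0])
    return out


def inter_subject_cqd(ensemble: SubjectEnsemble, mask: WeightedConnectome) -> EdgeVector:
    """Per-edge CQD across subjects, zero entries excluded; NaN if < 2 usable."""
    evs = [edge_vectorize(net, mask) for net in ensemble.subjects]
    stack = np.stack([ev.values for ev in evs])  # subjects x edges
    m = stack.shape[1]
    out = np.full(m, np.nan)
    for e in range(m):
        col = stack[:, e]
        col = col[col != 0]
        if len(col) >= 2:
            out[e] = cqd(col)
    return EdgeVector(
        idx=evs[0].idx, values=out, weight_name=ensemble.weight_name, subject_id="group"
    )


def node_mean_inter_cqd(inter: EdgeVector, n_nodes: int) -> np.ndarray:
    """Mean inter-subject CQD over the edges incident to each node."""
    sums = np.zeros(n_nodes)
    counts = np.zeros(n_nodes)
    ok = np.isfinite(inter.values)
    for (i, j), v in zip(inter.idx[ok], inter.values[ok]):
        sums[i] += v
        sums[j] += v
        counts[i] += 1
        counts[j] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(counts > 0, sums / np.where(counts > 0, counts, 1), np.nan)


# ---------------------------------------------------------------------------
# edge-length binning: five linear bins of width w plus a final 3w bin
# ---------------------------------------------------------------------------


@dataclass
class BinScheme:
    edges: np.ndarray  # 7 ascending bin boundaries spanning [min, max]
    w: float
    rule: str = "5xw + 1x3w"

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, lengths) -> np.ndarray:
        """0-based bin index; boundary values go to the lower bin, the
        global maximum to the final bin."""
        lengths = np.asarray(lengths, dtype=float)
        if np.any(lengths < self.edges[0] - 1e-9) or np.any(lengths > self.edges[-1] + 1e-9):
            raise ValueError("lengths outside the bin scheme span")
        # bins: [e0, e1], (e1, e2], ..., (e5, e6]
        idx = np.searchsorted(self.edges[1:-1], lengths, side="left")
        return idx.astype(np.int64)


def make_bins(lengths) -> BinScheme:
    """Six bins over [min, max]: five of width w = range/8 and one of width 3w."""
    lengths = np.asarray(lengths, dtype=float)
    if len(np.unique(lengths)) < 6:
        raise ValueError("need at least 6 distinct lengths to bin")
    lo, hi = float(lengths.min()), float(lengths.max())
    if hi == lo:
        raise ValueError("all lengths equal; binning undefined")
    w = (hi - lo) / 8.0
    edges = np.array([lo + k * w for k in range(6)] + [hi])
    return BinScheme(edges=edges, w=w)


def binned_statistic(values, lengths, bins: BinScheme, stat: str = "cqd", other=None):
    """Per-bin statistic plus its proportion of the within-network maximum.

    ``stat`` is "cqd" (dispersion of ``values`` per bin) or "spearman"
    (rank correlation of ``values`` with ``other`` per bin).
    Returns ``(per_bin, proportion_of_max)``.
    """
    values = np.asarray(values, dtype=float)
    lengths = np.asarray(lengths, dtype=float)
    idx = bins.assign(lengths)
    out = np.full(bins.n_bins, np.nan)
    for b in range(bins.n_bins):
        sel = idx == b
        if stat == "cqd":
            if sel.sum() >= 2:
                out[b] = cqd(values[sel])
        elif stat == "spearman":
            if other is None:
                raise ValueError("stat='spearman' requires the second vector")
            o = np.asarray(other, dtype=float)
            if sel.sum() >= 3:
                out[b] = spearman(values[sel], o[sel])
        else:
            raise ValueError(f"unknown stat {stat!r}")
    with np.errstate(invalid="ignore"):
        denom = np.nanmax(np.abs(out))
        prop = out / denom if denom and np.isfinite(denom) else np.full_like(out, np.nan)
    return out, prop


# ---------------------------------------------------------------------------
# module-resolved summaries
# ---------------------------------------------------------------------------


def _summarize(vals: np.ndarray) -> dict:
    if len(vals) == 0:
        return {"n": 0, "median": float("nan"), "q1": float("nan"), "q3": float("nan")}
    q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
    return {"n": int(len(vals)), "median": float(med), "q1": float(q1), "q3": float(q3)}


def module_edge_summary(
    net: WeightedConnectome, parc: Parcellation, mask: WeightedConnectome | None = None
) -> dict:
    """Group nonzero (masked) edges by module membership, two schemes.

    Scheme 1: within- vs between-module.  Scheme 2: unimodal (within VIS or
    SMN), transmodal (within DAN/SVAN/CONT/DMN), and everything else
    ("between", which also absorbs within-SUB/LIMB edges so every edge lands
    in exactly one group).
    """
    ev = edge_vectorize(net, mask)
    nz = ev.values != 0
    idx, vals = ev.idx[nz], ev.values[nz]
    mod_i = parc.module[idx[:, 0]]
    mod_j = parc.module[idx[:, 1]]
    within = mod_i == mod_j
    uni = within & np.isin(mod_i, UNIMODAL_MODULES)
    trans = within & np.isin(mod_i, TRANSMODAL_MODULES)
    groups = {
        "within": vals[within],
        "between": vals[~within],
        "unimodal": vals[uni],
        "transmodal": vals[trans],
        "between2": vals[~(uni | trans)],
    }
    summary = {name: _summarize(v) for name, v in groups.items()}
    summary["_flags"] = {
        "between_empty": bool((~within).sum() == 0),
        "n_edges": int(len(vals)),
    }
    return {"values": groups, "summary": summary}


# ---------------------------------------------------------------------------
# residualization, correlation, permutation
# ---------------------------------------------------------------------------


def residualize_on_length(values: EdgeVector, lengths: EdgeVector) -> EdgeVector:
    """OLS residuals of edge values after linear regression on edge length."""
    if not np.array_equal(values.idx, lengths.idx):
        raise ConsistencyError("values/lengths edge indices are not aligned")
    y = values.values
    x = lengths.values
    if len(y) < 3:
        raise ValueError("need at least 3 edges to residualize")
    if np.ptp(x) == 0:
        raise ValueError("edge lengths are constant; regression degenerate")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return EdgeVector(
        idx=values.idx,
        values=resid,
        weight_name=values.weight_name,
        subject_id=values.subject_id,
    )


def spearman(x, y) -> float:
    """Spearman rank correlation (average ranks for ties); NaN if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConsistencyError("vectors must be aligned")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(sps.spearmanr(x, y).statistic)


@dataclass
class PermutationResult:
    observed: float
    null: np.ndarray
    p: float
    seed: int
    direction: str  # "greater" or "less", taken from the observed sign
    n_perm: int

    def __post_init__(self):
        if not (0 < self.p <= 1):
            raise ConsistencyError("permutation p must be in (0, 1]")


def permutation_pvalue(
    x, y, n_perm: int = 10_000, seed: int = 0, direction: str = "auto"
) -> PermutationResult:
    """One-sided permutation p for Spearman(x, y) under label permutation of y.

    The null is the Spearman statistic under ``n_perm`` independent uniform
    permutations and p = (1 + #{null at least as extreme}) / (n_perm + 1).
    With ``direction="auto"`` the test direction follows the observed sign
    (the reported convention); note that such a sign-adaptive p is uniform
    on (0, 1/2] under the null, so calibration checks should fix
    ``direction`` to "greater" or "less".
    """
    if direction not in ("auto", "greater", "less"):
        raise ValueError("direction must be 'auto', 'greater' or 'less'")
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives a very coarse p value", stacklevel=2)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ConsistencyError("vectors must be aligned")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    obs = spearman(x, y)
    rng = np.random.default_rng(seed)
    # rank once; the null statistic is the Pearson correlation of the fixed
    # rank vector with a permuted rank vector
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    perms = np.argsort(rng.random((n_perm, len(ry))), axis=1)
    null = (ry[perms] @ rx) / len(rx)
    if direction == "auto":
        direction = "greater" if obs >= 0 else "less"
    if direction == "greater":
        extreme = int((null >= obs - 1e-12).sum())
    else:
        extreme = int((null <= obs + 1e-12).sum())
    p = (1.0 + extreme) / (n_perm + 1.0)
    return PermutationResult(
        observed=obs, null=null, p=p, seed=seed, direction=direction, n_perm=n_perm
    )
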