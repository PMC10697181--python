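"""Construction of weighted structural networks from streamline tables.

Eight structural weightings are supported: NoS (streamline count), LoS (mean
streamline length), SIFT2 (sum of SIFT2 streamline weights), COMMIT (the
length-weighted sum of COMMIT streamline weights,
``alpha_ij = sum_k x_ijk * l_k / Lbar_ij``), and four tractometry weightings
(R1, FA, RD, ICVF; per-streamline median, mean across streamlines).  NoS,
SIFT2 and COMMIT are normalized by node volume.  Post-processing applies a
streamline-level COMMIT filter, an edge-level COMMIT filter that enforces a
uniform binary map across weightings within subject, a group consensus mask,
and zero-excluding group averaging.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    METRICS,
    ConsistencyError,
    FormatError,
    Parcellation,
    StreamlineTable,
    SubjectEnsemble,
    WeightedConnectome,
)

__all__ = [
    "COMMIT_THRESHOLD",
    "EdgeWeightRecipe",
    "RECIPES",
    "commit_filter",
    "build_nos_los",
    "build_sift2",
    "build_commit",
    "build_tractometry",
    "volume_normalize",
    "build_fc",
    "consensus_mask",
    "apply_commit_edge_filter",
    "group_average",
    "build_all_weightings",
]

#: Streamlines with a COMMIT weight below this are treated as false positives.
COMMIT_THRESHOLD = 1e-12


@dataclass(frozen=True)
class EdgeWeightRecipe:
    weight_name: str
    aggregation: str  # "count" | "mean_length" | "sum" | "length_weighted_sum" | "mean_median"
    volume_normalized: bool


RECIPES = {
    "NoS": EdgeWeightRecipe("NoS", "count", True),
    "LoS": EdgeWeightRecipe("LoS", "mean_length", False),
    "SIFT2": EdgeWeightRecipe("SIFT2", "sum", True),
    "COMMIT": EdgeWeightRecipe("COMMIT", "length_weighted_sum", True),
    "R1": EdgeWeightRecipe("R1", "mean_median", False),
    "FA": EdgeWeightRecipe("FA", "mean_median", False),
    "RD": EdgeWeightRecipe("RD", "mean_median", False),
    "ICVF": EdgeWeightRecipe("ICVF", "mean_median", False),
}


def commit_filter(table: StreamlineTable, threshold: float = COMMIT_THRESHOLD):
    """Remove streamlines whose COMMIT weight falls below ``threshold``.

    Returns ``(filtered_table, report)`` where report counts retained and
    removed rows.  An empty result is legal (warned, not an error).
    """
    keep = table.df["w_commit"].to_numpy() >= threshold
    removed = int((~keep).sum())
    out = StreamlineTable(df=table.df.loc[keep], subject_id=table.subject_id)
    if len(out) == 0:
        warnings.warn("commit_filter removed every streamline", stacklevel=2)
    return out, {"retained": int(keep.sum()), "removed": removed}


def _edge_groups(table: StreamlineTable, n_nodes: int):
    """Flat pair index (i * n + j, i < j) per streamline row."""
    i = table.df["node_i"].to_numpy()
    j = table.df["node_j"].to_numpy()
    if len(i) and (i.min() < 0 or j.max() >= n_nodes):
        raise ConsistencyError("streamline endpoints outside parcellation")
    return i, j, i * n_nodes + j


def _accumulate(flat, values, n_nodes):
    acc = np.zeros(n_nodes * n_nodes)
    np.add.at(acc, flat, values)
    return acc.reshape(n_nodes, n_nodes)


def _symmetrize(upper: np.ndarray) -> np.ndarray:
    return upper + upper.T


def build_nos_los(table: StreamlineTable, parc: Parcellation):
    """NoS (streamline count) and LoS (mean streamline length) networks."""
    n = parc.n_nodes
    _, _, flat = _edge_groups(table, n)
    count = _accumulate(flat, np.ones(len(table)), n)
    lsum = _accumulate(flat, table.df["length_mm"].to_numpy(dtype=float), n)
    with np.errstate(invalid="ignore", divide="ignore"):
        los = np.where(count > 0, lsum / np.where(count > 0, count, 1), 0.0)
    nos = WeightedConnectome("NoS", table.subject_id, _symmetrize(count))
    los = WeightedConnectome("LoS", table.subject_id, _symmetrize(los))
    return nos, los


def build_sift2(table: StreamlineTable, parc: Parcellation) -> WeightedConnectome:
    """SIFT2 network: sum of SIFT2 streamline weights per node pair."""
    n = parc.n_nodes
    _, _, flat = _edge_groups(table, n)
    sums = _accumulate(flat, table.df["w_sift2"].to_numpy(dtype=float), n)
    return WeightedConnectome("SIFT2", table.subject_id, _symmetrize(sums))


def build_commit(table: StreamlineTable, parc: Parcellation) -> WeightedConnectome:
    """COMMIT network: length-weighted sum of COMMIT streamline weights.

    alpha_ij = sum_k x_ijk * l_k / Lbar_ij, where Lbar_ij is the mean
    streamline length of the pair.  Pairs with no streamlines are zero.
    """
    n = parc.n_nodes
    lengths = table.df["length_mm"].to_numpy(dtype=float)
    if np.any(lengths <= 0):
        raise ValueError("streamline lengths must be positive")
    _, _, flat = _edge_groups(table, n)
    count = _accumulate(flat, np.ones(len(table)), n)
    lsum = _accumulate(flat, lengths, n)
    wlsum = _accumulate(flat, table.df["w_commit"].to_numpy(dtype=float) * lengths, n)
    with np.errstate(invalid="ignore", divide="ignore"):
        lbar = np.where(count > 0, lsum / np.where(count > 0, count, 1), 0.0)
        alpha = np.where(count > 0, wlsum / np.where(lbar > 0, lbar, 1), 0.0)
    return WeightedConnectome("COMMIT", table.subject_id, _symmetrize(alpha))


def build_tractometry(table: StreamlineTable, parc: Parcellation, metric: str) -> WeightedConnectome:
    """Tractometry network: mean across streamlines of per-streamline medians."""
    if metric not in METRICS:
        raise FormatError(f"unknown tractometry metric {metric!r}; allowed: {METRICS}")
    col = f"med_{metric}"
    if col not in table.df.columns:
        raise FormatError(f"streamline table missing metric column {col!r}")
    n = parc.n_nodes
    _, _, flat = _edge_groups(table, n)
    count = _accumulate(flat, np.ones(len(table)), n)
    msum = _accumulate(flat, table.df[col].to_numpy(dtype=float), n)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(count > 0, msum / np.where(count > 0, count, 1), 0.0)
    return WeightedConnectome(metric, table.subject_id, _symmetrize(mean))


def volume_normalize(net: WeightedConnectome, parc: Parcellation) -> WeightedConnectome:
    """Divide each edge weight by the mean volume of its endpoint nodes.

    W'_ij = 2 W_ij / (v_i + v_j).  Symmetric in (i, j) and the identity for
    unit volumes; doubling all volumes halves all weights.
    """
    v = parc.volume
    if np.any(v <= 0):
        raise ConsistencyError("node volumes must be strictly positive")
    denom = (v[:, None] + v[None, :]) / 2.0
    return WeightedConnectome(net.weight_name, net.subject_id, net.matrix / denom)


def build_fc(time_series: np.ndarray, subject_id: str = "unknown") -> WeightedConnectome:
    """Fisher-Z-transformed Pearson correlation of node time series.

    ``time_series`` is node x T.  r is clipped to +-(1 - 1e-15) before
    atanh so perfectly correlated nodes yield a large finite value.
    """
    ts = np.asarray(time_series, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise FormatError("time series must be node x T with T >= 3")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"constant time series at node {bad}")
    r = np.corrcoef(ts)
    r = np.clip(r, -(1 - 1e-15), 1 - 1e-15)
    z = np.arctanh(r)
    np.fill_diagonal(z, 0.0)
    z = (z + z.T) / 2.0
    return WeightedConnectome("FC", subject_id, z)


def consensus_mask(ensemble: SubjectEnsemble, fraction: float = 0.5) -> WeightedConnectome:
    """Binary mask of edges nonzero in at least ``fraction`` of subjects.

    Ties at exactly ``fraction`` are retained (>= semantics: with 50
    subjects a "50% threshold" reads as at-least-half).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    stack = ensemble.stack() != 0
    frac_present = stack.mean(axis=0)
    mask = (frac_present >= fraction - 1e-12).astype(float)
    np.fill_diagonal(mask, 0.0)
    return WeightedConnectome("binary", "group", mask)


def apply_commit_edge_filter(
    ensembles: dict, commit_ensemble: SubjectEnsemble, threshold: float = COMMIT_THRESHOLD
) -> dict:
    """Zero edges in every weighting where the subject's COMMIT edge is below threshold.

    After this step the binary map is identical across weightings within
    each subject, which is the premise that lets edge weights alone drive
    all downstream comparisons.
    """
    out = {}
    n_subj = len(commit_ensemble)
    commit_stack = commit_ensemble.stack()
    keep = commit_stack >= threshold
    for name, ens in ensembles.items():
        if len(ens) != n_subj:
            raise ConsistencyError(f"{name}: subject count mismatch with COMMIT ensemble")
        nets = []
        for s, net in enumerate(ens.subjects):
            if net.subject_id != commit_ensemble.subjects[s].subject_id:
                raise ConsistencyError(f"{name}: subject order mismatch at position {s}")
            nets.append(
                WeightedConnectome(net.weight_name, net.subject_id, net.matrix * keep[s])
            )
        out[name] = SubjectEnsemble(ens.parcellation, ens.weight_name, nets)
    return out


def group_average(ensemble: SubjectEnsemble, mask: WeightedConnectome):
    """Subject-wise mean at each masked edge, excluding zero-valued entries.

    Returns ``(group_net, report)``; masked edges that are zero in every
    subject stay zero and are counted in the report.
    """
    stack = ensemble.stack()
    nz = stack != 0
    counts = nz.sum(axis=0)
    sums = (stack * nz).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.where(counts > 0, counts, 1), 0.0)
    m = mask.matrix != 0
    group = np.where(m, mean, 0.0)
    np.fill_diagonal(group, 0.0)
    empty = int(np.count_nonzero(m & (counts == 0)) // 2)
    net = WeightedConnectome(ensemble.weight_name, "group", group)
    return net, {"masked_edges_all_zero": empty}


def build_all_weightings(
    table: StreamlineTable,
    parc: Parcellation,
    commit_threshold: float = COMMIT_THRESHOLD,
) -> dict:
    """Build the eight structural weightings for one subject.

    NoS, LoS and SIFT2 are computed from the full (streamline-filtered)
    table; COMMIT and the tractometry weightings from the COMMIT-filtered
    table, mirroring the two-stage tractogram filtering.  The edge-level
    COMMIT filter (:func:`apply_commit_edge_filter`) is applied separately
    at the ensemble level.
    """
    table.validate_against(parc)
    filtered, _ = commit_filter(table, commit_threshold)
    nos, los = build_nos_los(table, parc)
    nets = {
        "NoS": volume_normalize(nos, parc),
        "LoS": los,
        "SIFT2": volume_normalize(build_sift2(table, parc), parc),
        "COMMIT": volume_normalize(build_commit(filtered, parc), parc),
    }
    for metric in METRICS:
        nets[metric] = build_tractometry(filtered, parc, metric)
    return nets
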