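"""Synthetic multi-subject cohorts with the statistical structure of real
weighted structural connectomes.

The generator emulates, at a configurable desk scale, the features the
analysis assumes: distance-dependent connection probability with modular
bias on nodes clustered in a 150 mm cube; heavy-tailed (lognormal) edge
distributions for the streamline-specific weightings and near-normal
distributions for the tractometry weightings; configurable sign and
magnitude of the Spearman coupling between each weighting and edge length;
a length-tercile-dependent coupling between the myelin (R1) and edge
caliber (COMMIT) weightings; a fraction of near-zero COMMIT streamline
weights to exercise filtering; and functional networks sampled from a
covariance that mixes the identity with a structure-derived matrix.

Couplings are imposed through a Gaussian copula on edge-level latent
variables: a target Spearman rho corresponds to a latent Pearson
correlation r = 2 sin(pi * rho / 6), and any monotone marginal transform
(lognormal quantiles for streamline weights, affine for tractometry)
preserves the Spearman value exactly.  Every output is a pure function of
(config, seed); one master seed yields fixed per-operation child seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components, minimum_spanning_tree
from scipy.special import ndtri

from . import build as _build
from .core import (
    METRICS,
    ConsistencyError,
    Parcellation,
    StreamlineTable,
    SubjectEnsemble,
    WeightedConnectome,
)

__all__ = [
    "GeneratorConfig",
    "Cohort",
    "rho_to_latent",
    "generate_parcellation",
    "generate_binary_topology",
    "generate_streamline_table",
    "generate_cohort",
    "simulate_cohort",
    "generate_fc",
    "planted_rich_club_network",
    "shuffle_weights",
]

# child-seed offsets (stream-of-seeds discipline: one master seed, fixed keys)
_OP_PARCELLATION = 0
_OP_TOPOLOGY = 1
_OP_LATENTS = 2
_OP_SUBJECT = 3  # + subject index in the spawn key
_OP_FC = 4
_OP_TABLE = 5


def _rng(seed: int, op: int, extra: tuple = ()) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(op, *extra)))


def rho_to_latent(rho: float) -> float:
    """Latent Pearson correlation giving Spearman ``rho`` under a Gaussian copula."""
    if not -1 < rho < 1:
        raise ValueError("target Spearman must be in (-1, 1)")
    return 2.0 * math.sin(math.pi * rho / 6.0)


def _default_rho_len() -> dict:
    # Sign pattern of the weight-length couplings: negative for the
    # streamline-specific weightings and RD, positive for R1/FA/ICVF.
    return {
        "NoS": -0.45,
        "SIFT2": -0.45,
        "COMMIT": -0.60,
        "R1": 0.40,
        "FA": 0.30,
        "ICVF": 0.30,
        "RD": -0.30,
    }


def _default_tract_marginals() -> dict:
    # (mean, sd) of the near-normal tractometry edge distributions; units:
    # R1 in 1/s, FA and ICVF dimensionless, RD in um^2/ms.
    return {"R1": (0.95, 0.10), "FA": (0.45, 0.08), "RD": (0.70, 0.08), "ICVF": (0.55, 0.08)}


@dataclass
class GeneratorConfig:
    """All knobs of the synthetic cohort; ``seed`` is mandatory."""

    n_nodes: int = 90
    n_modules: int = 8
    n_subjects: int = 10
    target_density: float = 0.25
    distance_decay: float = 0.02  # per mm
    modular_bias: float = 1.5
    streamline_count_dispersion: float = 0.7  # lognormal sigma of counts
    count_log_mean: float = 2.0  # median ~7 streamlines per edge
    commit_zero_fraction: float = 0.3
    rho_len: dict = field(default_factory=_default_rho_len)
    rho_myelin_short: float = -0.60  # R1-COMMIT residual coupling, shortest tercile
    rho_myelin_long: float = 0.35  # reversed sign in the longest tercile
    strength_shared_frac: float = 0.5  # shared variance of NoS/SIFT2/COMMIT residuals
    fc_coupling: float = 0.6
    fc_T: int = 500
    subject_noise_sd: float = 0.2  # multiplicative exp(N(0, sd^2)) on weights
    edge_dropout: float = 0.05
    tract_marginals: dict = field(default_factory=_default_tract_marginals)
    tract_streamline_sd: float = 0.01  # per-streamline median jitter
    tract_subject_sd: float = 0.005  # subject-level tractometry jitter
    commit_log_mean: float = -4.0
    commit_log_sd: float = 0.9
    sift2_log_mean: float = -2.0
    sift2_log_sd: float = 0.8
    length_jitter_sd: float = 0.05
    box_mm: float = 150.0
    seed: int | None = None

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory for reproducibility")
        if self.n_nodes < 2 * self.n_modules:
            raise ValueError("need n_nodes >= 2 * n_modules")
        if not 0 < self.target_density <= 1:
            raise ValueError("target_density must be in (0, 1]")
        if self.distance_decay < 0 or self.modular_bias < 0:
            raise ValueError("distance_decay and modular_bias must be >= 0")
        if not 0 <= self.commit_zero_fraction < 1:
            raise ValueError("commit_zero_fraction must be in [0, 1)")
        if not 0 <= self.fc_coupling < 1:
            raise ValueError("fc_coupling must be in [0, 1)")
        if not 0 <= self.edge_dropout < 1:
            raise ValueError("edge_dropout must be in [0, 1)")
        if self.fc_T < 3:
            raise ValueError("fc_T must be >= 3")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name, rho in self.rho_len.items():
            if not -1 < rho < 1:
                raise ValueError(f"rho_len[{name!r}] must be in (-1, 1)")


# ---------------------------------------------------------------------------
# geometry and topology
# ---------------------------------------------------------------------------


def generate_parcellation(cfg: GeneratorConfig) -> Parcellation:
    """Nodes clustered by module in a cube; lognormal volumes around 1,000 mm^3."""
    cfg.validate()
    rng = _rng(cfg.seed, _OP_PARCELLATION)
    n, k = cfg.n_nodes, cfg.n_modules
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    from .core import MODULES

    mods = list(MODULES[:k]) if k <= len(MODULES) else None
    if mods is None:
        raise ValueError(f"at most {len(MODULES)} modules supported")
    lo, hi = 0.2 * cfg.box_mm, 0.8 * cfg.box_mm
    centers = rng.uniform(lo, hi, size=(k, 3))
    module = np.repeat(np.asarray(mods, dtype=object), sizes)
    coords = centers[np.repeat(np.arange(k), sizes)] + rng.normal(0, 12.0, size=(n, 3))
    volume = rng.lognormal(mean=math.log(1000.0), sigma=0.3, size=n)
    node_ids = [f"n{idx:03d}" for idx in range(n)]
    labels = [f"{module[idx]}_{idx}" for idx in range(n)]
    return Parcellation(node_ids, labels, module, volume, coords)


def generate_binary_topology(parc: Parcellation, cfg: GeneratorConfig) -> WeightedConnectome:
    """Distance-decaying, module-biased random graph, forced connected via MST.

    Edge probability is proportional to exp(-lambda * d_ij) * (1 + beta *
    [same module]) and rescaled (with clipping at 1) so the expected density
    matches ``target_density``.
    """
    cfg.validate()
    rng = _rng(cfg.seed, _OP_TOPOLOGY)
    n = parc.n_nodes
    n_pairs = n * (n - 1) // 2
    if cfg.target_density < (n - 1) / n_pairs:
        raise ValueError("target_density below the connectivity floor (spanning tree)")
    d = parc.distance_matrix()
    iu, ju = np.triu_indices(n, k=1)
    same = parc.module[iu] == parc.module[ju]
    score = np.exp(-cfg.distance_decay * d[iu, ju]) * (1.0 + cfg.modular_bias * same)

    def expected(c):
        return np.minimum(1.0, c * score).mean()

    lo_c, hi_c = 0.0, cfg.target_density / score.mean()
    while expected(hi_c) < cfg.target_density and hi_c < 1e12:
        hi_c *= 2.0
    for _ in range(80):
        mid = (lo_c + hi_c) / 2.0
        if expected(mid) < cfg.target_density:
            lo_c = mid
        else:
            hi_c = mid
    p = np.minimum(1.0, hi_c * score)
    adj_u = rng.random(n_pairs) < p
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[adj_u], ju[adj_u]] = True
    # force connectivity by adding the Euclidean minimum-spanning-tree edges
    mst = minimum_spanning_tree(sparse.csr_matrix(np.triu(d, 1))).toarray()
    adj |= mst > 0
    adj |= adj.T
    n_comp, _ = connected_components(sparse.csr_matrix(adj), directed=False)
    if n_comp != 1:  # pragma: no cover - MST guarantees this
        raise ConsistencyError("generated topology is disconnected")
    return WeightedConnectome("binary", "group", adj.astype(float))


# ---------------------------------------------------------------------------
# edge-level latents (shared across subjects of a cohort)
# ---------------------------------------------------------------------------


@dataclass
class _EdgeBase:
    iu: np.ndarray
    ju: np.ndarray
    d: np.ndarray  # Euclidean endpoint distance per edge (mm)
    volfac: np.ndarray  # mean endpoint volume per edge
    count_log: np.ndarray  # log of the latent streamline count
    v_commit: np.ndarray  # target volume-normalized COMMIT edge value
    v_sift2: np.ndarray
    metrics: dict  # metric -> per-edge latent value

    @property
    def n_edges(self) -> int:
        return len(self.d)


def _edge_base(adj: np.ndarray, parc: Parcellation, cfg: GeneratorConfig, rng) -> _EdgeBase:
    n = parc.n_nodes
    iu, ju = np.triu_indices(n, k=1)
    keep = adj[iu, ju] != 0
    iu, ju = iu[keep], ju[keep]
    d = parc.distance_matrix()[iu, ju]
    m = len(d)
    volfac = (parc.volume[iu] + parc.volume[ju]) / 2.0
    # normal score of the length rank; ties are broken by stable argsort
    ranks = np.empty(m)
    ranks[np.argsort(d, kind="stable")] = np.arange(m)
    z_d = ndtri((ranks + 0.5) / m)
    u_len = (ranks + 0.5) / m

    def latent(rho, eta=None):
        r = rho_to_latent(rho)
        if eta is None:
            eta = rng.standard_normal(m)
        return r * z_d + math.sqrt(1.0 - r * r) * eta

    # NoS, SIFT2 and COMMIT are all connection-strength estimates: their
    # length-independent variation shares a common factor
    f = cfg.strength_shared_frac
    eta_shared = rng.standard_normal(m)

    def strength_eta():
        return math.sqrt(f) * eta_shared + math.sqrt(1.0 - f) * rng.standard_normal(m)

    g_count = latent(cfg.rho_len["NoS"], strength_eta())
    g_sift2 = latent(cfg.rho_len["SIFT2"], strength_eta())
    eta_c = strength_eta()
    r_c = rho_to_latent(cfg.rho_len["COMMIT"])
    g_commit = r_c * z_d + math.sqrt(1.0 - r_c * r_c) * eta_c

    metrics = {}
    for met in ("FA", "RD", "ICVF"):
        mean, sd = cfg.tract_marginals[met]
        metrics[met] = mean + sd * latent(cfg.rho_len[met])
    # R1: length coupling plus a tercile-dependent coupling to the
    # length-independent part of the COMMIT latent (eta_c)
    c_t = np.zeros(m)
    c_t[u_len < 1.0 / 3.0] = rho_to_latent(cfg.rho_myelin_short)
    c_t[u_len > 2.0 / 3.0] = rho_to_latent(cfg.rho_myelin_long)
    r_r1 = rho_to_latent(cfg.rho_len["R1"])
    resid = c_t * eta_c + np.sqrt(1.0 - c_t**2) * rng.standard_normal(m)
    g_r1 = r_r1 * z_d + math.sqrt(1.0 - r_r1 * r_r1) * resid
    mean, sd = cfg.tract_marginals["R1"]
    metrics["R1"] = mean + sd * g_r1

    sig = cfg.streamline_count_dispersion
    return _EdgeBase(
        iu=iu,
        ju=ju,
        d=d,
        volfac=volfac,
        count_log=cfg.count_log_mean + sig * g_count,
        v_commit=np.exp(cfg.commit_log_mean + cfg.commit_log_sd * g_commit),
        v_sift2=np.exp(cfg.sift2_log_mean + cfg.sift2_log_sd * g_sift2),
        metrics=metrics,
    )


def _materialize_table(
    base: _EdgeBase,
    cfg: GeneratorConfig,
    rng,
    subject_id: str,
    noise_sd: float = 0.0,
    dropout: float = 0.0,
) -> StreamlineTable:
    """Turn edge-level latents into a per-streamline table.

    Subject noise multiplies edge totals by exp(N(0, sd^2)); the latent
    streamline counts are engineered on the *volume-normalized* scale, so the
    materialized count carries the volume factor and the builder's
    normalization recovers the target value.
    """
    import pandas as pd

    m = base.n_edges
    keep = np.ones(m, dtype=bool)
    if dropout > 0:
        keep = rng.random(m) >= dropout
    idx = np.flatnonzero(keep)
    noise = lambda: noise_sd * rng.standard_normal(m) if noise_sd > 0 else np.zeros(m)
    # counts carry only the *relative* volume factor: the builder divides by
    # the absolute factor, so the normalized value recovers the target latent
    # up to a global constant while row counts stay at the configured scale
    rel_vol = np.log(base.volfac) - np.mean(np.log(base.volfac))
    counts = np.maximum(
        1, np.rint(np.exp(base.count_log + noise() + rel_vol)).astype(np.int64)
    )[idx]
    x_tot = (base.v_commit * np.exp(noise()) * base.volfac)[idx]
    s_tot = (base.v_sift2 * np.exp(noise()) * base.volfac)[idx]
    met_edge = {
        met: (vals + (cfg.tract_subject_sd * rng.standard_normal(m) if noise_sd > 0 else 0.0))[idx]
        for met, vals in base.metrics.items()
    }

    rows_edge = np.repeat(np.arange(len(idx)), counts)
    n_rows = len(rows_edge)
    d_row = base.d[idx][rows_edge]
    lengths = d_row * (1.0 + cfg.length_jitter_sd * rng.standard_normal(n_rows))
    lengths = np.maximum(lengths, np.maximum(1.0, 0.1 * d_row))

    # COMMIT streamline weights: a configured fraction falls below the
    # filtering threshold; the edge total is carried by the survivors.
    zero = rng.random(n_rows) < cfg.commit_zero_fraction
    shares = rng.gamma(1.0, 1.0, size=n_rows)
    shares[zero] = 0.0
    denom = np.zeros(len(idx))
    np.add.at(denom, rows_edge, shares)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = shares / np.where(denom[rows_edge] > 0, denom[rows_edge], 1.0)
    w_commit = frac * x_tot[rows_edge]
    w_commit[zero] = 1e-13 * rng.random(int(zero.sum()))

    s_shares = rng.gamma(1.0, 1.0, size=n_rows)
    s_denom = np.zeros(len(idx))
    np.add.at(s_denom, rows_edge, s_shares)
    w_sift2 = s_shares / s_denom[rows_edge] * s_tot[rows_edge]

    data = {
        "node_i": base.iu[idx][rows_edge],
        "node_j": base.ju[idx][rows_edge],
        "length_mm": lengths,
        "w_commit": w_commit,
        "w_sift2": w_sift2,
    }
    for met in METRICS:
        jitter = cfg.tract_streamline_sd * rng.standard_normal(n_rows)
        data[f"med_{met}"] = met_edge[met][rows_edge] + jitter
    return StreamlineTable(df=pd.DataFrame(data), subject_id=subject_id)


def generate_streamline_table(
    adj: WeightedConnectome, parc: Parcellation, cfg: GeneratorConfig
) -> StreamlineTable:
    """One streamline table on the given binary topology (no subject noise)."""
    cfg.validate()
    base = _edge_base(adj.binary(), parc, cfg, _rng(cfg.seed, _OP_LATENTS))
    return _materialize_table(base, cfg, _rng(cfg.seed, _OP_TABLE), "base")


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass
class Cohort:
    """A generated cohort plus its derived group-level artifacts."""

    config: GeneratorConfig
    parcellation: Parcellation
    topology: WeightedConnectome
    ensembles: dict  # weight_name -> SubjectEnsemble (8 SC + FC)
    mask: WeightedConnectome  # group consensus mask
    group: dict  # weight_name -> group-level WeightedConnectome


def generate_cohort(cfg: GeneratorConfig) -> dict:
    """Map weight_name -> SubjectEnsemble for the eight SC weightings + FC.

    One group topology is shared; each subject gets independent edge dropout
    and multiplicative weight noise, then all weightings are built through
    the standard construction pipeline (streamline filter, builders, node
    volume normalization, edge-level COMMIT filter).
    """
    return simulate_cohort(cfg).ensembles


def simulate_cohort(cfg: GeneratorConfig) -> Cohort:
    cfg.validate()
    parc = generate_parcellation(cfg)
    topo = generate_binary_topology(parc, cfg)
    base = _edge_base(topo.binary(), parc, cfg, _rng(cfg.seed, _OP_LATENTS))

    per_weight: dict = {name: [] for name in _build.RECIPES}
    # with no subject noise and no dropout the cohort is deterministic by
    # contract: every subject shares one materialization stream
    degenerate = cfg.subject_noise_sd == 0 and cfg.edge_dropout == 0
    for s in range(cfg.n_subjects):
        rng_s = _rng(cfg.seed, _OP_SUBJECT, (0 if degenerate else s,))
        table = _materialize_table(
            base,
            cfg,
            rng_s,
            subject_id=f"sub-{s:02d}",
            noise_sd=cfg.subject_noise_sd,
            dropout=cfg.edge_dropout,
        )
        nets = _build.build_all_weightings(table, parc)
        for name, net in nets.items():
            per_weight[name].append(net)

    ensembles = {
        name: SubjectEnsemble(parc, name, nets) for name, nets in per_weight.items()
    }
    ensembles = _build.apply_commit_edge_filter(ensembles, ensembles["COMMIT"])
    mask = _build.consensus_mask(ensembles["COMMIT"], fraction=0.5)
    group = {}
    for name, ens in ensembles.items():
        group[name], _ = _build.group_average(ens, mask)

    fc_ens = generate_fc(group["COMMIT"], cfg)
    ensembles["FC"] = SubjectEnsemble(parc, "FC", fc_ens.subjects)
    group["FC"], _ = _build.group_average(ensembles["FC"], mask)
    return Cohort(cfg, parc, topo, ensembles, mask, group)


# ---------------------------------------------------------------------------
# functional connectivity
# ---------------------------------------------------------------------------


def _nearest_pd_correlation(mat: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clipped positive-definite repair, rescaled to unit diagonal."""
    sym = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(sym)
    vals = np.maximum(vals, floor)
    repaired = (vecs * vals) @ vecs.T
    dd = np.sqrt(np.diag(repaired))
    repaired = repaired / np.outer(dd, dd)
    if np.linalg.eigvalsh(repaired).min() <= 0:
        raise ConsistencyError("positive-definite repair of the FC covariance failed")
    return repaired


def generate_fc(group_sc: WeightedConnectome, cfg: GeneratorConfig) -> SubjectEnsemble:
    """Per-subject FC from Gaussian time series with SC-derived covariance.

    Sigma = (1 - c) I + c R, where R is the positive-definite repair of
    I + A and A carries rank-normalized SC weights (a monotone transform of
    the weights, so every configured Spearman relationship survives).  Each
    subject's network is the Fisher-Z Pearson correlation of T samples.
    """
    cfg.validate()
    if np.any(group_sc.matrix < 0):
        raise ConsistencyError("FC generation expects a nonnegative SC network")
    rng = _rng(cfg.seed, _OP_FC)
    n = group_sc.n_nodes
    w = group_sc.matrix
    iu, ju = np.triu_indices(n, k=1)
    vals = w[iu, ju]
    nz = vals > 0
    a = np.zeros_like(vals)
    if nz.sum() > 0:
        ranks = np.empty(int(nz.sum()))
        ranks[np.argsort(vals[nz], kind="stable")] = np.arange(int(nz.sum()))
        a[nz] = 0.9 * (ranks + 1.0) / (nz.sum() + 1.0)
    A = np.zeros((n, n))
    A[iu, ju] = a
    A += A.T
    c = cfg.fc_coupling
    if c > 0:
        R = _nearest_pd_correlation(np.eye(n) + A)
        sigma = (1.0 - c) * np.eye(n) + c * R
    else:
        sigma = np.eye(n)
    chol = np.linalg.cholesky(sigma)
    nets = []
    parc_n = n
    for s in range(cfg.n_subjects):
        ts = chol @ rng.standard_normal((parc_n, cfg.fc_T))
        nets.append(_build.build_fc(ts, subject_id=f"sub-{s:02d}"))
    # SubjectEnsemble wants a parcellation; FC alone does not carry one, so a
    # caller with a real parcellation should rewrap.  Here we build a minimal
    # stand-in only if needed by direct use.
    from .core import MODULES

    parc = Parcellation(
        node_ids=[f"n{k:03d}" for k in range(n)],
        labels=[f"fc_{k}" for k in range(n)],
        module=np.asarray([MODULES[0]] * n, dtype=object),
        volume=np.ones(n),
        coords=np.zeros((n, 3)),
    )
    return SubjectEnsemble(parc, "FC", nets)


# ---------------------------------------------------------------------------
# planted structure for rich-club recovery checks
# ---------------------------------------------------------------------------


def planted_rich_club_network(
    n_nodes: int = 90,
    n_core: int = 15,
    periphery_degree: int = 20,
    core_degree: int = 60,
    weight_sigma: float = 0.25,
    core_gain: float = 2.5,
    seed: int = 0,
) -> WeightedConnectome:
    """Degree-typical network whose first ``n_core`` nodes form a high-weight core.

    The topology has a bimodal degree sequence (core nodes at
    ``core_degree``, the rest at ``periphery_degree``) and is sampled by
    heavy Maslov-Sneppen randomization of a deterministic realization, so
    the observed graph is itself typical of the degree-preserving null
    distribution and any rich-club signal is carried by the *weights*:
    lognormal(0, weight_sigma) everywhere, multiplied by ``core_gain`` on
    core-core edges.  Shuffling the weights on this topology therefore
    abolishes the planted structure.
    """
    import networkx as nx

    from .nulls import rewire_degree_preserving

    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    n = n_nodes
    deg_seq = [core_degree] * n_core + [periphery_degree] * (n - n_core)
    if sum(deg_seq) % 2:
        deg_seq[-1] += 1
    g = nx.havel_hakimi_graph(deg_seq)
    # havel-hakimi orders nodes by degree, so node 0..n_core-1 are the core
    adj = np.zeros((n, n))
    for a, b in g.edges():
        adj[a, b] = adj[b, a] = 1.0
    topo = WeightedConnectome("binary", "planted", adj)
    for attempt in range(10):
        randomized = rewire_degree_preserving(topo, swaps_per_edge=50, seed=seed + attempt)
        a = randomized.matrix != 0
        n_comp, _ = connected_components(sparse.csr_matrix(a), directed=False)
        if n_comp == 1:
            break
    else:  # pragma: no cover - dense bimodal graphs are essentially never disconnected
        raise ConsistencyError("could not sample a connected planted topology")
    core = np.zeros(n, dtype=bool)
    core[:n_core] = True
    w = np.zeros((n, n))
    ii, jj = np.where(np.triu(a, 1))
    vals = rng.lognormal(0.0, weight_sigma, size=len(ii))
    vals[core[ii] & core[jj]] *= core_gain
    w[ii, jj] = vals
    w += w.T
    return WeightedConnectome("COMMIT", "planted", w)


def shuffle_weights(net: WeightedConnectome, seed: int) -> WeightedConnectome:
    """Randomly permute the nonzero edge weights on the fixed topology."""
    rng = np.random.default_rng(seed)
    w = net.matrix.copy()
    iu, ju = np.where(np.triu(w, 1) != 0)
    vals = w[iu, ju]
    perm = rng.permutation(len(vals))
    w[iu, ju] = vals[perm]
    w[ju, iu] = vals[perm]
    return WeightedConnectome(net.weight_name, net.subject_id + "-shuffled", w)
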