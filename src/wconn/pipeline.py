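"""End-to-end orchestration: simulate -> build -> stats -> nulls -> topology.

A run is driven by a single JSON config; every random draw derives from the
config seed; a manifest records the config hash, per-stage file hashes and
seeds, so re-running with an unchanged config skips stages whose inputs are
unchanged and two runs with the same config produce identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nulls as _nulls
from . import stats as _stats
from . import synth as _synth
from . import topology as _topo
from .core import (
    SC_WEIGHTS,
    edge_vectorize,
    write_matrix,
    write_parcellation,
    write_streamlines,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunManifest", "validate_config", "run_pipeline", "PRESETS"]

#: Fixed constants of the "paper" preset: consensus threshold, streamline
#: filter threshold, bin count, and the two null-ensemble sizes.
PRESETS = {
    "desk": dict(
        n_nodes=60,
        n_subjects=6,
        n_nulls_smallworld=20,
        n_nulls_richclub=50,
        n_perm=1000,
        swaps_per_edge=20,
        fc_T=300,
    ),
    "paper": dict(
        n_nodes=414,
        n_subjects=50,
        n_nulls_smallworld=50,
        n_nulls_richclub=1000,
        n_perm=10000,
        swaps_per_edge=100,
        fc_T=700,
    ),
}


@dataclass
class RunConfig:
    preset: str = "desk"
    seed: int = 0
    # stage toggles
    stages: list = field(default_factory=lambda: ["simulate", "build", "stats", "nulls", "topology"])
    # simulate
    n_nodes: int = 60
    n_subjects: int = 6
    fc_T: int = 300
    # build
    commit_threshold: float = 1e-12
    consensus: float = 0.5
    # stats
    n_perm: int = 1000
    n_bins: int = 6
    # nulls / topology
    n_nulls_smallworld: int = 20
    n_nulls_richclub: int = 50
    swaps_per_edge: int = 20
    topology_weights: list = field(default_factory=lambda: ["COMMIT", "R1"])

    def validate(self):
        if self.preset not in PRESETS:
            raise ValueError(f"preset: must be one of {sorted(PRESETS)}")
        if not 0 < self.consensus <= 1:
            raise ValueError("consensus: must be in (0, 1]")
        if self.commit_threshold < 0:
            raise ValueError("commit_threshold: must be >= 0")
        if self.n_bins != 6:
            raise ValueError("n_bins: the binning rule defines exactly 6 bins")
        for key in ("n_nodes", "n_subjects", "n_perm", "n_nulls_smallworld",
                    "n_nulls_richclub", "swaps_per_edge", "fc_T"):
            if getattr(self, key) < 1:
                raise ValueError(f"{key}: must be a positive integer")
        unknown = set(self.stages) - {"simulate", "build", "stats", "nulls", "topology"}
        if unknown:
            raise ValueError(f"stages: unknown stage(s) {sorted(unknown)}")


def validate_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a JSON config; fill defaults; reject unknown keys.

    An empty or missing file yields the full-default desk config.  The
    "paper" preset pins n_nulls = 50/1000, consensus 0.5, commit threshold
    1e-12 and 6 bins.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text().strip()
        if text:
            raw = json.loads(text)
            if not isinstance(raw, dict):
                raise ValueError("config must be a JSON object")
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    preset = raw.get("preset", "desk")
    if preset not in PRESETS:
        raise ValueError(f"preset: must be one of {sorted(PRESETS)}")
    merged = dict(PRESETS[preset])
    merged.update(raw)
    merged["preset"] = preset
    cfg = RunConfig(**merged)
    cfg.validate()
    return cfg


@dataclass
class RunManifest:
    config_hash: str
    seeds: dict
    stages: dict = field(default_factory=dict)  # stage -> {inputs, outputs, wall_s}
    versions: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def _hash_bytes(b: bytes) -> str:
    return hashlib.sha256(b).hexdigest()


def _hash_file(path: Path) -> str:
    return _hash_bytes(path.read_bytes())


def _hash_config(cfg: RunConfig) -> str:
    return _hash_bytes(json.dumps(dataclasses.asdict(cfg), sort_keys=True).encode())


def _log(stage: str, **kv):
    logger.info("stage=%s %s", stage, " ".join(f"{k}={v}" for k, v in kv.items()))


def _generator_config(cfg: RunConfig) -> _synth.GeneratorConfig:
    return _synth.GeneratorConfig(
        n_nodes=cfg.n_nodes, n_subjects=cfg.n_subjects, fc_T=cfg.fc_T, seed=cfg.seed
    )


def run_pipeline(cfg: RunConfig, out_dir) -> RunManifest:
    """Execute the configured stages in dependency order under ``out_dir``.

    Stages whose recorded input hashes are unchanged since the previous run
    are skipped.  Artifacts are delimited text and JSON throughout.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config_echo.json").write_text(
        json.dumps(dataclasses.asdict(cfg), indent=2, sort_keys=True)
    )
    cfg_hash = _hash_config(cfg)
    manifest_path = out / "manifest.json"
    previous = {}
    if manifest_path.exists():
        try:
            previous = json.loads(manifest_path.read_text())
        except json.JSONDecodeError:
            previous = {}
    import numpy
    import scipy

    manifest = RunManifest(
        config_hash=cfg_hash,
        seeds={"master": cfg.seed},
        versions={"numpy": numpy.__version__, "scipy": scipy.__version__},
    )

    cohort = None  # in-memory carry-over to avoid re-reads between stages

    def stage_done(name: str, inputs: dict, outputs: list, t0: float):
        manifest.stages[name] = {
            "inputs": inputs,
            "outputs": {str(p.relative_to(out)): _hash_file(p) for p in outputs},
            "wall_s": round(time.time() - t0, 3),
            "skipped": False,
        }

    def can_skip(name: str, inputs: dict) -> bool:
        prev = previous.get("stages", {}).get(name)
        if not prev or prev.get("inputs") != inputs or previous.get("config_hash") != cfg_hash:
            return False
        for rel, digest in prev.get("outputs", {}).items():
            p = out / rel
            if not p.exists() or _hash_file(p) != digest:
                return False
        manifest.stages[name] = dict(prev, skipped=True)
        return True

    # ---- simulate -------------------------------------------------------
    if "simulate" in cfg.stages:
        inputs = {"config": cfg_hash}
        if not can_skip("simulate", inputs):
            t0 = time.time()
            gcfg = _generator_config(cfg)
            cohort = _synth.simulate_cohort(gcfg)
            outputs = [write_parcellation(cohort.parcellation, out / "parcellation.tsv")]
            for s in range(cfg.n_subjects):
                rng_s = np.random.default_rng(
                    np.random.SeedSequence(cfg.seed, spawn_key=(3, s))
                )
                table = _synth._materialize_table(
                    _synth._edge_base(
                        cohort.topology.binary(),
                        cohort.parcellation,
                        gcfg,
                        _synth._rng(gcfg.seed, _synth._OP_LATENTS),
                    ),
                    gcfg,
                    rng_s,
                    subject_id=f"sub-{s:02d}",
                    noise_sd=gcfg.subject_noise_sd,
                    dropout=gcfg.edge_dropout,
                )
                outputs.append(
                    write_streamlines(
                        table, cohort.parcellation, out / "streamlines" / f"sub-{s:02d}.tsv"
                    )
                )
            for s, net in enumerate(cohort.ensembles["FC"].subjects):
                outputs.append(
                    write_matrix(net, out / "fc" / f"sub-{s:02d}.csv", cohort.parcellation.node_ids)
                )
            _log("simulate", seed=cfg.seed, n_subjects=cfg.n_subjects,
                 n_streamline_files=cfg.n_subjects)
            stage_done("simulate", inputs, outputs, t0)

    if cohort is None and any(s in cfg.stages for s in ("build", "stats", "nulls", "topology")):
        cohort = _synth.simulate_cohort(_generator_config(cfg))

    # ---- build ----------------------------------------------------------
    if "build" in cfg.stages:
        inputs = {"config": cfg_hash}
        if not can_skip("build", inputs):
            t0 = time.time()
            ids = cohort.parcellation.node_ids
            outputs = [write_matrix(cohort.mask, out / "networks" / "mask.csv", ids)]
            for name, net in cohort.group.items():
                outputs.append(write_matrix(net, out / "networks" / "group" / f"{name}.csv", ids))
            for name, ens in cohort.ensembles.items():
                for net in ens.subjects:
                    outputs.append(
                        write_matrix(
                            net, out / "networks" / name / f"{net.subject_id}.csv", ids
                        )
                    )
            n_masked = int(cohort.mask.matrix.sum() // 2)
            report = {
                "n_masked_edges": n_masked,
                "density": cohort.group["COMMIT"].density(),
                "commit_threshold": cfg.commit_threshold,
                "consensus": cfg.consensus,
            }
            p = out / "build_report.json"
            p.write_text(json.dumps(report, indent=2))
            outputs.append(p)
            _log("build", n_masked_edges=n_masked)
            stage_done("build", inputs, outputs, t0)

    # ---- stats ----------------------------------------------------------
    if "stats" in cfg.stages:
        inputs = {"config": cfg_hash}
        if not can_skip("stats", inputs):
            t0 = time.time()
            outputs = run_stats_stage(cfg, cohort, out / "stats")
            _log("stats", n_perm=cfg.n_perm)
            stage_done("stats", inputs, outputs, t0)

    # ---- nulls ----------------------------------------------------------
    null_ens = {}

    def make_ensembles():
        for w_idx, name in enumerate(cfg.topology_weights):
            if name in null_ens:
                continue
            null_ens[name] = _nulls.generate_null_ensemble(
                cohort.group[name],
                n_nulls=cfg.n_nulls_smallworld,
                kind="weighted",
                swaps_per_edge=cfg.swaps_per_edge,
                seed=cfg.seed + 1000 + w_idx,
            )

    if "nulls" in cfg.stages:
        inputs = {"config": cfg_hash}
        if not can_skip("nulls", inputs):
            t0 = time.time()
            make_ensembles()
            outputs = []
            ids = cohort.parcellation.node_ids
            for name, ens in null_ens.items():
                for k, sur in enumerate(ens.surrogates):
                    outputs.append(
                        write_matrix(sur, out / "nulls" / name / f"null-{k:03d}.csv", ids)
                    )
                p = out / "nulls" / name / "ensemble.json"
                p.write_text(
                    json.dumps(
                        {
                            "kind": ens.kind,
                            "n": len(ens),
                            "seed": ens.seed,
                            "swaps": [int(x) for x in ens.swaps],
                        },
                        indent=2,
                    )
                )
                outputs.append(p)
            _log("nulls", n_ensembles=len(null_ens), n_each=cfg.n_nulls_smallworld)
            stage_done("nulls", inputs, outputs, t0)

    # ---- topology -------------------------------------------------------
    if "topology" in cfg.stages:
        inputs = {"config": cfg_hash}
        if not can_skip("topology", inputs):
            t0 = time.time()
            make_ensembles()
            outputs = run_topology_stage(cfg, cohort, null_ens, out / "topology")
            _log("topology", weights=",".join(cfg.topology_weights))
            stage_done("topology", inputs, outputs, t0)

    manifest_path.write_text(manifest.to_json())
    return manifest


def run_stats_stage(cfg: RunConfig, cohort, out: Path) -> list:
    """Edgewise statistics of a cohort; returns the list of files written."""
    import pandas as pd

    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    mask = cohort.mask
    lengths_group = edge_vectorize(cohort.group["LoS"], mask)

    # CQD tables
    rows = []
    for name in SC_WEIGHTS + ("FC",):
        ens = cohort.ensembles[name]
        intra = _stats.intra_subject_cqd(ens, mask)
        inter = _stats.inter_subject_cqd(ens, mask)
        rows.append(
            {
                "weight": name,
                "intra_cqd_median": float(np.nanmedian(intra)),
                "inter_cqd_median": float(np.nanmedian(inter.values)),
            }
        )
    p = out / "cqd_summary.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    outputs.append(p)

    # residual correlations with FC and R1 + permutation p
    summary = {}
    fc_res = _stats.residualize_on_length(
        edge_vectorize(cohort.group["FC"], mask), lengths_group
    )
    r1_res = _stats.residualize_on_length(
        edge_vectorize(cohort.group["R1"], mask), lengths_group
    )
    for name in ("NoS", "SIFT2", "COMMIT", "R1", "FA", "RD", "ICVF"):
        res = _stats.residualize_on_length(
            edge_vectorize(cohort.group[name], mask), lengths_group
        )
        pr_fc = _stats.permutation_pvalue(
            res.values, fc_res.values, n_perm=cfg.n_perm, seed=cfg.seed + 7
        )
        entry = {"rho_fc_residual": pr_fc.observed, "p_perm_fc": pr_fc.p}
        if name != "R1":
            pr_r1 = _stats.permutation_pvalue(
                res.values, r1_res.values, n_perm=cfg.n_perm, seed=cfg.seed + 8
            )
            entry.update({"rho_r1_residual": pr_r1.observed, "p_perm_r1": pr_r1.p})
        summary[name] = entry
    p = out / "summary.json"
    p.write_text(json.dumps(summary, indent=2))
    outputs.append(p)

    # binned CQD profiles
    bins = _stats.make_bins(lengths_group.values)
    rows = []
    for name in ("NoS", "SIFT2", "COMMIT", "R1", "FA", "RD", "ICVF", "FC"):
        vals = edge_vectorize(cohort.group[name], mask).values
        per_bin, prop = _stats.binned_statistic(vals, lengths_group.values, bins, stat="cqd")
        for b in range(bins.n_bins):
            rows.append({"weight": name, "bin": b + 1, "cqd": per_bin[b], "prop_max": prop[b]})
    p = out / "binned_cqd.csv"
    pd.DataFrame(rows).to_csv(p, index=False)
    outputs.append(p)
    return outputs


def run_topology_stage(cfg: RunConfig, cohort, null_ens: dict, out: Path) -> list:
    """Small-worldness, rich club and hubness for the configured weightings."""
    import pandas as pd

    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    tables = {}
    sw = {}
    for name in cfg.topology_weights:
        net = cohort.group[name]
        ens = null_ens.get(name)
        report = _topo.small_worldness(net, nulls=ens, seed=cfg.seed)
        sw[name] = {"C": report.C, "L": report.L, "S": report.S, "n_nulls": report.n_nulls}
        raw = _topo.rich_club_weighted(net)
        rc_nulls = ens
        if cfg.n_nulls_richclub > len(ens):
            rc_nulls = _nulls.generate_null_ensemble(
                net,
                n_nulls=cfg.n_nulls_richclub,
                kind="weighted",
                swaps_per_edge=cfg.swaps_per_edge,
                seed=cfg.seed + 2000,
            )
        curve = _topo.normalize_rich_club(raw, rc_nulls)
        p = out / f"richclub_{name}.csv"
        pd.DataFrame(
            {"k": curve.k, "phi": curve.phi, "phi_null": curve.phi_null, "phi_norm": curve.phi_norm}
        ).to_csv(p, index=False)
        outputs.append(p)
        tables[name] = _topo.hubness_scores(_topo.centrality_panel(net))
        p = out / f"hubness_{name}.csv"
        t = tables[name]
        pd.DataFrame(
            {
                "node_id": cohort.parcellation.node_ids,
                "strength": t.strength,
                "betweenness": t.betweenness,
                "closeness": t.closeness,
                "eigenvector": t.eigenvector,
                "clustering": t.clustering,
                "score": t.score,
            }
        ).to_csv(p, index=False)
        outputs.append(p)
    p = out / "smallworld.json"
    p.write_text(json.dumps(sw, indent=2))
    outputs.append(p)
    if len(tables) > 1:
        names, dist = _topo.hubness_distance(tables)
        p = out / "hubness_distance.csv"
        pd.DataFrame(dist, index=names, columns=names).to_csv(p)
        outputs.append(p)
    return outputs
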