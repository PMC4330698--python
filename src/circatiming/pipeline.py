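"""End-to-end orchestration: simulate -> dlmo -> prep -> fit -> compare -> recover.

Each stage reads and writes flat text files (CSV tables, key-value truth
records, YAML config) inside a run directory, so any stage can also be run
standalone on externally supplied tables.  All randomness flows from the
configured seed; identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohort, compare, dlmo, lmm, preprocess, recovery

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Resolved configuration of a pipeline run."""

    backend: str = "lmm"  # "lmm" | "mechanistic"
    seed: int = 1
    out_dir: str = "run"
    protocol: dict = field(default_factory=dict)  # ProtocolConfig overrides
    beta: dict | None = None  # lmm backend truth (defaults to reference values)
    re_sd: tuple = cohort.DEFAULT_RE_SD
    outlier_rule: str = "ratio"
    outlier_threshold: float = preprocess.OUTLIER_RATIO_THRESHOLD
    method: str = "ML"
    variance_groups: str = "cell"
    melatonin_noise_log_sd: float = 0.1
    replicates: int = 0  # >0 enables the recovery stage
    run_compare: bool = False

    def protocol_config(self) -> cohort.ProtocolConfig:
        return cohort.ProtocolConfig(**self.protocol)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["re_sd"] = list(self.re_sd)
        return yaml.safe_dump(d, sort_keys=True)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh) or {}
    if "re_sd" in d:
        d["re_sd"] = tuple(d["re_sd"])
    return PipelineConfig(**d)


def _write_truth(truth: cohort.TruthRecord, path: Path) -> None:
    with open(path, "w") as fh:
        for k, v in truth.flat().items():
            fh.write(f"{k}={v}\n")


def _stage(name):
    log.info("stage: %s", name)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every configured stage; returns the run directory.

    Stage outputs: ``trials.csv``/``occasions_raw.csv``, ``melatonin.csv``,
    ``truth.txt``, ``dlmo.csv``, ``occasions.csv`` (+ ``removed.csv``),
    ``fit.csv`` + ``variance_components.csv``, optionally ``compare.csv`` /
    ``compare_lrt.csv`` and ``recovery.csv`` / ``recovery_summary.csv``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.to_yaml())
    cfg = config.protocol_config()
    rng = np.random.default_rng(config.seed)
    spec = lmm.ModelSpec(variance_groups=config.variance_groups)

    _stage("simulate")
    if config.backend == "mechanistic":
        trials, melatonin, truth = cohort.simulate_mechanistic(
            cfg, melatonin_noise_log_sd=config.melatonin_noise_log_sd, rng=rng
        )
        trials.to_csv(out / "trials.csv", index=False)
        melatonin.to_csv(out / "melatonin.csv", index=False)
        _write_truth(truth, out / "truth.txt")

        _stage("dlmo")
        dlmo_table = dlmo.estimate_dlmo_table(melatonin)
        dlmo_table.to_csv(out / "dlmo.csv", index=False)

        _stage("prep")
        occ = preprocess.aggregate_and_ratio(trials)
        kept, removed = preprocess.filter_outliers(
            occ, threshold=config.outlier_threshold, rule=config.outlier_rule
        )
        removed.to_csv(out / "removed.csv", index=False)
        occasions = preprocess.align_to_dlmo(kept, dlmo_table)
    elif config.backend == "lmm":
        occasions, truth = cohort.simulate_from_lmm(
            cfg, beta=config.beta, re_sd=config.re_sd, spec=spec, rng=rng
        )
        _write_truth(truth, out / "truth.txt")
        dlmo_table = truth.dlmo_table()
        dlmo_table.to_csv(out / "dlmo.csv", index=False)
        kept, removed = preprocess.filter_outliers(
            occasions, threshold=config.outlier_threshold, rule=config.outlier_rule
        )
        removed.to_csv(out / "removed.csv", index=False)
        occasions = kept
    else:
        raise ValueError(f"unknown backend {config.backend!r}")
    occasions.to_csv(out / "occasions.csv", index=False)

    _stage("fit")
    f = lmm.fit_occasions(occasions, spec, method=config.method)
    lmm.wald_table(f).to_csv(out / "fit.csv", index=False)
    vc = pd.DataFrame(
        {
            "component": (
                ["sigma"]
                + [f"multiplier:{g}" for g in f.group_names]
                + [f"re_sd:{t}" for t in spec.random_terms]
                + ["loglik", "aic", "n_obs", "n_subjects", "converged"]
            ),
            "value": (
                [f.sigma]
                + [f.var_multipliers[g] for g in f.group_names]
                + list(np.sqrt(np.diag(f.re_cov)))
                + [f.loglik, f.aic, f.n_obs, f.n_subjects, float(f.converged)]
            ),
        }
    )
    vc.to_csv(out / "variance_components.csv", index=False)

    if config.run_compare:
        _stage("compare")
        report = compare.compare_ladder(occasions)
        report.drop(columns=[], inplace=False).to_csv(out / "compare.csv", index=False)
        report.attrs["lrt"].to_csv(out / "compare_lrt.csv", index=False)

    if config.replicates > 0:
        _stage("recover")
        reps = recovery.run_recovery(
            n_replicates=config.replicates,
            seed=config.seed,
            cfg=cfg,
            beta=config.beta,
            re_sd=config.re_sd,
            spec=spec,
            method=config.method,
        )
        reps.to_csv(out / "recovery.csv", index=False)
        summary = recovery.summarize_recovery(reps, beta=config.beta)
        summary.to_csv(out / "recovery_summary.csv", index=False)
        with open(out / "recovery_summary.json", "w") as fh:
            json.dump(summary.set_index("term").to_dict(orient="index"), fh, indent=1)

    return out
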