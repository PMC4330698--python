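"""Parameter-recovery experiments: simulate known-truth cohorts, refit, summarise.

The published coefficient estimates come from 18 subjects' raw data that
is not publicly available, so the pipeline's headline check is recovery:
simulate full-design cohorts from the trajectory model with the reference
coefficients as generating truth, refit each with the from-scratch mixed
model engine, and summarise bias, Monte-Carlo error and Wald coverage per
term.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .cohort import (
    DEFAULT_RE_SD,
    DEFAULT_SIGMA_CELLS,
    REFERENCE_BETA,
    ProtocolConfig,
    simulate_from_lmm,
)
from .lmm import ModelSpec, fit_occasions

__all__ = ["run_recovery", "summarize_recovery"]


def run_recovery(
    n_replicates: int = 20,
    seed: int = 1,
    cfg: ProtocolConfig = ProtocolConfig(),
    beta: dict | None = None,
    re_sd=DEFAULT_RE_SD,
    sigma_cells: dict | None = None,
    spec: ModelSpec = ModelSpec(),
    method: str = "ML",
) -> pd.DataFrame:
    """Fit ``n_replicates`` simulated cohorts; one row per replicate.

    Columns: replicate, converged, se-flagged columns ``se:<term>`` and one
    column per fixed-effect term with the fitted coefficient.  Replicate
    seeds are spawned deterministically from ``seed``.
    """
    if beta is None:
        beta = dict(REFERENCE_BETA)
    root = np.random.SeedSequence(seed)
    rows = []
    for rep, child in enumerate(root.spawn(n_replicates), start=1):
        rng = np.random.default_rng(child)
        occ, _ = simulate_from_lmm(
            cfg, beta=beta, re_sd=re_sd, sigma_cells=sigma_cells, spec=spec, rng=rng
        )
        f = fit_occasions(occ, spec, method=method)
        row = {"replicate": rep, "converged": f.converged, "loglik": f.loglik}
        for name, b, s in zip(f.term_names, f.beta, f.se):
            row[name] = b
            row[f"se:{name}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def summarize_recovery(replicates: pd.DataFrame, beta: dict | None = None) -> pd.DataFrame:
    """Per-term recovery summary: mean, MC standard error, bias, coverage.

    ``mc_se`` is the standard error of the replicate mean; ``coverage`` is
    the fraction of replicates whose value +/- 2*SE Wald interval contains
    the generating coefficient.
    """
    if beta is None:
        beta = dict(REFERENCE_BETA)
    terms = [c for c in replicates.columns
             if c in beta and not c.startswith("se:")]
    n = len(replicates)
    rows = []
    for term in terms:
        est = replicates[term].to_numpy(float)
        se = replicates[f"se:{term}"].to_numpy(float)
        truth = beta[term]
        mean = est.mean()
        mc_se = est.std(ddof=1) / np.sqrt(n)
        cover = np.mean((est - 2 * se <= truth) & (truth <= est + 2 * se))
        rows.append(
            {
                "term": term,
                "truth": truth,
                "mean": mean,
                "mc_se": mc_se,
                "bias": mean - truth,
                "abs_bias_in_mc_se": abs(mean - truth) / mc_se if mc_se > 0 else np.inf,
                "coverage": cover,
            }
        )
    return pd.DataFrame(rows)
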