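"""Candidate trajectory models and likelihood-ratio comparison.

The trajectory of the timing ratio across sustained wakefulness could be
flat, purely circadian (sinusoid), purely homeostatic (saturating
exponential), additive in both, or additionally duration- and
task-specific.  This module fits the named ladder of nested candidates by
maximum likelihood (random-effects structure held fixed) and compares them
with likelihood-ratio tests and AIC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .lmm import FIXED_TERMS, LmmFit, ModelSpec, fit_occasions

__all__ = ["CandidateSet", "default_candidates", "lrt", "compare_ladder"]

_BASE = ("Intercept", "TASK", "STIM", "CR", "TASK:STIM", "TASK:CR")
_SIN = ("sin", "cos")
_EXP = ("exp",)

_LADDER: dict[str, tuple[str, ...]] = {
    "constant": _BASE,
    "exponential_only": _BASE + _EXP,
    "sinusoid_only": _BASE + _SIN,
    "sinusoid_plus_exponential": _BASE + _EXP + _SIN,
    "equal_exponentials": tuple(t for t in FIXED_TERMS if t != "STIM:exp"),
    "full": FIXED_TERMS,
}

#: (reduced, full) pairs compared by LRT in the default ladder.
_NESTINGS = (
    ("constant", "exponential_only"),
    ("constant", "sinusoid_only"),
    ("exponential_only", "sinusoid_plus_exponential"),
    ("sinusoid_only", "sinusoid_plus_exponential"),
    ("sinusoid_plus_exponential", "full"),
    ("equal_exponentials", "full"),
)


@dataclass(frozen=True)
class CandidateSet:
    """Named reduced model specs plus their recorded nesting relations."""

    specs: dict[str, ModelSpec]
    nestings: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for red, full in self.nestings:
            if not self.specs[red].is_nested_in(self.specs[full]):
                raise ValueError(f"{red} is not nested in {full}")


def default_candidates(
    random_terms=("Intercept", "TASK", "STIM"), variance_groups="cell"
) -> CandidateSet:
    """The standard six-model ladder with a shared random/variance structure."""
    specs = {
        name: ModelSpec(
            fixed_terms=terms, random_terms=random_terms, variance_groups=variance_groups
        )
        for name, terms in _LADDER.items()
    }
    return CandidateSet(specs=specs, nestings=_NESTINGS)


def lrt(fit_reduced: LmmFit, fit_full: LmmFit):
    """Likelihood-ratio test of a reduced against a nesting full ML fit.

    Returns (statistic, df, p) with statistic = 2*(ll_full - ll_reduced)
    and df the fixed-parameter count difference.
    """
    if fit_reduced.method != "ML" or fit_full.method != "ML":
        raise ValueError("LRT of fixed effects requires ML fits")
    if fit_reduced.n_obs != fit_full.n_obs:
        raise ValueError("fits are not on identical data")
    if fit_reduced.spec is not None and fit_full.spec is not None:
        if not fit_reduced.spec.is_nested_in(fit_full.spec):
            raise ValueError("reduced model is not nested in the full model")
    df = fit_full.n_params - fit_reduced.n_params
    if df < 0:
        raise ValueError("'full' fit has fewer parameters than 'reduced'")
    statistic = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if statistic < -1e-6:
        raise RuntimeError(
            f"negative LRT statistic {statistic:.3g}: full-model optimum "
            "below the reduced model's; refit with better starts"
        )
    statistic = max(statistic, 0.0)
    p = 1.0 if df == 0 else float(stats.chi2.sf(statistic, df))
    return float(statistic), int(df), p


def compare_ladder(
    occasions: pd.DataFrame, candidates: CandidateSet | None = None
) -> pd.DataFrame:
    """Fit every candidate by ML and report loglik, AIC and nested LRTs.

    Non-converged candidates are reported but excluded from the AIC ranking
    and from LRTs.  Rows are ordered by AIC among converged fits.
    """
    if candidates is None:
        candidates = default_candidates()
    fits: dict[str, LmmFit] = {}
    rows = []
    for name, spec in candidates.specs.items():
        f = fit_occasions(occasions, spec, method="ML")
        fits[name] = f
        rows.append(
            {
                "model": name,
                "n_fixed": len(spec.fixed_terms),
                "n_params": f.n_params,
                "loglik": f.loglik,
                "aic": f.aic,
                "converged": f.converged,
            }
        )
    report = pd.DataFrame(rows)
    ok = report["converged"]
    report.loc[~ok, "aic"] = np.nan
    report = report.sort_values(
        by=["aic"], na_position="last", kind="stable"
    ).reset_index(drop=True)
    lrt_rows = []
    for red, full in candidates.nestings:
        if not (fits[red].converged and fits[full].converged):
            lrt_rows.append({"reduced": red, "full": full, "statistic": np.nan,
                             "df": np.nan, "p": np.nan})
            continue
        s, df, p = lrt(fits[red], fits[full])
        lrt_rows.append({"reduced": red, "full": full, "statistic": s, "df": df, "p": p})
    report.attrs["lrt"] = pd.DataFrame(lrt_rows)
    report.attrs["fits"] = fits
    return report
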