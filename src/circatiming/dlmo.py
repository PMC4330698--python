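"""Dim-light melatonin onset (DLMO) estimation via composite cosinor.

Plasma melatonin sampled hourly across a constant routine is z-score
standardised, fitted with a composite 24 h + 12 h cosine model by linear
least squares, back-transformed to pg/ml, and the DLMO is the earliest
time at which the fitted curve rises from a low background level through
the 10 pg/ml threshold with positive slope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .lmm import amplitude_phase

__all__ = [
    "MelatoninSeries",
    "CosinorFit",
    "fit_composite_cosinor",
    "compute_dlmo",
    "estimate_dlmo_table",
    "DLMO_THRESHOLD_PGML",
    "ASSAY_FLOOR_PGML",
]

#: Threshold (pg/ml) whose upward crossing defines DLMO.
DLMO_THRESHOLD_PGML = 10.0
#: Radioimmunoassay sensitivity floor (pg/ml).
ASSAY_FLOOR_PGML = 2.8


class CosinorError(ValueError):
    """Series unsuitable for composite-cosinor fitting."""


@dataclass(frozen=True)
class MelatoninSeries:
    """Hourly melatonin concentrations for one subject-epoch."""

    times: np.ndarray  # clock hours, strictly increasing
    conc: np.ndarray  # pg/ml, non-negative

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        c = np.asarray(self.conc, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "conc", c)
        if t.ndim != 1 or t.shape != c.shape:
            raise CosinorError("times and conc must be 1-d arrays of equal length")
        if np.any(np.diff(t) <= 0):
            raise CosinorError("times must be strictly increasing")
        if np.any(c < 0):
            raise CosinorError("concentrations must be non-negative")

    def validate_for_fit(self):
        if len(self.times) < 8 or (self.times[-1] - self.times[0]) < 24.0:
            raise CosinorError("need >= 8 samples spanning >= 24 h")


@dataclass(frozen=True)
class CosinorFit:
    """Composite 24/12-h cosinor fit on the z-score scale."""

    mesor: float
    amp24: float
    phase24: float  # acrophase of the 24-h component, hours in [0, 24)
    amp12: float
    phase12: float  # hours in [0, 12)
    series_mean: float  # pg/ml, for back-transform
    series_sd: float
    rss: float
    t_span: tuple[float, float]

    def curve_z(self, t):
        t = np.asarray(t, dtype=float)
        w1, w2 = 2 * np.pi / 24.0, 2 * np.pi / 12.0
        return (
            self.mesor
            + self.amp24 * np.cos(w1 * t - w1 * self.phase24)
            + self.amp12 * np.cos(w2 * t - w2 * self.phase12)
        )

    def curve_pgml(self, t):
        """Back-transformed fitted curve: mean + sd * z(t)."""
        return self.series_mean + self.series_sd * self.curve_z(t)


def _cosinor_design(t):
    w1, w2 = 2 * np.pi / 24.0, 2 * np.pi / 12.0
    return np.column_stack(
        [np.ones_like(t), np.cos(w1 * t), np.sin(w1 * t), np.cos(w2 * t), np.sin(w2 * t)]
    )


def fit_composite_cosinor(series: MelatoninSeries) -> CosinorFit:
    """Least-squares fit of z(t) = M + a cos w1 t + b sin w1 t + c cos w2 t + d sin w2 t."""
    series.validate_for_fit()
    t = series.times
    if len(np.unique(t)) < 5:
        raise CosinorError("need >= 5 distinct sample times")
    mean = float(np.mean(series.conc))
    sd = float(np.std(series.conc, ddof=0))
    if sd == 0:
        # flat series: z-scores undefined; represent as zero-amplitude fit
        return CosinorFit(0.0, 0.0, 0.0, 0.0, 0.0, mean, 0.0, 0.0,
                          (float(t[0]), float(t[-1])))
    z = (series.conc - mean) / sd
    Xd = _cosinor_design(t)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise CosinorError("rank-deficient cosinor design")
    coef, *_ = np.linalg.lstsq(Xd, z, rcond=None)
    resid = z - Xd @ coef
    m, c24, s24, c12, s12 = coef
    amp24, phase24 = amplitude_phase(s24, c24, period=24.0)
    amp12, phase12 = amplitude_phase(s12, c12, period=12.0)
    return CosinorFit(
        mesor=float(m),
        amp24=amp24,
        phase24=phase24,
        amp12=amp12,
        phase12=phase12,
        series_mean=mean,
        series_sd=sd,
        rss=float(resid @ resid),
        t_span=(float(t[0]), float(t[-1])),
    )


def compute_dlmo(
    fit: CosinorFit,
    threshold: float = DLMO_THRESHOLD_PGML,
    low_background_h: float = 1.0,
    grid_step_h: float = 0.01,
):
    """Locate the DLMO on the back-transformed fitted curve.

    Returns the earliest time within the observed span at which the curve
    crosses ``threshold`` upward after having stayed below it for at least
    ``low_background_h`` hours (a "rose from a low background" guard that
    excludes descending-limb artifacts).  The root is refined by bisection
    to <= 0.01 h.  Returns ``None`` when no such crossing exists (distinct
    from raising, which signals invalid input).
    """
    t0, t1 = fit.t_span
    grid = np.arange(t0, t1 + grid_step_h / 2, grid_step_h)
    vals = fit.curve_pgml(grid)
    below = vals < threshold
    f = lambda t: fit.curve_pgml(t) - threshold  # noqa: E731
    n_back = max(int(round(low_background_h / grid_step_h)), 1)
    for i in range(len(grid) - 1):
        if below[i] and not below[i + 1]:
            # require the curve to sit below threshold throughout the
            # preceding window (clipped to the start of the record)
            lo = max(0, i - n_back + 1)
            if not np.all(below[lo : i + 1]):
                continue
            root = optimize.brentq(f, grid[i], grid[i + 1], xtol=1e-3)
            return float(root)
    return None


def estimate_dlmo_table(
    melatonin: pd.DataFrame, threshold: float = DLMO_THRESHOLD_PGML
) -> pd.DataFrame:
    """Per subject-epoch DLMO estimates from a long melatonin table.

    ``melatonin`` columns: subject_id, cr, time_h, conc_pgml.  Rows whose
    series admits no upward threshold crossing get NaN.
    """
    rows = []
    for (sid, cr), grp in melatonin.groupby(["subject_id", "cr"], sort=True):
        series = MelatoninSeries(
            grp["time_h"].to_numpy(float), grp["conc_pgml"].to_numpy(float)
        )
        try:
            cfit = fit_composite_cosinor(series)
            dlmo = compute_dlmo(cfit, threshold=threshold)
        except CosinorError:
            dlmo = None
        rows.append(
            {"subject_id": sid, "cr": cr,
             "dlmo_h": np.nan if dlmo is None else dlmo}
        )
    return pd.DataFrame(rows)
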