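import numpy as np
import pandas as pd
import pytest

import circatiming as ct


@pytest.fixture(scope="session")
def small_cohort():
    """A compact simulated cohort (4 subjects, 8-h occasions): 160 rows."""
    cfg = ct.ProtocolConfig(n_subjects=4, sampling_interval_h=8.0)
    occ, truth = ct.simulate_from_lmm(cfg, seed=5)
    return occ, truth


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    occ, _ = small_cohort
    return ct.fit_occasions(occ, ct.ModelSpec(), method="ML")


@pytest.fixture(scope="session")
def homoscedastic_cohort():
    """Random-intercept, equal-variance cohort for the independent cross-check."""
    cfg = ct.ProtocolConfig(n_subjects=10, sampling_interval_h=4.0)
    sig = {(t, s): 9.0 for t in ("estimation", "production") for s in (10.0, 40.0)}
    occ, _ = ct.simulate_from_lmm(cfg, re_sd=(8.0, 0.0, 0.0), sigma_cells=sig, seed=11)
    return occ


def toy_occasions(ratios, t=0.0):
    """One-subject occasion frame with prescribed ratio values."""
    n = len(ratios)
    return pd.DataFrame(
        {
            "subject_id": ["S01"] * n,
            "cr": ["CR1"] * n,
            "occasion_time_h": np.arange(n, dtype=float),
            "task": ["estimation"] * n,
            "stimulus_s": [10.0] * n,
            "ratio": np.asarray(ratios, dtype=float),
            "t_dlmo_h": np.full(n, t),
        }
    )
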