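"""Synthetic cohort generators: geometry, determinism, generative contracts."""

import numpy as np
import pandas as pd
import pytest

import circatiming as ct
from circatiming.cohort import ProtocolConfig, occasion_grid
from circatiming.lmm import FIXED_TERMS, ModelSpec, build_design


def test_occasion_grid_has_20_two_hourly_points():
    grid = occasion_grid(ProtocolConfig())
    assert len(grid) == 20
    assert grid[0] == 0.0 and grid[-1] == 38.0


def test_mechanistic_row_count_matches_protocol_arithmetic():
    # 18 subjects x 2 CR x 20 occasions x 4 cells x 3 trials = 8640
    trials, melatonin, _ = ct.simulate_mechanistic(seed=1)
    assert len(trials) == 18 * 2 * 20 * 4 * 3 == 8640
    # hourly melatonin: 39 samples over 38.67 h, per subject-epoch
    assert len(melatonin) == 18 * 2 * 39


def test_lmm_row_count_and_cell_conservation():
    occ, _ = ct.simulate_from_lmm(seed=1)
    assert len(occ) == 18 * 2 * 20 * 4 == 2880
    counts = occ.groupby(["task", "stimulus_s"]).size()
    assert (counts == 720).all()


def test_same_seed_gives_identical_tables():
    a, ta = ct.simulate_from_lmm(seed=33)
    b, tb = ct.simulate_from_lmm(seed=33)
    pd.testing.assert_frame_equal(a, b)
    t1, m1, _ = ct.simulate_mechanistic(seed=33)
    t2, m2, _ = ct.simulate_mechanistic(seed=33)
    pd.testing.assert_frame_equal(t1, t2)
    pd.testing.assert_frame_equal(m1, m2)


def test_mechanistic_zero_noise_zero_modulation_is_veridical():
    pop = ct.PacemakerParams()  # no modulation, no leakage
    sig0 = {(t, s): 0.0 for t in ("estimation", "production") for s in (10.0, 40.0)}
    trials, _, _ = ct.simulate_mechanistic(
        ProtocolConfig(n_subjects=2), pop=pop,
        pacemaker_sd={"h_amp": 0, "c_amp": 0, "c_phase": 0},
        sigma_cells=sig0,
    )
    assert np.allclose(trials["response_s"], trials["stimulus_s"])


def test_lmm_intercept_only_no_noise_is_constant():
    beta = {t: 0.0 for t in FIXED_TERMS}
    beta["Intercept"] = 100.0
    sig0 = {(t, s): 0.0 for t in ("estimation", "production") for s in (10.0, 40.0)}
    occ, _ = ct.simulate_from_lmm(
        ProtocolConfig(n_subjects=2), beta=beta, re_sd=(0, 0, 0), sigma_cells=sig0, seed=4
    )
    assert np.allclose(occ["ratio"], 100.0)


def test_lmm_zero_noise_equals_design_times_beta():
    """Row-by-row hand evaluation of the generating equation."""
    cfg = ProtocolConfig(n_subjects=2, sampling_interval_h=19.0)  # 2 occasions
    sig0 = {(t, s): 0.0 for t in ("estimation", "production") for s in (10.0, 40.0)}
    occ, truth = ct.simulate_from_lmm(cfg, re_sd=(0, 0, 0), sigma_cells=sig0, seed=8)
    for _, row in occ.iterrows():
        t = row["t_dlmo_h"]
        task = 1.0 if row["task"] == "estimation" else 0.0
        stim = 1.0 if row["stimulus_s"] == 40.0 else 0.0
        cr = 1.0 if row["cr"] == "CR2" else 0.0
        e = np.exp(-t / 18.2)
        s = np.sin(2 * np.pi * t / 24)
        c = np.cos(2 * np.pi * t / 24)
        b = truth.beta
        y = (
            b["Intercept"] + b["TASK"] * task + b["STIM"] * stim + b["CR"] * cr
            + b["exp"] * e + b["sin"] * s + b["cos"] * c
            + b["TASK:STIM"] * task * stim + b["TASK:CR"] * task * cr
            + b["TASK:exp"] * task * e + b["TASK:sin"] * task * s
            + b["TASK:cos"] * task * c + b["STIM:exp"] * stim * e
            + b["STIM:sin"] * stim * s + b["STIM:cos"] * stim * c
        )
        assert row["ratio"] == pytest.approx(y, abs=1e-10)


def test_truth_record_retains_generating_quantities():
    occ, truth = ct.simulate_from_lmm(ProtocolConfig(n_subjects=3), seed=6)
    assert set(truth.beta) == set(FIXED_TERMS)
    assert len(truth.subjects) == 3
    flat = truth.flat()
    assert flat["beta.Intercept"] == truth.beta["Intercept"]
    assert "subject.S01.dlmo_cr1" in flat
    dlmo_tbl = truth.dlmo_table()
    assert len(dlmo_tbl) == 6


def test_melatonin_profile_contracts():
    mel = ct.simulate_melatonin(14.0, noise_log_sd=0.2, rng=np.random.default_rng(1))
    assert (mel["conc_pgml"] >= 2.8).all()  # assay floor
    assert len(mel) == 39
    # noiseless profile crosses the mesor upward exactly at DLMO
    quiet = ct.simulate_melatonin(14.0)
    f = ct.fit_composite_cosinor(
        ct.MelatoninSeries(quiet["time_h"].to_numpy(), quiet["conc_pgml"].to_numpy())
    )
    assert ct.compute_dlmo(f) == pytest.approx(14.0, abs=0.1)


def test_mechanistic_cohort_shows_opposite_task_trends():
    """Fitting the full model to mechanistic data recovers the predicted
    directions: rising estimation and falling production homeostatic
    components when the pacemaker rate builds with time awake."""
    trials, melatonin, truth = ct.simulate_mechanistic(seed=3)
    occ = ct.aggregate_and_ratio(trials)
    kept, _ = ct.filter_outliers(occ)
    dlmo = ct.estimate_dlmo_table(melatonin)
    occ2 = ct.align_to_dlmo(kept, dlmo)
    f = ct.fit_occasions(occ2, ModelSpec(), "ML")
    coefs = dict(zip(f.term_names, f.beta))
    # exp(-t/18.2) decays with t: a negative coefficient means a rising
    # trajectory.  Estimation = reference + TASK interaction.
    assert coefs["exp"] + coefs["TASK:exp"] < 0  # estimation rises
    assert coefs["exp"] > 0  # production falls
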