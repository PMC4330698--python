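"""From-scratch mixed-model engine: design, likelihood, Wald table, prediction."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import circatiming as ct
from circatiming.lmm import (
    FIXED_TERMS,
    DesignError,
    ModelSpec,
    amplitude_phase,
    build_design,
    fit,
    fit_occasions,
    predict,
    wald_table,
)


def _row(task, stim, cr, t):
    return pd.DataFrame(
        {
            "subject_id": ["S01"],
            "cr": [cr],
            "task": [task],
            "stimulus_s": [stim],
            "t_dlmo_h": [t],
        }
    )


class TestBuildDesign:
    def test_reference_row_at_t0(self):
        # reference cell (production, 10 s, CR1) at t=0: only intercept,
        # exp(0)=1 and cos(0)=1 are non-zero
        X, Z, subj, vg = build_design(_row("production", 10.0, "CR1", 0.0))
        expected = np.zeros(15)
        expected[[0, 4, 6]] = 1.0
        assert np.allclose(X[0], expected)
        assert Z[0].tolist() == [1.0, 0.0, 0.0]

    def test_column_count_is_15(self):
        X, *_ = build_design(_row("estimation", 40.0, "CR2", 6.0))
        assert X.shape[1] == len(FIXED_TERMS) == 15

    def test_sin_column_at_quarter_period(self):
        X, *_ = build_design(_row("production", 10.0, "CR1", 6.0))
        assert X[0, FIXED_TERMS.index("sin")] == pytest.approx(1.0, abs=1e-12)

    def test_interactions_are_products(self):
        X, *_ = build_design(_row("estimation", 40.0, "CR2", 7.3))
        cols = dict(zip(FIXED_TERMS, X[0]))
        assert cols["TASK"] == cols["STIM"] == cols["CR"] == 1.0
        assert cols["TASK:exp"] == pytest.approx(cols["exp"])
        assert cols["STIM:sin"] == pytest.approx(cols["sin"])
        assert cols["exp"] == pytest.approx(np.exp(-7.3 / 18.2))

    def test_unknown_factor_level_rejected(self):
        with pytest.raises(DesignError):
            build_design(_row("reproduction", 10.0, "CR1", 0.0))
        with pytest.raises(DesignError):
            build_design(_row("estimation", 10.0, "CR9", 0.0))


class TestFit:
    def test_zero_noise_interpolation(self):
        """Data generated as X @ beta with no random terms is recovered exactly."""
        cfg = ct.ProtocolConfig(n_subjects=3, sampling_interval_h=8.0)
        sig0 = {(t, s): 0.0 for t in ("estimation", "production") for s in (10.0, 40.0)}
        occ, truth = ct.simulate_from_lmm(cfg, re_sd=(0, 0, 0), sigma_cells=sig0, seed=2)
        f = fit_occasions(occ, ModelSpec(), method="ML")
        truth_beta = np.array([truth.beta[t] for t in FIXED_TERMS])
        assert np.max(np.abs(f.beta - truth_beta) / np.abs(truth_beta)) < 1e-6

    def test_loglik_matches_dense_gaussian_oracle(self, small_cohort, small_fit):
        """Profiled optimum equals a brute-force joint-normal density, and the
        GLS closed form reproduces beta-hat, on a <=200-row instance."""
        occ, _ = small_cohort
        f = small_fit
        X, Z, subj, vg = build_design(occ, ModelSpec())
        y = occ["ratio"].to_numpy()
        n = len(y)
        assert n <= 200
        V = np.zeros((n, n))
        for s in np.unique(subj):
            idx = np.flatnonzero(subj == s)
            V[np.ix_(idx, idx)] = Z[idx] @ f.re_cov @ Z[idx].T
        V += np.diag([f.sigma**2 * f.var_multipliers[str(g)] ** 2 for g in vg])
        ll_dense = stats.multivariate_normal.logpdf(y, mean=X @ f.beta, cov=V)
        assert f.loglik == pytest.approx(ll_dense, abs=1e-6)
        Vi = np.linalg.inv(V)
        beta_gls = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
        assert np.allclose(beta_gls, f.beta, atol=1e-8)

    def test_homoscedastic_reduction_matches_statsmodels(self, homoscedastic_cohort):
        """Random-intercept, equal-variance fit agrees with an independent
        implementation to 1e-4."""
        from statsmodels.regression.mixed_linear_model import MixedLM

        occ = homoscedastic_cohort
        spec = ModelSpec(random_terms=("Intercept",), variance_groups="none")
        f = fit_occasions(occ, spec, method="ML")
        X, Z, subj, _ = build_design(occ, spec)
        ref = MixedLM(occ["ratio"].to_numpy(), X, groups=subj).fit(reml=False)
        assert np.max(np.abs(np.asarray(ref.params)[:15] - f.beta)) < 1e-4
        assert f.loglik == pytest.approx(ref.llf, abs=1e-4)
        assert f.sigma == pytest.approx(np.sqrt(ref.scale), abs=1e-4)

    def test_variance_multipliers_recovered(self):
        """Per-cell residual SDs are recovered on a low-noise large cohort."""
        cfg = ct.ProtocolConfig(n_subjects=12)
        occ, truth = ct.simulate_from_lmm(cfg, seed=9)
        f = fit_occasions(occ, ModelSpec(), method="REML")
        ref_cell = f.group_names[0]
        task, stim = ref_cell.split(":")
        base_truth = truth.sigma_cells[(task, float(stim))]
        for g in f.group_names:
            task, stim = g.split(":")
            implied = f.sigma * f.var_multipliers[g]
            assert implied == pytest.approx(truth.sigma_cells[(task, float(stim))], rel=0.15)
        assert f.var_multipliers[ref_cell] == 1.0

    def test_factorial_variance_structure_nested_in_cell(self, small_cohort):
        """Two multiplicative task/stimulus variance factors: the implied
        cell multipliers are rank-1 in log scale, and the free per-cell
        version attains at least the same likelihood."""
        occ, _ = small_cohort
        f_fact = fit_occasions(occ, ModelSpec(variance_groups="task-stim"), "ML")
        f_cell = fit_occasions(occ, ModelSpec(variance_groups="cell"), "ML")
        m = f_fact.var_multipliers
        prod_check = (
            m["estimation:10.0"] * m["production:40.0"]
            - m["estimation:40.0"] * m["production:10.0"]
        )
        assert prod_check == pytest.approx(0.0, abs=1e-6)
        assert f_cell.loglik >= f_fact.loglik - 1e-6
        assert f_fact.n_params == f_cell.n_params - 1

    def test_reml_and_ml_agree_on_beta_direction(self, small_cohort):
        occ, _ = small_cohort
        fm = fit_occasions(occ, ModelSpec(), "ML")
        fr = fit_occasions(occ, ModelSpec(), "REML")
        assert np.allclose(fm.beta, fr.beta, atol=0.5)

    def test_fewer_than_two_subjects_rejected(self):
        occ = _row("production", 10.0, "CR1", 0.0)
        occ["ratio"] = 100.0
        with pytest.raises(DesignError):
            fit_occasions(pd.concat([occ] * 20, ignore_index=True), ModelSpec())


class TestWaldTable:
    def test_containment_df_arithmetic(self, small_fit):
        # every fixed term (incl. intercept) varies within subjects
        f = small_fit
        assert f.df == f.n_obs - f.n_subjects - 15
        table = wald_table(f)
        assert (table["df"] == f.df).all()

    def test_t_is_value_over_se(self, small_fit):
        table = wald_table(small_fit)
        assert np.allclose(table["t"], table["value"] / table["se"])
        # two-sided p from the t distribution
        row = table.iloc[0]
        assert row["p"] == pytest.approx(2 * stats.t.sf(abs(row["t"]), row["df"]))

    def test_full_design_df_matches_protocol_arithmetic(self, small_fit):
        # 4 subjects x 2 CR x 5 occasions x 4 cells = 160 obs; df = 160-4-15
        assert small_fit.df == 141


class TestAmplitudePhase:
    @pytest.mark.parametrize(
        "s, c, expected",
        [
            (0.0, 1.0, (1.0, 0.0)),
            (1.0, 0.0, (1.0, 6.0)),
            (2.64, -0.92, (np.hypot(2.64, 0.92), None)),
        ],
    )
    def test_closed_form(self, s, c, expected):
        amp, acro = amplitude_phase(s, c, period=24.0)
        assert amp == pytest.approx(expected[0], rel=1e-9)
        if expected[1] is not None:
            assert acro == pytest.approx(expected[1], abs=1e-9)
        assert 0 <= acro < 24.0

    def test_identity_reconstructs_waveform(self):
        s, c = 2.64, -0.92
        amp, acro = amplitude_phase(s, c)
        w = 2 * np.pi / 24
        t = np.linspace(0, 24, 97)
        assert np.allclose(amp * np.cos(w * t - w * acro), s * np.sin(w * t) + c * np.cos(w * t))


class TestPredict:
    def test_intercept_only_beta_predicts_constant(self, small_cohort, small_fit):
        occ, _ = small_cohort
        f = small_fit
        from dataclasses import replace

        beta0 = np.zeros_like(f.beta)
        beta0[0] = 100.0
        import copy

        f0 = copy.copy(f)
        f0.beta = beta0
        assert np.allclose(predict(f0, occ), 100.0)

    def test_subject_level_approaches_y_in_low_noise_limit(self):
        cfg = ct.ProtocolConfig(n_subjects=4, sampling_interval_h=8.0)
        tiny = {(t, s): 1e-4 for t in ("estimation", "production") for s in (10.0, 40.0)}
        occ, _ = ct.simulate_from_lmm(cfg, re_sd=(10, 5, 5), sigma_cells=tiny, seed=3)
        f = fit_occasions(occ, ModelSpec(), "ML")
        yhat = predict(f, occ, level="subject")
        assert np.max(np.abs(yhat - occ["ratio"])) < 0.01

    def test_population_trend_signs_under_reference_beta(self):
        """The reference coefficients imply a rising estimation and falling
        production trajectory at mid-protocol."""
        spec = ModelSpec()
        beta = np.array([ct.REFERENCE_BETA[t] for t in FIXED_TERMS])
        for task, sign in (("estimation", +1), ("production", -1)):
            rows = pd.concat(
                [_row(task, 10.0, "CR1", 11.0), _row(task, 10.0, "CR1", 13.0)],
                ignore_index=True,
            )
            X, *_ = build_design(rows, spec)
            dy = (X[1] - X[0]) @ beta
            assert sign * dy > 0

    def test_unknown_subject_rejected_at_subject_level(self, small_fit):
        new = _row("production", 10.0, "CR1", 0.0)
        new["subject_id"] = "S99"
        with pytest.raises(KeyError):
            predict(small_fit, new, level="subject")
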