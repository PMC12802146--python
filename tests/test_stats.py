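"""Linear fits, AIC model comparison, binned summaries, two-sample tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import polagg as pg
from polagg.stats import DELTA_AIC_SUPPORT, ModelSpec


class TestFitDiameterGrowth:
    def test_exact_line(self):
        t = np.linspace(0, 39, 25)
        pts = list(zip(t, 0.01 * t + 0.4))
        fit = pg.fit_diameter_growth(pts)
        assert fit.coefficients["slope"] == pytest.approx(0.01, abs=1e-12)
        assert fit.coefficients["intercept"] == pytest.approx(0.4, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_cutoff_restricts_fit(self):
        t = np.array([0.0, 10.0, 20.0, 30.0, 50.0])
        d = 0.01 * t + 0.4
        d[-1] = 10.0  # wild post-cutoff point must not influence the fit
        fit = pg.fit_diameter_growth(list(zip(t, d)), time_cutoff=40.0)
        assert fit.coefficients["slope"] == pytest.approx(0.01, abs=1e-12)
        assert fit.n_obs == 4

    def test_two_points_flagged_low_n(self):
        fit = pg.fit_diameter_growth([(0.0, 0.4), (10.0, 0.6)], time_cutoff=None)
        assert fit.r_squared == 1.0
        assert fit.notes == "low_n"

    def test_degenerate_design_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            pg.fit_diameter_growth([(5.0, 0.4), (5.0, 0.5), (5.0, 0.6)])

    @given(st.integers(min_value=0, max_value=10**6))
    @settings(max_examples=30, deadline=None)
    def test_matches_normal_equations_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 40))
        t = rng.uniform(0, 39, n)
        if np.ptp(t) == 0:
            t[0] += 1.0
        d = rng.normal(0.5, 0.2, n)
        fit = pg.fit_diameter_growth(list(zip(t, d)))
        # closed-form normal equations
        X = np.column_stack([np.ones(n), t])
        beta = np.linalg.solve(X.T @ X, X.T @ d)
        assert fit.coefficients["intercept"] == pytest.approx(beta[0], rel=1e-8, abs=1e-10)
        assert fit.coefficients["slope"] == pytest.approx(beta[1], rel=1e-8, abs=1e-10)


class TestCompareModels:
    @staticmethod
    def dataset(n=400, role_effect=0.0, seed=0):
        rng = np.random.default_rng(seed)
        role = np.repeat(["mother", "daughter"], n // 2)
        time = rng.uniform(0, 40, n)
        y = 1.0 + 0.01 * time + role_effect * (role == "mother") + rng.normal(0, 1, n)
        return pd.DataFrame({"y": y, "time": time, "role": role})

    def test_duplicated_specs_tie_and_no_flag(self):
        data = self.dataset()
        spec = ModelSpec("m", "y", linear_terms=["time"])
        results = pg.compare_models(data, [spec, ModelSpec("m2", "y", linear_terms=["time"])])
        assert results[0].aic == pytest.approx(results[1].aic)
        assert results[1].delta_aic == pytest.approx(0.0, abs=1e-9)
        assert not results[0].substantially_better

    def test_strong_effect_selected(self):
        data = self.dataset(role_effect=2.0, seed=3)
        results = pg.compare_models(
            data,
            [ModelSpec("base", "y", linear_terms=["time"]),
             ModelSpec("role", "y", linear_terms=["time"], factor_terms=["role"])],
        )
        assert results[0].model_id == "role"
        assert results[0].substantially_better
        assert results[1].delta_aic > DELTA_AIC_SUPPORT

    def test_row_order_invariance(self):
        data = self.dataset(role_effect=0.7, seed=5)
        specs = [
            ModelSpec("base", "y", linear_terms=["time"]),
            ModelSpec("role", "y", linear_terms=["time"], factor_terms=["role"]),
        ]
        a = pg.compare_models(data, specs)
        shuffled = data.sample(frac=1.0, random_state=9).reset_index(drop=True)
        b = pg.compare_models(shuffled, specs)
        assert [r.model_id for r in a] == [r.model_id for r in b]
        for ra, rb in zip(a, b):
            assert ra.aic == pytest.approx(rb.aic, rel=1e-9)

    def test_smooth_term_captures_nonlinearity(self):
        rng = np.random.default_rng(8)
        time = rng.uniform(0, 40, 600)
        y = np.sin(time / 6.0) + rng.normal(0, 0.3, 600)
        data = pd.DataFrame({"y": y, "time": time})
        results = pg.compare_models(
            data,
            [ModelSpec("linear", "y", linear_terms=["time"]),
             ModelSpec("smooth", "y", smooth_terms={"time": 8})],
        )
        assert results[0].model_id == "smooth"
        assert results[0].substantially_better
        assert results[0].deviance_explained > results[1].deviance_explained

    def test_tensor_interaction_improves_fit_when_present(self):
        rng = np.random.default_rng(13)
        n = 800
        u = rng.uniform(0, 1, n)
        v = rng.uniform(0, 1, n)
        y = np.sin(3 * u) * np.cos(3 * v) + rng.normal(0, 0.2, n)
        data = pd.DataFrame({"y": y, "u": u, "v": v})
        results = pg.compare_models(
            data,
            [ModelSpec("additive", "y", smooth_terms={"u": 5, "v": 5}),
             ModelSpec("interaction", "y", smooth_terms={"u": 5, "v": 5},
                       tensor_terms=[("u", "v")])],
        )
        assert results[0].model_id == "interaction"
        assert results[0].substantially_better

    def test_negative_binomial_identity_family_runs(self):
        rng = np.random.default_rng(4)
        n = 500
        time = rng.uniform(0, 40, n)
        mu = 700 + 5 * time
        y = rng.negative_binomial(20, 20 / (20 + mu)).astype(float)
        data = pd.DataFrame({"y": y, "time": time})
        results = pg.compare_models(
            data,
            [ModelSpec("nb", "y", linear_terms=["time"], family="nb_identity"),
             ModelSpec("nb0", "y", family="nb_identity")],
        )
        assert results[0].model_id == "nb"
        assert np.isfinite(results[0].aic)
        assert 0 <= results[0].deviance_explained <= 1


class TestBinnedSummary:
    def test_small_bin_dropped(self):
        out = pg.binned_summary(np.arange(9.0), np.arange(9.0), bin_width=100.0)
        assert len(out.frame) == 0
        assert out.n_dropped == 9

    def test_identical_values_zero_sd(self):
        out = pg.binned_summary(np.zeros(10), np.full(10, 3.3), bin_width=1.0)
        assert len(out.frame) == 1
        assert out.frame.iloc[0]["mean"] == pytest.approx(3.3)
        assert out.frame.iloc[0]["sd"] == 0.0

    def test_identity_line_recovered(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 10, 1000)
        out = pg.binned_summary(x, x, bin_width=0.5)
        for _, row in out.frame.iterrows():
            assert abs(row["mean"] - row["bin_center"]) <= 0.25

    def test_count_conservation(self):
        rng = np.random.default_rng(7)
        x = rng.normal(0, 3, 500)
        out = pg.binned_summary(x, x**2, bin_width=0.8)
        assert out.n_total == 500

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            pg.binned_summary([0.0, np.nan], [1.0, 2.0], 1.0)


class TestTwoSampleTests:
    def test_ks_identical_samples(self):
        a = np.arange(50.0)
        stat, p = pg.ks_two_sample(a, a)
        assert stat == 0.0

    def test_ks_shifted_uniforms_detected(self):
        rng = np.random.default_rng(11)
        a = rng.uniform(0, 1, 500)
        b = rng.uniform(0.5, 1.5, 500)
        _, p = pg.ks_two_sample(a, b)
        assert p < 1e-6

    def test_ks_null_pvalues_uniform(self):
        from scipy.stats import kstest

        rng = np.random.default_rng(15)
        # asymptotic-regime sample sizes give effectively continuous p-values
        pvals = [
            pg.ks_two_sample(rng.normal(size=250), rng.normal(size=250))[1]
            for _ in range(150)
        ]
        assert kstest(pvals, "uniform").pvalue > 0.01

    def test_welch_identical_samples(self):
        a = np.array([1.0, 2.0, 3.0])
        t, p = pg.welch_t(a, a)
        assert t == 0.0

    def test_welch_closed_form(self):
        """Means 0 vs 1, SD 1, n=100 each: |t| = 1/sqrt(2/100) ≈ 7.07."""
        rng = np.random.default_rng(19)
        a = rng.normal(0, 1, 100)
        b = rng.normal(1, 1, 100)
        # standardize to exact moments so the closed form applies
        a = (a - a.mean()) / a.std(ddof=1)
        b = (b - b.mean()) / b.std(ddof=1) + 1.0
        t, p = pg.welch_t(a, b)
        assert abs(t) == pytest.approx(np.sqrt(100 / 2), rel=1e-9)
        assert p < 1e-9

    def test_welch_zero_variance_equal_means(self):
        t, p = pg.welch_t([2.0, 2.0], [2.0, 2.0])
        assert t == 0.0 and p == 1.0

    def test_bearing_cells_slower_in_pooled_population(self):
        """Pooled over roles, aggregate-bearing cells grow more slowly than
        aggregate-free cells (negative Welch t), mirroring the population-
        level comparison before conditioning on pole inheritance."""
        cfg = pg.SimConfig(seed=29, n_wells=40, duration=15.0)
        table, log = pg.simulate_lineages(cfg)
        filt = pg.filter_complete_cycles(table)
        truth = log.frame.set_index("cycle_id")["bearing"]
        bearing, free = [], []
        for rec in filt:
            r = pg.fit_elongation_rate(rec.length_series).elongation_rate
            (bearing if truth.loc[rec.cycle_id] else free).append(r)
        t, _ = pg.welch_t(bearing, free)
        assert t < 0

    def test_too_small_samples_rejected(self):
        with pytest.raises(ValueError):
            pg.ks_two_sample([1.0], [1.0, 2.0])
        with pytest.raises(ValueError):
            pg.welch_t([1.0], [1.0, 2.0])
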