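"""Age and cognition models: OLS identities, mixed model, BH-FDR, predictions."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from lc_relaxo.cohort import CohortGenSpec, CognitionBetas, generate_cohort
from lc_relaxo.models import (
    bh_fdr,
    fit_cross_sectional,
    fit_linear_age,
    fit_longitudinal,
    fit_quadratic_age,
    fit_slice_ages,
    predict_profile_at_ages,
)


def _cohort(n=120, seed=0):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "participant_id": [f"P{i}" for i in range(n)],
            "age": rng.uniform(22, 94, n),
            "sex": rng.integers(0, 2, n),
            "race": rng.choice(["white", "black", "other"], n, p=[0.68, 0.19, 0.13]),
            "edy": rng.normal(16, 2.7, n),
        }
    )


class TestLinearAge:
    def test_noiseless_identity(self):
        cohort = _cohort()
        cohort["metric"] = 2.0 - 0.01 * cohort["age"]
        fit = fit_linear_age(cohort, "metric")
        assert fit.term("age")[0] == pytest.approx(-0.01, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(1)
        cohort = _cohort(60, seed=1)
        cohort["metric"] = 1.0 - 0.005 * cohort["age"] + rng.normal(0, 0.1, 60)
        fit = fit_linear_age(cohort, "metric")
        x = np.column_stack(
            [
                np.ones(60),
                cohort["age"],
                cohort["sex"],
                (cohort["race"] == "black").astype(float),
                (cohort["race"] == "other").astype(float),
                cohort["edy"],
            ]
        )
        beta = np.linalg.solve(x.T @ x, x.T @ cohort["metric"].to_numpy())
        assert fit.term("age")[0] == pytest.approx(beta[1], abs=1e-10)

    def test_rank_deficiency_reported(self):
        cohort = _cohort(40)
        cohort["edy"] = 16.0  # constant regressor
        cohort["metric"] = cohort["age"] * 0.01
        with pytest.raises(ValueError, match="rank|constant"):
            fit_linear_age(cohort, "metric")

    def test_null_pvalues_uniform(self):
        """Type-I calibration: p(beta_age) ~ U(0,1) under the null."""
        from scipy import stats

        rng = np.random.default_rng(7)
        cohort = _cohort(120, seed=7)
        pvals = []
        for _ in range(400):
            cohort["metric"] = rng.standard_normal(120)
            pvals.append(fit_linear_age(cohort, "metric").term("age")[2])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestQuadraticAge:
    def test_pure_quadratic_identity(self):
        cohort = _cohort()
        cohort["metric"] = (cohort["age"] - cohort["age"].mean()) ** 2
        fit = fit_quadratic_age(cohort, "metric")
        assert fit.term("age_c2")[0] == pytest.approx(1.0, abs=1e-10)
        assert fit.term("age_c")[0] == pytest.approx(0.0, abs=1e-10)

    def test_centering_does_not_change_fitted_values(self):
        rng = np.random.default_rng(3)
        cohort = _cohort(80, seed=3)
        cohort["metric"] = 0.5 + 0.01 * cohort["age"] + rng.normal(0, 0.05, 80)
        fit = fit_quadratic_age(cohort, "metric")
        # refit on raw age + age^2 (uncentered reparameterization)
        import statsmodels.formula.api as smf

        cohort["age2"] = cohort["age"] ** 2
        raw = smf.ols("metric ~ age + age2 + sex + C(race) + edy", cohort).fit()
        np.testing.assert_allclose(
            fit.sm_result.fittedvalues, raw.fittedvalues, atol=1e-10
        )

    def test_null_quadratic_rarely_significant(self):
        rng = np.random.default_rng(5)
        cohort = _cohort(120, seed=5)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            cohort["metric"] = 1.0 - 0.004 * cohort["age"] + rng.normal(0, 0.1, 120)
            if fit_quadratic_age(cohort, "metric").term("age_c2")[2] < 0.05:
                hits += 1
        assert hits / n_rep < 0.10


class TestCrossSectional:
    def test_noiseless_recovery(self):
        cohort = _cohort()
        cohort["metric"] = 1.0 - 0.005 * cohort["age"]
        # perfectly deterministic cognition with beta_qmri = 0.5
        cohort["memory"] = 0.5 * cohort["metric"] - 0.01 * cohort["age"] + 0.1 * cohort["sex"]
        # a second regressor so qmri is not collinear with age
        rng = np.random.default_rng(0)
        cohort["metric"] += rng.normal(0, 0.05, len(cohort))
        cohort["memory"] = 0.5 * cohort["metric"] - 0.01 * cohort["age"]
        fit = fit_cross_sectional(cohort, None, "metric", "memory")
        assert fit.term("metric")[0] == pytest.approx(0.5, abs=1e-10)

    def test_age_confounding_adjusted(self):
        """qMRI and cognition share an age cause but no direct link."""
        rng = np.random.default_rng(9)
        ests = []
        for rep in range(200):
            cohort = _cohort(150, seed=rep)
            cohort["metric"] = -0.01 * cohort["age"] + rng.normal(0, 0.1, 150)
            cohort["memory"] = -0.02 * cohort["age"] + rng.normal(0, 0.3, 150)
            ests.append(fit_cross_sectional(cohort, None, "metric", "memory").term("metric")[0])
        mean_est = np.mean(ests)
        se = np.std(ests, ddof=1) / np.sqrt(len(ests))
        assert abs(mean_est) < 4 * se


class TestLongitudinal:
    def _spec(self, n=300, seed=0, **beta_kw):
        betas = {d: CognitionBetas() for d in
                 ("memory", "attention", "executive", "fluency", "processing_speed")}
        betas["memory"] = CognitionBetas(**beta_kw)
        return CohortGenSpec(
            n_participants=n, seed=seed, cognition_betas=betas,
            random_intercept_sd=0.4, residual_sd=0.25, visits_mean=4.0,
        )

    def test_key_terms_recovered(self):
        spec = self._spec(
            n=400, seed=2, time=-0.03, qmri=0.05, qmri_time=0.02, qmri_time_age=0.002,
        )
        cohort, visits = generate_cohort(spec)
        fit = fit_longitudinal(cohort, visits, "rostral_r2", "memory")
        est, se, _ = fit.term("qmri_c:time")
        assert abs(est - 0.02) < 3 * se
        est3, se3, _ = fit.term("age_x:qmri_c:time")
        assert abs(est3 - 0.002) < 3 * se3
        assert fit.random_intercept_sd == pytest.approx(0.4, abs=0.1)
        assert fit.residual_sd == pytest.approx(0.25, abs=0.05)

    def test_zero_random_intercept_boundary(self):
        spec = self._spec(n=150, seed=4, time=-0.03)
        spec.random_intercept_sd = 0.0
        cohort, visits = generate_cohort(spec)
        fit = fit_longitudinal(cohort, visits, "rostral_r2", "memory")
        assert fit.random_intercept_sd < 0.05
        # fixed effects then match plain OLS on the same design
        import statsmodels.formula.api as smf

        data = visits.merge(cohort, on="participant_id")
        data["qmri_c"] = data["rostral_r2"] - data["rostral_r2"].mean()
        data["age_x"] = data["age"] - data["age"].mean()
        ref = data["race"].value_counts().idxmax()
        ols = smf.ols(
            f"memory ~ age_x*qmri_c*time + sex + C(race, Treatment(reference='{ref}')) + edy",
            data,
        ).fit()
        assert fit.term("time")[0] == pytest.approx(ols.params["time"], abs=0.01)

    def test_permuted_metric_breaks_association(self):
        spec = self._spec(n=300, seed=6, qmri_time=0.05)
        cohort, visits = generate_cohort(spec)
        rng = np.random.default_rng(0)
        shuffled = cohort.copy()
        shuffled["rostral_r2"] = rng.permutation(shuffled["rostral_r2"].to_numpy())
        fit = fit_longitudinal(shuffled, visits, "rostral_r2", "memory")
        est, se, p = fit.term("qmri_c:time")
        assert abs(est) < 3 * se
        # while the intact cohort recovers it clearly
        fit_true = fit_longitudinal(cohort, visits, "rostral_r2", "memory")
        assert fit_true.term("qmri_c:time")[2] < 1e-4

    def test_reml_matches_gls_oracle_with_known_variances(self):
        """REML fixed effects vs closed-form GLS at the true variance components."""
        spec = self._spec(n=250, seed=8, time=-0.03, qmri_time=0.02)
        cohort, visits = generate_cohort(spec)
        fit = fit_longitudinal(cohort, visits, "rostral_r2", "memory")
        data = visits.merge(cohort, on="participant_id")
        data["qmri_c"] = data["rostral_r2"] - data["rostral_r2"].mean()
        data["age_x"] = data["age"] - data["age"].mean()
        import patsy

        ref = data["race"].value_counts().idxmax()
        y, x = patsy.dmatrices(
            f"memory ~ age_x*qmri_c*time + sex + C(race, Treatment(reference='{ref}')) + edy",
            data, return_type="dataframe",
        )
        # block-diagonal GLS with the generating variance components
        tau2, s2 = 0.4**2, 0.25**2
        xtvx = np.zeros((x.shape[1], x.shape[1]))
        xtvy = np.zeros(x.shape[1])
        for _, g in data.groupby("participant_id").indices.items():
            xi = x.to_numpy()[g]
            yi = y.to_numpy()[g, 0]
            v = s2 * np.eye(len(g)) + tau2
            vi = np.linalg.inv(v)
            xtvx += xi.T @ vi @ xi
            xtvy += xi.T @ vi @ yi
        beta_gls = np.linalg.solve(xtvx, xtvy)
        idx = list(x.columns).index("qmri_c:time")
        est, se, _ = fit.term("qmri_c:time")
        assert abs(est - beta_gls[idx]) < 0.5 * se


class TestBhFdr:
    def test_hand_worked_example(self):
        res = bh_fdr([0.01, 0.02, 0.03, 0.04, 0.05], q=0.05)
        np.testing.assert_allclose(res.adjusted_p, 0.05)
        assert res.rejected.all()

    def test_single_p_unchanged(self):
        res = bh_fdr([0.03])
        assert res.adjusted_p[0] == pytest.approx(0.03)

    def test_order_invariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(0.001, 1.0, 50)
        perm = rng.permutation(50)
        a = bh_fdr(p)
        b = bh_fdr(p[perm])
        np.testing.assert_allclose(a.adjusted_p[perm], b.adjusted_p)

    def test_matches_statsmodels_and_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(300):
            m = rng.integers(1, 25)
            p = rng.uniform(1e-6, 1.0, m)
            mine = bh_fdr(p, q=0.05)
            reject_sm, adj_sm, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
            np.testing.assert_allclose(mine.adjusted_p, adj_sm, rtol=1e-12)
            np.testing.assert_array_equal(mine.rejected, reject_sm)
            # brute-force step-up: largest k with p_(k) <= k q / m
            order = np.argsort(p)
            ks = [k for k in range(1, m + 1) if p[order][k - 1] <= 0.05 * k / m]
            n_rej = max(ks) if ks else 0
            assert mine.rejected.sum() == n_rej

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            bh_fdr([])
        with pytest.raises(ValueError, match="p-values"):
            bh_fdr([0.0, 0.5])


class TestSlicePredictions:
    def _slice_table(self, slopes, n=150, seed=0):
        rng = np.random.default_rng(seed)
        base = _cohort(n, seed=seed)
        rows = []
        n_slices = len(slopes)
        for k, slope in enumerate(slopes):
            t = base.copy()
            t["slice_percentile"] = 100.0 * (k + 0.5) / n_slices
            t["r2"] = 17.0 + slope * (t["age"] - 60.0) + rng.normal(0, 0.2, n)
            rows.append(t)
        return pd.concat(rows, ignore_index=True)

    def test_zero_slope_identical_predictions(self):
        table = self._slice_table([0.0, 0.0, 0.0])
        fits = fit_slice_ages(table, "r2")
        pred = predict_profile_at_ages(fits, ages=(40.0, 75.0))
        wide = pred.pivot(index="slice_percentile", columns="age", values="predicted")
        np.testing.assert_allclose(wide[40.0], wide[75.0], atol=0.15)

    def test_steeper_rostral_slopes_widen_the_gap(self):
        # rostral slices age faster -> larger 40-vs-75 separation rostrally
        table = self._slice_table([-0.06, -0.04, -0.02, -0.005])
        fits = fit_slice_ages(table, "r2")
        pred = predict_profile_at_ages(fits, ages=(40.0, 75.0))
        wide = pred.pivot(index="slice_percentile", columns="age", values="predicted")
        gaps = (wide[40.0] - wide[75.0]).to_numpy()
        assert gaps[0] > gaps[-1]
        assert np.all(np.diff(gaps) < 0.05)

    def test_extrapolation_warns(self):
        table = self._slice_table([0.0])
        fits = fit_slice_ages(table, "r2")
        with pytest.warns(UserWarning, match="outside"):
            predict_profile_at_ages(fits, ages=(150.0,))
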