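"""Weighted/unweighted subtype-outcome regression and bootstrap CIs."""

import numpy as np
import pandas as pd
import pytest

from nreclass import bootstrap_ci, compare_weightings, fit_subtype_model


def random_cohort(rng, n=60, k=3):
    labels = rng.choice([f"G{i}" for i in range(k)], size=n)
    effects = {f"G{i}": float(i * 2) for i in range(k)}
    y = np.array([effects[l] for l in labels]) + rng.normal(0, 1, n)
    w = rng.uniform(0.05, 1.0, n)
    return y, labels, w


def normal_equations_wls(y, labels, w, levels):
    """Independent closed-form WLS solve (X'WX)^-1 X'Wy."""
    X = np.column_stack(
        [np.ones(len(y))] + [(labels == l).astype(float) for l in levels[1:]]
    )
    W = np.diag(w)
    beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
    return beta


class TestFitSubtypeModel:
    def test_perfect_separation(self):
        fit = fit_subtype_model(
            [1.0, 1.0, 3.0, 3.0], ["A", "A", "B", "B"], np.ones(4)
        )
        assert fit.predicted_means["A"] == pytest.approx(1.0)
        assert fit.predicted_means["B"] == pytest.approx(3.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_no_between_group_variance(self):
        fit = fit_subtype_model(
            [0.0, 2.0, 0.0, 2.0], ["A", "A", "B", "B"], [0.4, 0.4, 0.9, 0.9]
        )
        assert fit.predicted_means["A"] == pytest.approx(1.0)
        assert fit.predicted_means["B"] == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_zero_weight_group_flagged_undefined(self):
        fit = fit_subtype_model(
            [1.0, 1.0, 3.0, 9.0],
            ["A", "A", "A", "B"],
            [1.0, 1.0, 0.5, 0.0],
        )
        est_b = fit.estimate_for("B")
        assert not est_b.defined
        assert est_b.mean is None and est_b.n == 1
        assert fit.estimate_for("A").defined

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            fit_subtype_model([1.0, 2.0], ["A", "B"], [0.0, 0.0])

    def test_single_subtype_rejected(self):
        with pytest.raises(ValueError, match="2 distinct"):
            fit_subtype_model([1.0, 2.0], ["A", "A"], [1.0, 1.0])

    def test_missing_outcomes_dropped_and_counted(self):
        fit = fit_subtype_model(
            [1.0, np.nan, 3.0, 3.0, np.nan],
            ["A", "A", "B", "B", "B"],
            np.ones(5),
        )
        assert fit.n_used == 3
        assert fit.n_dropped_missing_outcome == 2

    def test_coefficients_match_normal_equations_oracle(self, rng):
        for _ in range(20):
            y, labels, w = random_cohort(rng)
            levels = sorted(set(labels))
            fit = fit_subtype_model(y, labels, w, subtype_order=levels)
            beta = normal_equations_wls(y, labels, w, levels)
            assert fit.intercept == pytest.approx(beta[0], abs=1e-9)
            for j, level in enumerate(levels[1:], start=1):
                assert fit.coefficients[level] == pytest.approx(
                    beta[j], abs=1e-9
                )

    def test_predicted_means_are_weighted_group_means(self, rng):
        # saturated one-factor identity: fitted subtype mean equals the
        # weighted mean of that subtype's outcomes
        y, labels, w = random_cohort(rng)
        fit = fit_subtype_model(y, labels, w)
        for est in fit.estimates:
            mask = labels == est.subtype
            expected = np.average(y[mask], weights=w[mask])
            assert est.mean == pytest.approx(expected, abs=1e-10)
            assert est.ci_low <= est.mean <= est.ci_high

    def test_means_equal_intercept_plus_coefficient(self, rng):
        y, labels, w = random_cohort(rng)
        levels = sorted(set(labels))
        fit = fit_subtype_model(y, labels, w, subtype_order=levels)
        assert fit.estimate_for(levels[0]).mean == pytest.approx(fit.intercept)
        for level in levels[1:]:
            assert fit.estimate_for(level).mean == pytest.approx(
                fit.intercept + fit.coefficients[level], abs=1e-10
            )

    def test_constant_weights_reduce_to_ols(self, rng):
        import statsmodels.api as sm

        for c in (1.0, 0.37, 12.0):
            y, labels, _ = random_cohort(rng)
            levels = sorted(set(labels))
            fit = fit_subtype_model(
                y, labels, np.full(len(y), c), subtype_order=levels
            )
            X = pd.DataFrame({"const": np.ones(len(y))})
            for l in levels[1:]:
                X[l] = (labels == l).astype(float)
            ols = sm.OLS(y, X).fit()
            assert fit.intercept == pytest.approx(ols.params["const"], abs=1e-10)
            assert fit.r_squared == pytest.approx(ols.rsquared, abs=1e-10)
            for l in levels[1:]:
                assert fit.coefficients[l] == pytest.approx(
                    ols.params[l], abs=1e-10
                )

    def test_r_squared_invariant_to_weight_rescaling(self, rng):
        y, labels, w = random_cohort(rng)
        r1 = fit_subtype_model(y, labels, w).r_squared
        r2 = fit_subtype_model(y, labels, 5.0 * w).r_squared
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_r_squared_uses_weighted_grand_mean(self, rng):
        y, labels, w = random_cohort(rng)
        fit = fit_subtype_model(y, labels, w)
        fitted = np.array(
            [fit.estimate_for(l).mean for l in labels]
        )
        grand = np.average(y, weights=w)
        ssr = np.sum(w * (y - fitted) ** 2)
        sst = np.sum(w * (y - grand) ** 2)
        assert fit.r_squared == pytest.approx(1 - ssr / sst, abs=1e-10)

    def test_means_invariant_to_label_permutation(self, rng):
        y, labels, w = random_cohort(rng)
        fit1 = fit_subtype_model(y, labels, w, subtype_order=["G0", "G1", "G2"])
        fit2 = fit_subtype_model(y, labels, w, subtype_order=["G2", "G0", "G1"])
        for level in ("G0", "G1", "G2"):
            assert fit1.estimate_for(level).mean == pytest.approx(
                fit2.estimate_for(level).mean, abs=1e-10
            )


class TestCompareWeightings:
    def test_constant_nre_gives_identical_fits(self, rng):
        y, labels, _ = random_cohort(rng)
        fit_u, fit_w, delta, shifts = compare_weightings(
            y, labels, np.full(len(y), 0.42)
        )
        assert delta == pytest.approx(0.0, abs=1e-10)
        assert all(s == pytest.approx(0.0, abs=1e-10) for s in shifts.values())

    def test_weighted_means_track_the_prototypical_subset(self):
        # high-certainty members sit at a shifted outcome level; with
        # weights 1 vs 0.01 the weighted group mean lands near them
        y = np.array([10.0, 10.0, 0.0, 0.0, 5.0, 5.0, 1.0, 1.0])
        labels = np.array(["A"] * 4 + ["B"] * 4)
        w = np.array([1.0, 1.0, 0.01, 0.01, 1.0, 1.0, 0.01, 0.01])
        _, fit_w, _, _ = compare_weightings(y, labels, w)
        # hand-computed weighted means: A -> (10*2 + 0*0.02)/2.02
        assert fit_w.estimate_for("A").mean == pytest.approx(20.0 / 2.02)
        assert fit_w.estimate_for("B").mean == pytest.approx(10.02 / 2.02)

    def test_nre_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="\\[0, 1\\]"):
            compare_weightings([1.0, 2.0], ["A", "B"], [0.5, 1.5])

    def test_both_fits_use_identical_complete_cases(self):
        y = [1.0, np.nan, 3.0, 4.0]
        labels = ["A", "A", "B", "B"]
        fit_u, fit_w, _, _ = compare_weightings(y, labels, [0.2, 0.9, 0.5, 0.7])
        assert fit_u.n_used == fit_w.n_used == 3


class TestBootstrapCI:
    def test_constant_sample_degenerate_interval(self):
        lo, hi = bootstrap_ci(np.median, [4.2] * 30, n_boot=300, seed=1)
        assert lo == hi == 4.2

    def test_median_interval_contains_truth(self):
        data = np.arange(1, 1001, dtype=float)
        lo, hi = bootstrap_ci(np.median, data, n_boot=500, seed=7)
        assert lo < 500.5 < hi

    def test_deterministic_given_seed(self):
        data = np.random.default_rng(3).normal(size=50)
        assert bootstrap_ci(np.mean, data, seed=11) == bootstrap_ci(
            np.mean, data, seed=11
        )
        assert bootstrap_ci(np.mean, data, seed=11) != bootstrap_ci(
            np.mean, data, seed=12
        )

    def test_too_small_sample_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_ci(np.median, [1.0], seed=0)

    def test_low_n_boot_rejected(self):
        with pytest.raises(ValueError, match="200"):
            bootstrap_ci(np.median, [1.0, 2.0, 3.0], n_boot=50, seed=0)

    def test_nominal_coverage_for_the_mean(self):
        # ~95% coverage for the mean of normal samples (n=100), within
        # Monte-Carlo error over 300 replicates
        rng = np.random.default_rng(2026)
        hits = 0
        reps = 300
        for i in range(reps):
            sample = rng.normal(0.0, 1.0, size=100)
            lo, hi = bootstrap_ci(np.mean, sample, n_boot=400, seed=i)
            hits += lo <= 0.0 <= hi
        coverage = hits / reps
        assert 0.90 <= coverage <= 0.99
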