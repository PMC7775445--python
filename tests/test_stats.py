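import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from scipy import stats as sps

import salience_cpt as sc
from salience_cpt.stats import (
    MEASURES,
    battery_targets,
    bonferroni_threshold,
    choose_method,
    exclude_outliers,
    extreme_groups,
    gated_partial_correlation,
    independent_t_extreme_groups,
    min_detectable_r,
    one_sample_t,
    partial_correlation,
    polynomial_fit_r2,
    run_correlation_battery,
)
from tests.conftest import null_records, partial_correlation_precision_oracle


class TestOutlierExclusion:
    def test_single_extreme_point_removed(self):
        values = np.concatenate([np.zeros(31), [100.0]])
        keep = exclude_outliers(values)
        assert keep.sum() == 31
        assert not keep[-1]

    def test_constant_sample_keeps_all(self):
        keep = exclude_outliers(np.full(31, 3.0))
        assert keep.all()

    def test_single_pass_no_reiteration(self):
        # After removing the big outlier the remaining spread shrinks, but a
        # second pass must NOT happen: 10 stays in.
        values = np.concatenate([np.zeros(30), [10.0], [1000.0]])
        keep = exclude_outliers(values)
        assert not keep[-1]
        assert keep[-2]

    def test_clean_normal_sample_untouched(self):
        rng = np.random.default_rng(0)
        keep = exclude_outliers(rng.standard_normal(31))
        assert keep.all()

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            exclude_outliers(np.array([1.0, 2.0]))


class TestMethodGate:
    def test_gaussian_goes_pearson(self):
        rng = np.random.default_rng(1)
        x, y = rng.standard_normal(31), rng.standard_normal(31)
        method, gate = choose_method(x, y)
        assert method == "pearson"
        assert gate["x"] > 0.05 and gate["y"] > 0.05

    def test_lognormal_triggers_spearman(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(100):
            x = rng.standard_normal(31)
            y = np.exp(rng.standard_normal(31))
            hits += choose_method(x, y)[0] == "spearman"
        assert hits >= 90  # Shapiro-Wilk has high power vs lognormal at n=31

    def test_gate_is_affine_invariant(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(31)
        y = np.exp(rng.standard_normal(31))
        assert choose_method(x, y)[0] == choose_method(3 * x - 7, 2 * y + 5)[0]

    def test_constant_counts_as_non_normal(self):
        method, gate = choose_method(np.full(31, 2.0), np.random.default_rng(4).standard_normal(31))
        assert method == "spearman"
        assert gate["x"] == 0.0


class TestPartialCorrelation:
    def test_matches_precision_matrix_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            x = rng.standard_normal(31)
            y = 0.4 * x + rng.standard_normal(31)
            cov = rng.standard_normal((31, 3))
            r, _ = partial_correlation(x, y, cov, "pearson")
            oracle = partial_correlation_precision_oracle(x, y, cov)
            assert r == pytest.approx(oracle, abs=1e-10)

    def test_matches_pingouin_pearson(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        cov = rng.standard_normal((40, 3))
        df = pd.DataFrame(
            {"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1], "c3": cov[:, 2]}
        )
        ours_r, ours_p = partial_correlation(x, y, cov, "pearson")
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2", "c3"])
        assert ours_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours_p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_matches_pingouin_spearman(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(40)
        y = 0.5 * x + rng.standard_normal(40)
        cov = rng.standard_normal((40, 2))
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1]})
        ours_r, ours_p = partial_correlation(x, y, cov, "spearman")
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"], method="spearman")
        assert ours_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert ours_p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_orthogonal_covariates_equal_zero_order(self):
        rng = np.random.default_rng(8)
        n = 40
        x = rng.standard_normal(n)
        y = 0.6 * x + rng.standard_normal(n)
        # project covariates out of span{1, x, y}
        basis = np.column_stack([np.ones(n), x, y])
        q, _ = np.linalg.qr(basis)
        cov = rng.standard_normal((n, 2))
        cov = cov - q @ (q.T @ cov)
        r, _ = partial_correlation(x, y, cov, "pearson")
        assert r == pytest.approx(float(np.corrcoef(x, y)[0, 1]), abs=1e-9)

    def test_y_equal_to_covariate_gives_zero(self):
        rng = np.random.default_rng(9)
        x = rng.standard_normal(31)
        c = rng.standard_normal(31)
        r, p = partial_correlation(x, c, c[:, None], "pearson")
        assert r == 0.0
        assert p == 1.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            partial_correlation(np.zeros(4), np.zeros(4), np.zeros((4, 3)))

    def test_collinear_covariates_rejected(self):
        rng = np.random.default_rng(10)
        x, y = rng.standard_normal(31), rng.standard_normal(31)
        c = rng.standard_normal(31)
        with pytest.raises(ValueError):
            partial_correlation(x, y, np.column_stack([c, 2 * c]), "pearson")

    def test_gated_wrapper_excludes_outlier_and_reports(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(31)
        y = 0.5 * x + 0.3 * rng.standard_normal(31)
        y[0] = 50.0  # gross outlier
        cov = rng.standard_normal((31, 3))
        res = gated_partial_correlation(x, y, cov, "adhd", "measure")
        assert res.n_outliers_removed == 1
        assert res.n_after_exclusion == 30
        assert res.method in ("pearson_partial", "spearman_partial")

    def test_gated_wrapper_drops_nan_pairwise(self):
        rng = np.random.default_rng(12)
        x = rng.standard_normal(31)
        y = 0.5 * x + rng.standard_normal(31)
        y[3] = np.nan
        cov = rng.standard_normal((31, 3))
        res = gated_partial_correlation(x, y, cov)
        assert res.n_after_exclusion + res.n_outliers_removed == 30


class TestTTests:
    def test_one_sample_known_values(self):
        out = one_sample_t(np.array([1.0, 2.0, 3.0]), mu=0.0)
        assert out["t"] == pytest.approx(2.0 / (1.0 / np.sqrt(3.0)))
        assert out["df"] == 2
        assert out["cohens_d"] == pytest.approx(2.0)

    def test_one_sample_constant_at_mu(self):
        out = one_sample_t(np.full(10, 5.0), mu=5.0)
        assert out["t"] == 0.0
        assert out["p"] == 1.0

    def test_one_sample_matches_scipy(self):
        rng = np.random.default_rng(13)
        v = rng.standard_normal(25) + 0.4
        out = one_sample_t(v, mu=0.0)
        ref = sps.ttest_1samp(v, 0.0)
        assert out["t"] == pytest.approx(float(ref.statistic))
        assert out["p"] == pytest.approx(float(ref.pvalue))

    def test_extreme_groups_tercile_sizes(self):
        records = pd.DataFrame({"adhd_index": np.arange(30), "v": np.zeros(30)})
        hi, lo = extreme_groups(records)
        assert len(hi) == len(lo) == 10
        assert set(records.loc[hi, "adhd_index"]) == set(range(20, 30))
        assert set(records.loc[lo, "adhd_index"]) == set(range(10))

    def test_extreme_groups_deterministic_ties(self):
        records = pd.DataFrame(
            {"adhd_index": [1] * 30, "subject_id": [f"s{i:02d}" for i in range(30)]}
        )
        hi1, lo1 = extreme_groups(records)
        hi2, lo2 = extreme_groups(records)
        assert np.array_equal(hi1, hi2) and np.array_equal(lo1, lo2)

    def test_extreme_groups_too_small(self):
        with pytest.raises(ValueError):
            extreme_groups(pd.DataFrame({"adhd_index": [1, 2, 3]}))

    def test_independent_t_pooled_formula(self):
        rng = np.random.default_rng(14)
        records = pd.DataFrame(
            {
                "adhd_index": np.repeat([0, 1, 2], 10),
                "v": np.concatenate(
                    [rng.normal(0, 1, 10), rng.normal(0, 1, 10), rng.normal(1, 1, 10)]
                ),
            }
        )
        out = independent_t_extreme_groups(records, "v")
        a = records["v"][20:].to_numpy()
        b = records["v"][:10].to_numpy()
        ref = sps.ttest_ind(a, b, equal_var=out["equal_var"])
        assert out["t"] == pytest.approx(float(ref.statistic))
        assert out["p"] == pytest.approx(float(ref.pvalue))
        assert out["n"] == (10, 10)

    def test_identical_distributions_small_t(self):
        rng = np.random.default_rng(15)
        records = pd.DataFrame(
            {"adhd_index": np.arange(60), "v": rng.standard_normal(60)}
        )
        out = independent_t_extreme_groups(records, "v")
        assert abs(out["t"]) < 2.5


class TestPolynomialFits:
    def test_exact_quadratic_r2_one(self):
        x = np.linspace(-2, 2, 31)
        y = 1.0 + 2.0 * x - 3.0 * x**2
        assert polynomial_fit_r2(x, y, "quadratic") == pytest.approx(1.0)
        assert polynomial_fit_r2(x, y, "cubic") == pytest.approx(1.0)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(16)
        x = rng.standard_normal(31)
        y = rng.standard_normal(31)
        design = np.column_stack([np.ones_like(x), x, x**2])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        resid = y - design @ beta
        oracle = 1.0 - (resid @ resid) / ((y - y.mean()) ** 2).sum()
        assert polynomial_fit_r2(x, y, "quadratic") == pytest.approx(oracle, abs=1e-10)

    def test_nesting_monotonicity(self):
        rng = np.random.default_rng(17)
        x = rng.standard_normal(31)
        y = rng.standard_normal(31)
        r2_lin = polynomial_fit_r2(x, y, "linear")
        r2_quad = polynomial_fit_r2(x, y, "quadratic")
        r2_cub = polynomial_fit_r2(x, y, "cubic")
        assert r2_lin <= r2_quad + 1e-12 <= r2_cub + 1e-12

    def test_log_fit_shifts_nonpositive_x(self):
        x = np.linspace(-5, 5, 31)
        y = np.linspace(0, 1, 31)
        r2 = polynomial_fit_r2(x, y, "log")
        assert 0.0 <= r2 <= 1.0

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            polynomial_fit_r2(np.arange(10.0), np.arange(10.0), "quartic")


class TestThresholdsAndPower:
    def test_bonferroni(self):
        assert bonferroni_threshold(0.05, 4) == pytest.approx(0.0125)
        assert bonferroni_threshold(0.05, 1) == pytest.approx(0.05)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)

    def test_min_detectable_r_closed_form(self):
        z = sps.norm.ppf(0.975) + sps.norm.ppf(0.80)
        assert min_detectable_r(31) == pytest.approx(np.tanh(z / np.sqrt(28)))
        assert min_detectable_r(50) == pytest.approx(np.tanh(z / np.sqrt(47)))

    def test_min_detectable_r_monotone_decreasing(self):
        values = [min_detectable_r(n) for n in (10, 31, 100, 1000)]
        assert all(a > b for a, b in zip(values, values[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            min_detectable_r(3)


class TestBattery:
    def test_targets_structure(self):
        targets = battery_targets()
        assert len(targets) == 20  # (3 primary + 2 replication sites) x 4 measures
        assert len(battery_targets(include_replication=False)) == 12
        comps = {t[0] for t in targets}
        assert comps == {"inhibition_P3", "salience_P3", "salience_N2"}
        assert all(t[3] == f"{t[0]}_{t[1]}_{t[2]}" for t in targets)

    def test_battery_on_null_records(self):
        records = null_records(60, seed=18)
        battery = run_correlation_battery(
            records, targets=battery_targets(include_replication=False)
        )
        assert len(battery) == 12
        assert set(battery["measure"]) == set(MEASURES)
        assert (battery["p"] >= 0).all() and (battery["p"] <= 1).all()
        assert (battery["n"] <= 60).all()
        # with all effects null, large coefficients should not appear
        assert battery["coefficient"].abs().max() < 0.5

    def test_battery_flags_consistent(self):
        records = null_records(40, seed=19)
        battery = run_correlation_battery(
            records, targets=battery_targets(include_replication=False)
        )
        assert (battery["sig_bonf"] <= battery["sig_unc"]).all()
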