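"""Correlation, leave-one-out, agreement and filtering statistics."""

import numpy as np
import pandas as pd
import pytest

from prrtdose.stats import (
    filter_tumours,
    kidney_average,
    log_ratio_bland_altman,
    loo_interval,
    pearson,
    rmcorr,
    weighted_pearson,
)


def rmcorr_dummy_regression_oracle(subject_ids, x, y):
    """Brute-force ANCOVA: subject dummies + common slope via lstsq."""
    subject_ids = np.asarray(subject_ids)
    ids = np.unique(subject_ids)
    dummies = (subject_ids[:, None] == ids[None, :]).astype(float)
    X_full = np.column_stack([dummies, x])
    beta, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    resid_full = y - X_full @ beta
    ss_full = float(resid_full @ resid_full)
    beta0, *_ = np.linalg.lstsq(dummies, y, rcond=None)
    resid_red = y - dummies @ beta0
    ss_red = float(resid_red @ resid_red)
    ss_x = ss_red - ss_full
    r = np.sign(beta[-1]) * np.sqrt(ss_x / (ss_x + ss_full))
    return float(r), float(beta[-1])


class TestPearson:
    def test_perfect_line(self):
        x = np.arange(5.0)
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)
        assert res.intercept == pytest.approx(1.0)

    def test_matches_direct_formula_on_fixed_table(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 9.0])
        y = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        res = pearson(x, y)
        r_direct = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert res.r == pytest.approx(r_direct, abs=1e-14)

    def test_symmetry_in_arguments(self):
        rng = np.random.default_rng(1)
        x, y = rng.random(10), rng.random(10)
        assert pearson(x, y).r == pytest.approx(pearson(y, x).r)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestWeightedPearson:
    def test_equal_weights_reduce_to_pearson(self):
        rng = np.random.default_rng(2)
        x, y = rng.random(8), rng.random(8)
        w = np.full(8, 3.0)
        a, b = weighted_pearson(x, y, w), pearson(x, y)
        assert a.r == pytest.approx(b.r, abs=1e-12)
        assert a.slope == pytest.approx(b.slope, abs=1e-12)

    def test_integer_weights_equal_expanded_dataset(self):
        rng = np.random.default_rng(3)
        x, y = rng.random(6), rng.random(6)
        w = np.array([1, 2, 3, 1, 2, 4])
        res_w = weighted_pearson(x, y, w)
        xe = np.repeat(x, w)
        ye = np.repeat(y, w)
        res_e = pearson(xe, ye)
        assert res_w.r == pytest.approx(res_e.r, abs=1e-12)
        assert res_w.slope == pytest.approx(res_e.slope, abs=1e-12)

    def test_perfect_weighted_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = weighted_pearson(x, 3 * x - 1, np.array([1.0, 5.0, 2.0, 1.0]))
        assert res.r == pytest.approx(1.0)


class TestRmcorr:
    def test_parallel_lines_give_perfect_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        sid = np.array(["a", "a", "a", "b", "b", "b"])
        y = 3 * x + np.where(sid == "a", 10.0, -5.0)
        res = rmcorr(sid, x, y)
        assert res.r == pytest.approx(1.0)
        assert res.slope == pytest.approx(3.0)

    def test_invariant_to_per_subject_offsets(self):
        rng = np.random.default_rng(4)
        sid = np.repeat(np.arange(5), 4)
        x = rng.random(20)
        y = 2 * x + rng.normal(0, 0.1, 20)
        r0 = rmcorr(sid, x, y).r
        y_shift = y + np.repeat(rng.normal(0, 50, 5), 4)
        assert rmcorr(sid, x, y_shift).r == pytest.approx(r0, abs=1e-12)

    def test_matches_dummy_variable_regression_oracle(self):
        rng = np.random.default_rng(5)
        sid = np.repeat(np.arange(6), [3, 4, 2, 5, 3, 4])
        x = rng.random(21) * 10
        y = 1.7 * x + np.repeat(rng.normal(0, 5, 6), [3, 4, 2, 5, 3, 4])
        y += rng.normal(0, 1.0, 21)
        res = rmcorr(sid, x, y)
        r_oracle, slope_oracle = rmcorr_dummy_regression_oracle(sid, x, y)
        assert res.r == pytest.approx(r_oracle, abs=1e-10)
        assert res.slope == pytest.approx(slope_oracle, abs=1e-10)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        sid = np.repeat(np.arange(5), 4)
        x = rng.random(20)
        y = 0.8 * x + np.repeat(rng.normal(0, 1, 5), 4) + rng.normal(0, 0.3, 20)
        res = rmcorr(sid, x, y)
        df = pd.DataFrame({"s": sid, "x": x, "y": y})
        ref = pg.rm_corr(data=df, x="x", y="y", subject="s")
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-6)
        assert res.p == pytest.approx(float(ref["pval"].iloc[0]), rel=1e-4)

    def test_singletons_dropped_with_warning(self):
        sid = np.array(["a", "a", "a", "b"])
        x = np.array([1.0, 2.0, 3.0, 7.0])
        y = np.array([1.0, 2.0, 3.1, 100.0])
        with pytest.warns(UserWarning, match="single observation"):
            with pytest.raises(ValueError):
                rmcorr(sid, x, y)  # only one subject left


class TestLooInterval:
    def test_perfect_line_gives_degenerate_interval(self):
        units = [(float(i), 2.0 * i + 1) for i in range(6)]
        fn = lambda u: pearson([a for a, _ in u], [b for _, b in u])  # noqa: E731
        assert loo_interval(units, fn) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_outlier_widens_interval(self):
        rng = np.random.default_rng(7)
        x = rng.random(9)
        y = rng.normal(0, 1, 9)
        units = list(zip(x, y)) + [(30.0, 30.0)]  # leverage point forces r up
        fn = lambda u: pearson([a for a, _ in u], [b for _, b in u])  # noqa: E731
        full_r = fn(units).r
        no_outlier_r = fn(units[:-1]).r
        lo, hi = loo_interval(units, fn)
        assert lo <= no_outlier_r <= hi
        assert hi - lo > abs(full_r - no_outlier_r) * 0.5

    def test_number_of_recomputations(self):
        calls = []

        def fn(u):
            calls.append(len(u))
            return pearson([a for a, _ in u], [b for _, b in u])

        units = [(0.0, 0.1), (1.0, 1.2), (2.0, 1.8), (3.0, 3.3)]
        loo_interval(units, fn)
        assert len(calls) == 4 and all(n == 3 for n in calls)

    def test_too_few_units_rejected(self):
        with pytest.raises(ValueError):
            loo_interval([(1, 1)] * 3, lambda u: None)


class TestBlandAltman:
    def test_identical_values(self):
        res = log_ratio_bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.mean_deviation_pct == pytest.approx(0.0)
        assert res.ci_low_pct == pytest.approx(0.0)
        assert res.ci_high_pct == pytest.approx(0.0)

    def test_constant_factor_two(self):
        meas = np.array([1.0, 2.0, 5.0])
        res = log_ratio_bland_altman(2 * meas, meas)
        assert res.mean_deviation_pct == pytest.approx(100.0)
        assert res.ci_low_pct == pytest.approx(100.0)
        assert res.ci_high_pct == pytest.approx(100.0)

    def test_monte_carlo_matches_closed_form(self):
        rng = np.random.default_rng(8)
        mu, sigma, n = 0.1, 0.5, 100_000
        d = rng.normal(mu, sigma, n)
        meas = np.ones(n)
        res = log_ratio_bland_altman(np.exp(d), meas)
        assert res.mean_deviation_pct == pytest.approx(
            (np.exp(mu) - 1) * 100, abs=0.5
        )
        assert res.ci_low_pct == pytest.approx(
            (np.exp(mu - 1.96 * sigma) - 1) * 100, rel=0.01
        )
        assert res.ci_high_pct == pytest.approx(
            (np.exp(mu + 1.96 * sigma) - 1) * 100, rel=0.01
        )

    def test_patient_level_averages_first(self):
        pred = [2.0, 4.0, 1.0]
        meas = [1.0, 1.0, 1.0]
        res = log_ratio_bland_altman(pred, meas, level="patient",
                                     patient_ids=["a", "a", "b"])
        assert res.n == 2
        assert res.log_mean == pytest.approx(0.5 * (np.log(3.0) + np.log(1.0)))

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            log_ratio_bland_altman([1.0, -1.0], [1.0, 1.0])


class TestFilterAndKidneys:
    def test_strict_boundary(self):
        df = pd.DataFrame({"volume_pet_ml": [4.9, 5.0, 5.1],
                           "tumour_id": list("abc")})
        kept, excluded = filter_tumours(df)
        assert kept["tumour_id"].tolist() == ["c"]
        assert set(excluded["tumour_id"]) == {"a", "b"}

    def test_zero_cutoff_keeps_all(self):
        df = pd.DataFrame({"volume_pet_ml": [0.1, 5.0, 50.0]})
        kept, excluded = filter_tumours(df, volume_cutoff_ml=0.0)
        assert len(kept) == 3 and len(excluded) == 0

    def test_missing_volume_routed_with_reason(self):
        df = pd.DataFrame({"volume_pet_ml": [np.nan, 8.0]})
        kept, excluded = filter_tumours(df)
        assert len(kept) == 1
        assert excluded["exclusion_reason"].iloc[0] == "missing volume"

    def test_kept_count_matches_brute_force(self):
        rng = np.random.default_rng(9)
        vols = np.exp(rng.uniform(np.log(0.5), np.log(80), 200))
        df = pd.DataFrame({"volume_pet_ml": vols})
        kept, _ = filter_tumours(df)
        assert len(kept) == int((vols > 5.0).sum())

    def test_kidney_average(self):
        assert kidney_average(2.0, 4.0) == 3.0
        assert kidney_average(5.0, 5.0) == 5.0
        with pytest.warns(UserWarning, match="single kidney"):
            assert kidney_average(None, 7.0) == 7.0
        with pytest.raises(ValueError):
            kidney_average(None, None)
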