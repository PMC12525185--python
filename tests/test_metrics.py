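"""Validation statistics: R², CCC, IIC, Q², F, RMSE/MAE and cluster diagnostics."""

import numpy as np
import pytest
import scipy.stats

import smilescw as s
from smilescw.errors import UndefinedStatisticError

# Published per-set rows (R², n, printed integer F) of the univariate models:
# both target functions, five splits, active/passive/calibration sets.
PUBLISHED_F_ROWS = [
    (0.4791, 63, 56), (0.3648, 63, 35), (0.4507, 65, 52),
    (0.4473, 62, 49), (0.3894, 59, 36), (0.4161, 63, 43),
    (0.4589, 66, 54), (0.4700, 60, 51), (0.5530, 59, 71),
    (0.5687, 66, 84), (0.3214, 64, 29), (0.4549, 62, 50),
    (0.4992, 60, 58), (0.4753, 66, 58), (0.5726, 61, 79),
    (0.3206, 63, 29), (0.2829, 63, 24), (0.6803, 65, 134),
    (0.4053, 62, 41), (0.3246, 59, 27), (0.6543, 63, 115),
    (0.4588, 66, 54), (0.4267, 60, 43), (0.7075, 59, 138),
    (0.5773, 66, 87), (0.3646, 64, 36), (0.6193, 62, 98),
    (0.5218, 60, 63), (0.4557, 66, 54), (0.6524, 61, 111),
]


class TestR2:
    def test_perfect_and_sign_blind(self):
        obs = np.array([1.0, 2.0, 4.0])
        assert s.r2(obs, obs) == pytest.approx(1.0)
        assert s.r2(obs, -obs) == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            s.r2([1, 1, 1], [1, 2, 3])

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        obs, pred = rng.normal(size=30), rng.normal(size=30)
        r, _ = scipy.stats.pearsonr(obs, pred)
        assert s.r2(obs, pred) == pytest.approx(r**2, rel=1e-12)


class TestCCC:
    def test_identity(self):
        obs = np.array([1.0, 2.0, 3.0, 7.0])
        assert s.ccc(obs, obs) == pytest.approx(1.0)

    def test_pure_shift_closed_form(self):
        rng = np.random.default_rng(1)
        obs = rng.normal(size=200)
        c = 1.5
        var = obs.var()
        assert s.ccc(obs, obs + c) == pytest.approx(
            2 * var / (2 * var + c**2), rel=1e-10
        )

    def test_formula_oracle_and_bound(self):
        rng = np.random.default_rng(2)
        obs, pred = rng.normal(size=40), rng.normal(size=40)
        n = 40
        cov = np.cov(obs, pred, ddof=0)[0, 1]
        ref = 2 * cov / (obs.var() + pred.var() + (obs.mean() - pred.mean()) ** 2)
        val = s.ccc(obs, pred)
        assert val == pytest.approx(ref, rel=1e-12)
        r = scipy.stats.pearsonr(obs, pred)[0]
        assert abs(val) <= abs(r) + 1e-12


class TestIIC:
    def test_worked_example(self):
        # residuals (-1, 0, 1): one-sided MAEs 1 and 0.5, r = 15/sqrt(252)
        val = s.iic([0, 1, 3], [1, 1, 2])
        assert val == pytest.approx(0.5 * 15 / np.sqrt(252), rel=1e-12)
        assert round(val, 4) == 0.4725

    def test_symmetric_residuals_equal_r(self):
        obs = np.array([0.0, 1.0, 2.0, 3.0])
        pred = np.array([0.5, 0.5, 2.5, 2.5])  # residuals -.5,+.5,-.5,+.5
        r = scipy.stats.pearsonr(obs, pred)[0]
        assert s.iic(obs, pred) == pytest.approx(r, rel=1e-12)

    def test_perfect_fit_convention(self):
        obs = np.array([1.0, 2.0, 3.0])
        assert s.iic(obs, obs) == pytest.approx(1.0)

    def test_one_empty_class_gives_zero(self):
        obs = np.array([1.0, 2.0, 3.0])
        pred = obs - 0.5  # all residuals positive
        assert s.iic(obs, pred) == 0.0

    def test_magnitude_bounded_by_r(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            obs, pred = rng.normal(size=25), rng.normal(size=25)
            r = scipy.stats.pearsonr(obs, pred)[0]
            assert abs(s.iic(obs, pred)) <= abs(r) + 1e-12


class TestQ2:
    def test_exact_linear_data(self):
        x = np.arange(10.0)
        assert s.q2_loo(x, 3 * x + 1) == pytest.approx(1.0)

    def test_brute_force_refit_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=5)
        y = 0.5 * x + rng.normal(size=5)
        press = 0.0
        for i in range(5):
            mask = np.arange(5) != i
            c0, c1 = s.fit_calibration_line(x[mask], y[mask])
            press += (y[i] - (c0 + c1 * x[i])) ** 2
        tss = ((y - y.mean()) ** 2).sum()
        assert s.q2_loo(x, y) == pytest.approx(1 - press / tss, rel=1e-10)

    def test_never_exceeds_r2(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            x = rng.normal(size=12)
            y = x + rng.normal(size=12)
            c0, c1 = s.fit_calibration_line(x, y)
            assert s.q2_loo(x, y) <= s.r2(y, c0 + c1 * x) + 1e-12


class TestF:
    @pytest.mark.parametrize("r2_val, n, expected", PUBLISHED_F_ROWS)
    def test_reproduces_published_integers(self, r2_val, n, expected):
        assert round(s.f_from_r2(r2_val, n)) == expected

    def test_small_case(self):
        assert s.f_from_r2(0.5, 4) == pytest.approx(2.0)

    def test_monotone_in_r2(self):
        values = [s.f_from_r2(r, 60) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert values == sorted(values)
        assert all(b > a for a, b in zip(values, values[1:]))

    def test_r2_one_is_infinite(self):
        with pytest.raises(UndefinedStatisticError):
            s.f_from_r2(1.0, 60)


class TestRmseMae:
    def test_examples(self):
        assert s.rmse_mae([1, 2], [1, 2]) == (0.0, 0.0)
        assert s.rmse_mae([1, -1], [0, 0]) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_formula_oracle_and_ordering(self):
        rng = np.random.default_rng(6)
        obs, pred = rng.normal(size=30), rng.normal(size=30)
        rmse, mae = s.rmse_mae(obs, pred)
        d = obs - pred
        assert rmse == pytest.approx(np.sqrt((d**2).mean()), rel=1e-12)
        assert mae == pytest.approx(np.abs(d).mean(), rel=1e-12)
        assert rmse >= mae


class TestClusterR2:
    def test_all_residuals_nonnegative(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        pred = obs - 0.5
        report = s.cluster_r2(obs, pred)
        assert report.n_low == 0 and report.low_cluster_r2 is None
        assert report.overall_r2 == pytest.approx(1.0)

    def test_ties_go_to_high_cluster(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        report = s.cluster_r2(obs, obs)
        assert report.n_high == 4 and report.n_low == 0

    def test_two_band_construction(self):
        # two parallel lines offset ±1 around the diagonal: within-cluster
        # correlation is perfect while the pooled correlation is diluted
        x = np.linspace(0, 3, 8)
        obs = np.concatenate([x + 1.0, x - 1.0])
        pred = np.concatenate([x, x])
        report = s.cluster_r2(obs, pred)
        assert report.n_low == 8 and report.n_high == 8
        assert report.low_cluster_r2 == pytest.approx(1.0)
        assert report.high_cluster_r2 == pytest.approx(1.0)
        assert report.overall_r2 < report.low_cluster_r2
        assert report.n == 16


def test_compute_bundle_consistency():
    rng = np.random.default_rng(7)
    x = rng.normal(size=25)
    y = 2 * x + rng.normal(size=25)
    c0, c1 = s.fit_calibration_line(x, y)
    bundle = s.compute_bundle(y, c0 + c1 * x, descriptor=x)
    assert bundle.n == 25
    assert bundle.r2 == pytest.approx(s.r2(y, c0 + c1 * x))
    assert bundle.q2 is not None and bundle.q2 <= bundle.r2
    assert bundle.rmse >= bundle.mae >= 0
    assert bundle.f == pytest.approx(s.f_from_r2(bundle.r2, 25))
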