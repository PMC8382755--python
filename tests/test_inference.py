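"""Normality gate, exact Spearman inference, Pearson, paired comparisons."""

import numpy as np
import pytest
from scipy import stats

import eyegaba as eg
from eyegaba.exceptions import (
    DegenerateInputError,
    InsufficientDataError,
    ParameterError,
)
from eyegaba.inference import _exact_p_from_s, _mc_p, spearman_s_null_counts

from _oracles import oracle_spearman, oracle_spearman_null_r


class TestNormalityGate:
    def test_constant_sample_degenerate_nonparametric(self):
        with pytest.warns(UserWarning):
            g = eg.normality_gate([1.0, 1.0, 1.0, 1.0])
        assert g.decision == "nonparametric"
        assert g.degenerate

    def test_too_small_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            eg.normality_gate([1.0, 2.0])

    def test_heavy_skew_detected(self, rng):
        flags = [
            eg.normality_gate(rng.lognormal(0, 1.2, size=80)).decision
            for _ in range(50)
        ]
        assert flags.count("nonparametric") >= 45

    def test_type_i_rate_under_normality(self, rng):
        """Under a normal sample the gate should stay parametric ~95% of the
        time (the Shapiro-Wilk type-I rate)."""
        flags = [
            eg.normality_gate(rng.normal(0, 1, size=40)).decision
            for _ in range(300)
        ]
        rate = flags.count("parametric") / 300
        assert 0.90 <= rate <= 0.99


class TestSpearmanExact:
    def test_monotone_transform_gives_r_one(self):
        x = np.array([0.3, 1.1, 2.0, 5.4, 9.9])
        res = eg.spearman_exact(x, np.exp(x))
        assert res.r == pytest.approx(1.0)

    def test_n3_concordant_p_is_two_sixths(self):
        res = eg.spearman_exact([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(2 / 6)
        assert res.p_method == "exact"

    @pytest.mark.parametrize(
        "y", [(3, 1, 4, 2), (1, 3, 2, 4), (4, 3, 2, 1), (2, 4, 1, 3)]
    )
    def test_n4_matches_enumeration_oracle(self, y):
        x = [1.0, 2.0, 3.0, 4.0]
        res = eg.spearman_exact(x, list(map(float, y)))
        r_o, p_o = oracle_spearman(x, y)
        assert res.r == pytest.approx(r_o, abs=1e-12)
        assert res.p == pytest.approx(p_o, abs=1e-12)

    def test_ties_handled_via_average_ranks(self, rng):
        x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
        y = [2.0, 1.0, 4.0, 4.0, 3.0, 6.0]
        res = eg.spearman_exact(x, y)
        r_scipy = stats.spearmanr(x, y).statistic
        assert res.r == pytest.approx(r_scipy)
        _, p_o = oracle_spearman(x, y)
        assert res.p == pytest.approx(p_o, abs=1e-12)

    def test_subset_dp_null_matches_enumeration(self):
        """The subset-DP exact null of S reproduces the n!-enumeration null."""
        for n in (5, 8):
            null_r = oracle_spearman_null_r(n)
            counts = spearman_s_null_counts(n)
            for r_obs in np.unique(np.round(np.abs(null_r), 12)):
                p_dp = _exact_p_from_s(n, float(r_obs))
                p_enum = float(np.mean(np.abs(null_r) >= r_obs - 1e-12))
                assert p_dp == pytest.approx(p_enum, abs=1e-12)
            assert counts.sum() == len(null_r)

    def test_exact_p_invariant_under_monotone_transform(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        a = eg.spearman_exact(x, y)
        b = eg.spearman_exact(np.exp(x), y**3)
        assert a.r == pytest.approx(b.r)
        assert a.p == pytest.approx(b.p)

    def test_p_nonincreasing_in_abs_r(self):
        n = 6
        null_r = oracle_spearman_null_r(n)
        rs = np.unique(np.abs(null_r))
        ps = [_exact_p_from_s(n, float(r)) for r in rs]
        assert all(p1 >= p2 - 1e-15 for p1, p2 in zip(ps, ps[1:]))

    def test_monte_carlo_requires_seed(self, rng):
        x = np.arange(10, dtype=float)
        y = rng.normal(size=10)
        y[1] = y[0]  # tie forces the Monte-Carlo path at n=10
        x[3] = x[2]
        with pytest.raises(ParameterError):
            eg.spearman_exact(x, y)
        res = eg.spearman_exact(x, y, seed=5)
        assert res.p_method == "monte_carlo"
        assert 0 < res.p <= 1

    def test_monte_carlo_close_to_exact(self, rng):
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        exact = eg.spearman_exact(x, y)  # tie-free n=10 -> DP route
        assert exact.p_method == "exact"
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        approx = _mc_p(rx, ry, exact.r, seed=17, n_mc=200_000)
        assert approx == pytest.approx(exact.p, abs=0.01)

    def test_insufficient_n_rejected(self):
        with pytest.raises(InsufficientDataError):
            eg.spearman_exact([1, 2], [3, 4])


class TestPearson:
    def test_affine_relationship(self):
        x = np.array([1.0, 2.0, 5.0, 7.0])
        assert eg.pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)
        assert eg.pearson_corr(x, -x).r == pytest.approx(-1.0)

    def test_degenerate_variable_rejected(self):
        with pytest.raises(DegenerateInputError):
            eg.pearson_corr([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_null_p_uniform(self, rng):
        """Independent normal pairs give a uniform p-value distribution."""
        ps = [
            eg.pearson_corr(rng.normal(size=12), rng.normal(size=12)).p
            for _ in range(300)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPairedCompare:
    def test_identical_pairs_degenerate(self):
        with pytest.warns(UserWarning):
            res = eg.paired_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.p == 1.0
        assert res.degenerate

    def test_shift_power_matches_closed_form(self, rng):
        """Rejection rate under a constant shift with normal noise should
        match the paired t-test's analytical power."""
        n, shift, sd = 30, 0.5, 1.0
        ncp = shift * np.sqrt(n) / sd
        tcrit = stats.t.ppf(0.975, n - 1)
        power = 1 - stats.nct.cdf(tcrit, n - 1, ncp) + stats.nct.cdf(-tcrit, n - 1, ncp)
        rejections = 0
        reps = 400
        for _ in range(reps):
            b = rng.normal(0, 1.0, size=n)
            a = b + shift + rng.normal(0, sd, size=n)  # paired diffs ~ N(shift, sd)
            rejections += eg.paired_compare(a, b).p < 0.05
        assert rejections / reps == pytest.approx(power, abs=0.08)

    def test_null_type_i_rate(self, rng):
        rejections = 0
        reps = 400
        for _ in range(reps):
            a = rng.normal(size=20)
            b = rng.normal(size=20)
            rejections += eg.paired_compare(a, b).p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)
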