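"""Shared statistics: BCa bootstrap, Fisher, Mann-Whitney, Pearson."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from citniche.stats import (
    BootstrapConfig,
    ContingencyTable2x2,
    _bca_levels,
    bca_interval,
    fisher_exact_two_tailed,
    mann_whitney_two_tailed,
    pearson_test,
    rng_for,
)


class TestBcaInterval:
    def test_degenerate_data_gives_degenerate_interval(self):
        assert bca_interval([7, 7, 7, 7], BootstrapConfig(n_boot=100, seed=0)) == (7, 7)

    def test_fewer_than_two_replicates_rejected(self):
        with pytest.raises(ValueError):
            bca_interval([1.0], BootstrapConfig(n_boot=100, seed=0))

    def test_zero_correction_reduces_to_percentile_levels(self):
        # With z0 = 0 and a = 0 the BCa quantile levels are exactly the
        # percentile method's.
        lo, hi = _bca_levels(0.0, 0.0, 0.05)
        assert lo == pytest.approx(0.025, abs=1e-12)
        assert hi == pytest.approx(0.975, abs=1e-12)

    def test_matches_scipy_bca_endpoints(self):
        rng = np.random.default_rng(7)
        x = rng.exponential(2.0, 25)
        mine = bca_interval(x, BootstrapConfig(n_boot=20_000, seed=3))
        ref = sps.bootstrap(
            (x,), np.mean, n_resamples=20_000, method="BCa", random_state=3
        ).confidence_interval
        # Same method, independent implementation: agreement up to
        # Monte-Carlo resampling noise.
        assert mine[0] == pytest.approx(ref.low, abs=0.05)
        assert mine[1] == pytest.approx(ref.high, abs=0.05)

    def test_interval_contains_mean_and_is_seed_stable(self):
        vals = [1.0, 2.0, 4.0, 8.0, 16.0, 32.0]
        cfg = BootstrapConfig(n_boot=5000, seed=11)
        lo, hi = bca_interval(vals, cfg)
        assert lo <= np.mean(vals) <= hi
        assert bca_interval(vals, cfg) == (lo, hi)  # reproducible per seed

    def test_coverage_for_normal_mean(self):
        # BCa at n = 30 is known to undercover slightly; assert the
        # 90% floor used for interval quality throughout the package.
        rng = np.random.default_rng(42)
        cover = sum(
            (lambda ci: ci[0] <= 0 <= ci[1])(
                bca_interval(rng.normal(0, 1, 30), BootstrapConfig(n_boot=500, seed=s))
            )
            for s in range(400)
        )
        assert cover / 400 >= 0.90

    def test_weighted_statistic_travels_with_replicates(self):
        vals = np.array([0.1, 0.2, 0.3, 0.4])
        w = np.array([100.0, 1.0, 1.0, 1.0])
        lo, hi = bca_interval(vals, BootstrapConfig(n_boot=4000, seed=5), weights=w)
        # The heavily weighted replicate dominates every resample that
        # includes it, pulling the interval toward 0.1.
        assert lo < 0.15

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            BootstrapConfig(n_boot=0)
        with pytest.raises(ValueError):
            BootstrapConfig(alpha=1.5)


class TestFisherExact:
    # 2x2 tables reconstructed from the published clone counts, with
    # their printed two-tailed p-values.
    @pytest.mark.parametrize(
        "table,printed",
        [
            ((11, 1, 4, 8), 0.0094),   # yhiO: 11/12 vs 4/12
            ((11, 1, 3, 9), 0.0028),   # gltA: 11/12 vs 3/12
            ((1, 11, 9, 3), 0.0028),   # aceB: 1/12 vs 9/12
            ((0, 12, 5, 7), 0.0373),   # menC: 0/12 vs 5/12
            ((6, 6, 0, 12), 0.0137),   # fadL: 6/12 vs 0/12
            ((1, 15, 5, 3), 0.0069),   # dctA amplification by ancestry
        ],
    )
    def test_reproduces_printed_p_values(self, table, printed):
        p = fisher_exact_two_tailed(ContingencyTable2x2(*table))
        assert round(p, 4) == printed

    def test_symmetric_minimal_table(self):
        assert fisher_exact_two_tailed(ContingencyTable2x2(1, 0, 0, 1)) == 1.0

    def test_zero_margin_is_uninformative(self):
        assert fisher_exact_two_tailed(ContingencyTable2x2(0, 0, 3, 5)) == 1.0

    @given(
        a=st.integers(0, 12), b=st.integers(0, 12),
        c=st.integers(0, 12), d=st.integers(0, 12),
    )
    @settings(deadline=None, max_examples=100)
    def test_invariant_to_row_and_column_swaps(self, a, b, c, d):
        p0 = fisher_exact_two_tailed(ContingencyTable2x2(a, b, c, d))
        p_rows = fisher_exact_two_tailed(ContingencyTable2x2(c, d, a, b))
        p_cols = fisher_exact_two_tailed(ContingencyTable2x2(b, a, d, c))
        assert p0 == pytest.approx(p_rows, abs=1e-12)
        assert p0 == pytest.approx(p_cols, abs=1e-12)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 1, 1, 1)


class TestMannWhitney:
    def test_small_sample_exact_enumeration(self):
        # x=(1,2) vs y=(3,4): 2 of the C(4,2)=6 label assignments are as
        # extreme as observed.
        assert mann_whitney_two_tailed([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_samples_give_p_one(self):
        assert mann_whitney_two_tailed([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 1.0

    def test_all_tied_gives_p_one(self):
        assert mann_whitney_two_tailed([5, 5, 5], [5] * 20) == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_two_tailed([], [1.0])

    def test_exact_and_asymptotic_branches_agree(self, rng):
        # At combined n = 12 the exact and tie-corrected normal branches
        # should agree within 0.02 on continuous data.
        for _ in range(100):
            x, y = rng.normal(0, 1, 6), rng.normal(0, 1, 6)
            pe = mann_whitney_two_tailed(x, y)
            pa = sps.mannwhitneyu(
                x, y, alternative="two-sided", method="asymptotic"
            ).pvalue
            assert abs(pe - pa) <= 0.02

    def test_type_i_error_rate(self, rng):
        # 12 vs 12 from one distribution: rejection rate at alpha=0.05
        # within +-2 MC SE over 1000 simulations.
        rej = sum(
            mann_whitney_two_tailed(rng.normal(0, 1, 12), rng.normal(0, 1, 12)) < 0.05
            for _ in range(1000)
        )
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rej / 1000 - 0.05) <= 2 * se


class TestPearson:
    def test_perfect_linearity(self):
        r, df, p = pearson_test([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)
        assert df == 1
        assert p < 0.05

    def test_hand_computed_correlation(self):
        # cov/sd computation by hand for (1,2,3) vs (1,2,4) gives 0.9820.
        r, df, p = pearson_test([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(0.9820, abs=5e-5)
        assert df == 1

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_test([1, 1, 1], [1, 2, 3])

    def test_null_correlation_unbiased(self, rng):
        rs = [
            pearson_test(rng.normal(0, 1, 14), rng.normal(0, 1, 14))[0]
            for _ in range(1000)
        ]
        mc_se = np.std(rs) / np.sqrt(len(rs))
        assert abs(np.mean(rs)) < 2 * mc_se + 1e-9


def test_rng_streams_independent_and_reproducible():
    a1 = rng_for(1, "alpha").random(5)
    a2 = rng_for(1, "alpha").random(5)
    b = rng_for(1, "beta").random(5)
    assert np.array_equal(a1, a2)
    assert not np.array_equal(a1, b)
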