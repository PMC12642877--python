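"""Single-cell decoding: Poisson filter, rate conversion, ranks tests, extrapolation."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from lakesip.config import Config
from lakesip.singlecell import (
    CellCensus,
    bh_adjust,
    cell_rate,
    compare_groups,
    decode_cells,
    extrapolate_population,
    poisson_relative_error,
    summarize_distribution,
)
from lakesip.synthetic import CellGroupTruth, CellTruth, simulate_cells


class TestPoissonRelativeError:
    @pytest.mark.parametrize(
        "minor, major, expected",
        [(500, 45_000, 0.0450), (100, 10_000, 0.1005)],
    )
    def test_closed_form(self, minor, major, expected):
        assert poisson_relative_error(minor, major) == pytest.approx(expected, abs=5e-4)

    def test_zero_minor_counts_give_infinite_error(self):
        assert math.isinf(poisson_relative_error(0, 10_000))

    def test_filter_monotone_in_count_depth(self):
        """Scaling both counts up never increases the error (never un-passes)."""
        threshold = 0.05
        for scale in (1, 2, 5, 10, 100):
            errs = [
                poisson_relative_error(500 * scale, 45_000 * scale),
                poisson_relative_error(500, 45_000),
            ]
            assert errs[0] <= errs[1]
            if errs[1] < threshold:
                assert errs[0] < threshold


class TestCellRate:
    def test_closed_form(self):
        # (0.012089 - 0.0111) / (0.43 - 0.0111) * 1.75e-15 / 2
        r = cell_rate(0.012089, 0.0111, 0.43, 1.75e-15, 2.0)
        assert r == pytest.approx(2.0658e-18, rel=1e-3)

    def test_enrichment_implied_by_known_rate_round_trips(self):
        target = 2.17e-18
        x = 0.0111 + target * 2.0 / 1.75e-15 * (0.43 - 0.0111)
        assert cell_rate(x, 0.0111, 0.43, 1.75e-15, 2.0) == pytest.approx(target, rel=1e-12)

    def test_natural_abundance_is_zero_rate(self):
        assert cell_rate(0.0111, 0.0111, 0.43, 1.75e-15, 2.0) == 0.0

    def test_full_labeling_renews_entire_cell(self):
        r = cell_rate(0.43, 0.0111, 0.43, 1.75e-15, 2.0)
        assert r == pytest.approx(1.75e-15 / 2.0, rel=1e-12)

    def test_negative_excess_clipped_unless_raw(self):
        assert cell_rate(0.010, 0.0111, 0.43, 1.75e-15, 2.0) == 0.0
        assert cell_rate(0.010, 0.0111, 0.43, 1.75e-15, 2.0, clip=False) < 0.0

    def test_invalid_labeling_rejected(self):
        with pytest.raises(ValueError):
            cell_rate(0.012, 0.0111, 0.0111, 1.75e-15, 2.0)


class TestSummarizeDistribution:
    def test_symmetric_sample(self):
        s = summarize_distribution([1, 2, 3, 4, 5])
        assert s.median == 3.0
        assert s.iqr == 2.0
        assert s.skewness == pytest.approx(0.0, abs=1e-12)

    def test_all_equal_sample_flags_zero_variance(self):
        s = summarize_distribution([2.0, 2.0, 2.0, 2.0])
        assert s.skewness == 0.0
        assert s.zero_variance

    def test_tiny_sample_has_no_skewness(self):
        assert summarize_distribution([1.0, 2.0]).skewness is None

    def test_generator_calibration_recovered_at_n1e4(self):
        """Simulated AOA carbon rates summarize to the configured median/IQR."""
        ct = CellTruth(
            groups={"AOA": CellGroupTruth(10_000, 2.17e-18, 3.8e-18, 8.14e-18, 23.4e-18)},
            seed=3,
        )
        s = summarize_distribution(simulate_cells(ct)["true_rate_c"].to_numpy())
        assert s.median == pytest.approx(2.17e-18, rel=0.02)
        assert s.iqr == pytest.approx(3.8e-18, rel=0.02)
        assert s.skewness > 2  # right-skewed, as in the measured distributions


def brute_force_two_sided_p(a, b):
    """Independent oracle: enumerate every group assignment of the pooled ranks."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = len(a)
    offset = n_a * (n_a + 1) / 2.0
    total = n_a * len(b)
    u_obs = ranks[:n_a].sum() - offset
    u_min = min(u_obs, total - u_obs)
    us = np.array([sum(c) - offset for c in itertools.combinations(ranks, n_a)])
    eps = 1e-9
    return min(1.0, (np.sum(us <= u_min + eps) + np.sum(us >= total - u_min - eps)) / us.size)


class TestCompareGroups:
    def test_identical_singletons(self):
        c = compare_groups([1.0], [1.0])
        assert c.p_raw == 1.0

    def test_fully_separated_small_groups(self):
        c = compare_groups([1, 2, 3], [4, 5, 6])
        assert c.statistic == 0.0
        assert c.p_raw == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(6))
    def test_equals_enumeration_for_small_groups(self, seed):
        """Exact p matches brute-force enumeration, with and without ties."""
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 8, size=2)
        # integer draws force ties; floats are tie-free
        a = rng.integers(0, 6, n_a).astype(float) if seed % 2 else rng.normal(size=n_a)
        b = rng.integers(0, 6, n_b).astype(float) if seed % 2 else rng.normal(size=n_b)
        c = compare_groups(a, b)
        assert c.p_raw == pytest.approx(brute_force_two_sided_p(a, b), abs=1e-12)

    def test_large_sample_path_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(0.5, size=60)
        c = compare_groups(a, b)
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert c.p_raw == pytest.approx(ref.pvalue)

    def test_type_one_error_near_alpha_for_equal_lognormals(self):
        """Equal lognormal groups reject at ~5% (two-sided, alpha = .05)."""
        rng = np.random.default_rng(99)
        hits = 0
        n_sim = 10_000
        for _ in range(n_sim):
            a = rng.lognormal(0.0, 1.0, 25)
            b = rng.lognormal(0.0, 1.0, 25)
            hits += compare_groups(a, b).p_raw < 0.05
        assert hits / n_sim == pytest.approx(0.05, abs=0.01)


class TestBHAdjust:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_adjusted_values_dominate_raw_and_preserve_order(self, ps):
        adj = bh_adjust(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-15)
        assert np.all(adj <= 1.0)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-15)  # monotone in raw p


class TestExtrapolation:
    def test_volumetric_arithmetic(self):
        census = CellCensus("s", dapi_density=2.96e5, aoa_density=0.24e5)
        out = extrapolate_population({"AOA": 3.33e-18, "other": 0.0}, census)
        # 3.33e-18 mol/cell/d * 2.4e7 cells/l = 0.080 nmol/l/d
        assert out["volumetric_nmol_l_d"]["AOA"] == pytest.approx(0.080, abs=5e-4)

    def test_zero_density_gives_zero_share(self):
        census = CellCensus("s", dapi_density=1e5, aoa_density=0.0)
        out = extrapolate_population({"AOA": 1e-18, "other": 1e-18}, census)
        assert out["volumetric_nmol_l_d"]["AOA"] == 0.0
        assert out["shares"]["AOA"] == 0.0

    def test_shares_conserve(self):
        census = CellCensus("s", dapi_density=2.96e5, aoa_density=0.24e5)
        out = extrapolate_population({"AOA": 3.3e-18, "other": 0.4e-18}, census)
        assert sum(out["shares"].values()) == pytest.approx(1.0, abs=1e-12)

    def test_zero_combined_rate_flagged(self):
        census = CellCensus("s", dapi_density=1e5, aoa_density=1e4)
        out = extrapolate_population({"AOA": 0.0, "other": 0.0}, census)
        assert out["flag"] == "zero_combined_rate"
        assert math.isnan(out["shares"]["AOA"])


class TestEndToEnd:
    def test_filter_monotonicity_on_decoded_cells(self, config):
        """Raising the count depth never flips a passing cell to failing."""
        base = CellTruth(
            groups={"g": CellGroupTruth(300, 2.17e-18, 3.8e-18, 8.14e-18, 23.4e-18)},
            total_ion_counts=2e4,
            seed=4,
        )
        deep = CellTruth(groups=base.groups, total_ion_counts=2e6, seed=4)
        shallow_pass = decode_cells(simulate_cells(base), config, 0.43, 0.93, 2.0)[
            "passed_filter_c"
        ]
        deep_pass = decode_cells(simulate_cells(deep), config, 0.43, 0.93, 2.0)[
            "passed_filter_c"
        ]
        assert deep_pass.mean() >= shallow_pass.mean()

    def test_recovery_of_both_channels(self, config):
        ct = CellTruth(
            groups={"AOA": CellGroupTruth(2000, 2.17e-18, 3.8e-18, 8.14e-18, 23.4e-18)},
            seed=7,
        )
        decoded = decode_cells(simulate_cells(ct), config, 0.43, 0.93, 2.0)
        med_c = decoded.loc[decoded.passed_filter_c, "rate_c"].median()
        med_n = decoded.loc[decoded.passed_filter_n, "rate_n"].median()
        assert med_c == pytest.approx(2.17e-18, rel=0.05)
        assert med_n == pytest.approx(8.14e-18, rel=0.05)
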