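"""Generator contracts: closed-form means, seed determinism, distributional fidelity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lakesip.bulk import endpoint_rate, fit_oxidation_rate
from lakesip.config import Config
from lakesip.singlecell import decode_cells
from lakesip.synthetic import (
    CellGroupTruth,
    CellTruth,
    TemperatureTruth,
    TruthConfig,
    UnimodalModel,
    ExponentialModel,
    lognormal_from_median_iqr,
    simulate_cells,
    simulate_endpoint,
    simulate_oxidation_series,
    simulate_temperature,
)


class TestLognormalFromMedianIqr:
    @pytest.mark.parametrize(
        "median, iqr, sigma_expected",
        [
            (1.0, 1.4537, 1.000),  # sigma=1: IQR = e^z - e^-z = 1.4537
            (1.0, 0.0, 0.0),  # degenerate point mass
            (0.36e-18, 1.51e-18, 2.2036),  # heavy right skew, picoplankton C scale
        ],
    )
    def test_matches_quantile_oracle(self, median, iqr, sigma_expected):
        mu, sigma = lognormal_from_median_iqr(median, iqr)
        assert mu == pytest.approx(math.log(median))
        assert sigma == pytest.approx(sigma_expected, abs=5e-4)

    @given(
        median=st.floats(1e-20, 1e3), iqr_ratio=st.floats(0.0, 50.0)
    )
    @settings(max_examples=100, deadline=None)
    def test_round_trips_through_lognormal_quantiles(self, median, iqr_ratio):
        """(mu, sigma) reproduces the requested median and IQR exactly."""
        iqr = iqr_ratio * median
        mu, sigma = lognormal_from_median_iqr(median, iqr)
        z = 0.6744897501960817
        implied_iqr = math.exp(mu) * 2.0 * math.sinh(z * sigma)
        assert math.exp(mu) == pytest.approx(median, rel=1e-12)
        assert implied_iqr == pytest.approx(iqr, rel=1e-10, abs=1e-300)

    def test_rejects_invalid(self):
        with pytest.raises(ValueError):
            lognormal_from_median_iqr(0.0, 1.0)
        with pytest.raises(ValueError):
            lognormal_from_median_iqr(1.0, -0.1)


class TestOxidationSeries:
    def test_noiseless_accumulation_is_rate_times_f_times_t(self):
        truth = TruthConfig(
            true_ox_rate=139.0, f15n=0.93, noise_cv=0.0,
            timepoints=(0.0, 1.0, 2.0), duration=2.0,
        )
        (series,) = simulate_oxidation_series(truth, 1)
        np.testing.assert_allclose(series.n15_nitrite, [0.0, 129.27, 258.54], rtol=1e-12)

    def test_zero_rate_gives_flat_series(self):
        truth = TruthConfig(true_ox_rate=0.0, noise_cv=0.0)
        (series,) = simulate_oxidation_series(truth, 1)
        assert np.all(series.n15_nitrite == 0.0)

    def test_noise_cv_is_calibrated(self):
        """Per-timepoint sample CV over many replicates matches noise_cv."""
        truth = TruthConfig(noise_cv=0.05, seed=11)
        series = simulate_oxidation_series(truth, 500)
        conc = np.array([s.n15_nitrite for s in series])  # (500, 5)
        cv = conc[:, 1:].std(axis=0, ddof=1) / conc[:, 1:].mean(axis=0)
        np.testing.assert_allclose(cv, 0.05, rtol=0.15)

    def test_depletion_mode_rejects_pool_exhaustion(self):
        truth = TruthConfig(
            true_ox_rate=5000.0, nh4_pool=5324.0, depletion=True, noise_cv=0.0
        )
        with pytest.raises(ValueError, match="exhaust"):
            simulate_oxidation_series(truth, 1)

    def test_depletion_mode_label_never_exceeds_initial_labeled_ammonium(self):
        truth = TruthConfig(
            true_ox_rate=2600.0, nh4_pool=5324.0, depletion=True, noise_cv=0.0
        )
        for s in simulate_oxidation_series(truth, 3):
            assert np.all(s.n15_nitrite <= truth.f15n * truth.nh4_pool + 1e-9)

    def test_deterministic_for_fixed_seed(self):
        a = simulate_oxidation_series(TruthConfig(seed=3), 3)
        b = simulate_oxidation_series(TruthConfig(seed=3), 3)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.n15_nitrite, sb.n15_nitrite)


class TestEndpoint:
    def test_noiseless_excess_matches_closed_form(self):
        truth = TruthConfig(
            true_dic_rate=1.3, poc=10.0, f13c=0.43, duration=2.0,
            timepoints=(0.0, 2.0), noise_cv=0.0,
        )
        pair = simulate_endpoint(truth, "C")
        assert pair.x0 == pytest.approx(0.0111)
        assert pair.x_end - pair.x0 == pytest.approx(1.0894e-4, rel=1e-3)

    def test_zero_rate_stays_at_natural_abundance(self):
        truth = TruthConfig(true_dic_rate=0.0, noise_cv=0.0)
        pair = simulate_endpoint(truth, "C")
        assert pair.x_end == pair.x0

    def test_nitrogen_round_trips_through_estimator(self):
        truth = TruthConfig(true_n_assim_rate=5.5, pon=1.5, f15n=0.93, noise_cv=0.0)
        est = endpoint_rate(simulate_endpoint(truth, "N"))
        assert est.rate == pytest.approx(5.5, rel=1e-10)

    def test_unphysical_truth_rejected(self):
        truth = TruthConfig(true_dic_rate=1e9, poc=0.001, noise_cv=0.0)
        with pytest.raises(ValueError, match="newly fixed"):
            simulate_endpoint(truth, "C")


class TestSimulateCells:
    def test_zero_iqr_collapses_to_the_median(self, config):
        ct = CellTruth(
            groups={"AOA": CellGroupTruth(50, 2.17e-18, 0.0, 8.14e-18, 0.0)}, seed=1
        )
        cells = simulate_cells(ct)
        np.testing.assert_allclose(cells["true_rate_c"], 2.17e-18, rtol=1e-12)
        np.testing.assert_allclose(cells["true_rate_n"], 8.14e-18, rtol=1e-12)

    def test_decoded_median_recovers_truth_at_n2000(self, config):
        ct = CellTruth(
            groups={"AOA": CellGroupTruth(2000, 2.17e-18, 3.8e-18, 8.14e-18, 23.4e-18)},
            seed=7,
        )
        decoded = decode_cells(simulate_cells(ct), config, 0.43, 0.93, 2.0)
        med_c = decoded.loc[decoded.passed_filter_c, "rate_c"].median()
        assert med_c == pytest.approx(2.17e-18, rel=0.05)

    def test_distributional_fidelity_at_n1e4(self):
        """Sample median and IQR of drawn rates within 2% of targets."""
        ct = CellTruth(
            groups={"g": CellGroupTruth(10_000, 2.17e-18, 3.8e-18, 8.14e-18, 23.4e-18)},
            seed=5,
        )
        cells = simulate_cells(ct)
        r = cells["true_rate_c"].to_numpy()
        q25, q75 = np.percentile(r, [25, 75])
        assert np.median(r) == pytest.approx(2.17e-18, rel=0.02)
        assert q75 - q25 == pytest.approx(3.8e-18, rel=0.02)

    def test_low_count_depth_fails_the_error_filter(self, config):
        """At 1e4 major counts and x ~ 0.012 the ratio error is ~9%: filtered."""
        ct = CellTruth(
            groups={"g": CellGroupTruth(200, 0.36e-18, 0.0, 1.67e-18, 0.0)},
            total_ion_counts=1e4,
            seed=2,
        )
        decoded = decode_cells(simulate_cells(ct), config, 0.43, 0.93, 2.0)
        # x_c ~ 0.0114 at this truth; minor ~ 115 counts -> ~9% error
        assert decoded["rel_err_c"].median() == pytest.approx(0.09, abs=0.02)
        assert not decoded["passed_filter_c"].any()

    def test_deterministic_for_fixed_seed(self):
        a = simulate_cells(CellTruth(seed=9))
        b = simulate_cells(CellTruth(seed=9))
        assert a.equals(b)


class TestSimulateTemperature:
    def test_q10_doubles_per_ten_degrees(self):
        truth = TemperatureTruth(
            model_fix=ExponentialModel(r_ref=1.0, q10=2.0, t_ref=5.0),
            temperatures=(5.0, 15.0, 25.0, 35.0),
            replicates=1,
            noise_cv=0.0,
        )
        df = simulate_temperature(truth)
        fix = df[df.process == "dic_fixation"].sort_values("temperature_c")
        np.testing.assert_allclose(fix["rate"], [1.0, 2.0, 4.0, 8.0], rtol=1e-12)

    def test_noiseless_oxidation_peaks_at_t_opt(self):
        truth = TemperatureTruth(replicates=1, noise_cv=0.0)
        df = simulate_temperature(truth)
        ox = df[df.process == "oxidation"]
        assert ox.loc[ox["rate"].idxmax(), "temperature_c"] == 10.0

    def test_default_assim_fix_ratio_hits_both_calibration_points(self):
        """Noiseless defaults give assimilation:fixation 2.9 at 5C, 6.5 at 20C."""
        truth = TemperatureTruth(replicates=1, noise_cv=0.0)
        df = simulate_temperature(truth)
        pivot = df.pivot_table(index="temperature_c", columns="process", values="rate")
        ratio = pivot["n_assimilation"] / pivot["dic_fixation"]
        assert ratio[5.0] == pytest.approx(2.9, rel=1e-12)
        assert ratio[20.0] == pytest.approx(6.5, rel=1e-12)

    def test_oxidation_doubles_from_5_to_10(self):
        truth = TemperatureTruth(replicates=1, noise_cv=0.0)
        m = truth.model_ox
        assert m.rate(10.0) / m.rate(5.0) == pytest.approx(2.0, rel=1e-12)


class TestNoiselessRoundTrips:
    """Every simulated dataset inverts back to its truth at zero noise."""

    def test_oxidation_slope(self):
        truth = TruthConfig(true_ox_rate=7.5, noise_cv=0.0)
        (series,) = simulate_oxidation_series(truth, 1)
        assert fit_oxidation_rate(series).rate == pytest.approx(7.5, rel=1e-10)

    @pytest.mark.parametrize("element, attr", [("C", "true_dic_rate"), ("N", "true_n_assim_rate")])
    def test_endpoint(self, element, attr):
        truth = TruthConfig(noise_cv=0.0)
        est = endpoint_rate(simulate_endpoint(truth, element))
        assert est.rate == pytest.approx(getattr(truth, attr), rel=1e-10)
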