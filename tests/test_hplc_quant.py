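"""Standard-curve fitting, quantification and assay summaries."""

import numpy as np
import pytest

from capko.datamodel import StandardCurve, load_fixtures
from capko.hplc_quant import (
    CalibrationPoint,
    CalibrationSeries,
    category_means,
    fit_standard_curve,
    quantify_sample,
    recovery_rate,
    replicate_summary,
)
from capko.rounding import round_half_up
from capko.synthetic_data import gen_peak_areas

CAPSAICIN_STANDARDS = [0.313, 1.25, 5.0, 20.0, 80.0]


def series_on_line(slope, intercept, concs=CAPSAICIN_STANDARDS):
    return CalibrationSeries(
        points=[
            CalibrationPoint(concentration=c, peak_area=slope * c + intercept)
            for c in concs
        ]
    )


class TestFit:
    def test_exact_line_through_origin(self):
        curve = fit_standard_curve(series_on_line(1000.0, 0.0))
        assert curve.slope == pytest.approx(1000.0)
        assert curve.intercept == pytest.approx(0.0, abs=1e-9)
        assert curve.r_squared == pytest.approx(1.0)

    def test_exact_line_with_intercept(self):
        curve = fit_standard_curve(series_on_line(500.0, 20.0))
        assert curve.slope == pytest.approx(500.0)
        assert curve.intercept == pytest.approx(20.0)

    def test_noisy_refit_recovers_slope(self):
        truth = StandardCurve(slope=800.0, intercept=0.0, r_squared=1.0)
        areas = gen_peak_areas(truth, CAPSAICIN_STANDARDS, noise_sd_rel=0.01, seed=11)
        series = CalibrationSeries(
            points=[
                CalibrationPoint(concentration=c, peak_area=a)
                for c, a in zip(CAPSAICIN_STANDARDS, areas)
            ]
        )
        assert fit_standard_curve(series).slope == pytest.approx(800.0, rel=0.05)

    def test_degenerate_series_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            CalibrationSeries(
                points=[
                    CalibrationPoint(concentration=5.0, peak_area=1.0),
                    CalibrationPoint(concentration=5.0, peak_area=2.0),
                ]
            )


class TestQuantify:
    def test_powder_dimensional_chain(self):
        # 12 ug/ml x 25 ml = 300 ug in 3 g = 10 mg/100 g
        curve = StandardCurve(slope=100.0, intercept=0.0, r_squared=1.0)
        res = quantify_sample(1200.0, curve, extract_volume=25.0, sample_mass=3.0)
        assert res.mg_per_100g == pytest.approx(10.0)

    def test_liquid_sample_mass(self):
        curve = StandardCurve(slope=100.0, intercept=0.0, r_squared=1.0)
        res = quantify_sample(1200.0, curve, extract_volume=25.0, sample_mass=1.0)
        assert res.mg_per_100g == pytest.approx(30.0)

    def test_area_at_intercept_is_zero(self):
        curve = StandardCurve(slope=100.0, intercept=50.0, r_squared=1.0)
        res = quantify_sample(50.0, curve)
        assert res.mg_per_100g == 0.0 and not res.below_range

    def test_below_range_flagged_not_negative(self):
        curve = StandardCurve(slope=100.0, intercept=50.0, r_squared=1.0)
        res = quantify_sample(10.0, curve)
        assert res.below_range and res.mg_per_100g == 0.0

    def test_affine_in_area(self):
        curve = StandardCurve(slope=100.0, intercept=50.0, r_squared=1.0)
        a = quantify_sample(150.0, curve).mg_per_100g
        b = quantify_sample(250.0, curve).mg_per_100g
        assert b == pytest.approx(2 * a)

    def test_fit_then_quantify_noiseless_round_trip(self):
        series = series_on_line(750.0, 12.0)
        curve = fit_standard_curve(series)
        for c in CAPSAICIN_STANDARDS:
            res = quantify_sample(750.0 * c + 12.0, curve, 25.0, 3.0)
            assert res.extract_conc == pytest.approx(c, rel=1e-9)

    def test_parameter_recovery_over_200_replicates(self):
        # median absolute relative error of recovered content stays
        # below the 1% area noise injected; samples are measured in
        # triplicate (the assay protocol) and sit inside the
        # calibration interpolation range, as assayed extracts do
        rng = np.random.default_rng(2024)
        noise = 0.01
        errors = []
        for _ in range(200):
            truth = StandardCurve(
                slope=float(rng.uniform(200, 2000)), intercept=0.0, r_squared=1.0
            )
            areas = gen_peak_areas(truth, CAPSAICIN_STANDARDS, noise, rng)
            series = CalibrationSeries(
                points=[
                    CalibrationPoint(concentration=c, peak_area=a)
                    for c, a in zip(CAPSAICIN_STANDARDS, areas)
                ]
            )
            curve = fit_standard_curve(series)
            true_conc = float(rng.uniform(5.0, 60.0))
            sample_area = float(
                np.mean(gen_peak_areas(truth, [true_conc] * 3, noise, rng))
            )
            got = quantify_sample(sample_area, curve, 25.0, 3.0).extract_conc
            errors.append(abs(got - true_conc) / true_conc)
        assert np.median(errors) < noise


class TestRecovery:
    @pytest.mark.parametrize(
        "measured,baseline,spike,expected",
        [(30.0, 6.0, 24.0, 100.0), (21.288, 0.0, 24.0, 88.7), (30, 10, 24, 83.33)],
    )
    def test_values(self, measured, baseline, spike, expected):
        assert recovery_rate(measured, baseline, spike) == pytest.approx(
            expected, abs=0.005
        )

    def test_zero_spike(self):
        with pytest.raises(ValueError):
            recovery_rate(10, 0, 0)


class TestReplicates:
    @pytest.mark.parametrize(
        "values,mean,sd",
        [([10, 10, 10], 10.0, 0.0), ([1, 2, 3], 2.0, 1.0), ([5.0, 5.4, 5.8], 5.4, 0.4)],
    )
    def test_mean_sd(self, values, mean, sd):
        m, s = replicate_summary(values)
        assert m == pytest.approx(mean) and s == pytest.approx(sd)

    def test_single_value_rejected(self):
        with pytest.raises(ValueError):
            replicate_summary([3.0])


@pytest.fixture(scope="module")
def means():
    return category_means(load_fixtures("table7"))


class TestCategoryMeans:

    @pytest.mark.parametrize(
        "key,n,per_packet",
        [
            (("regular", "mild"), 6, 0.70),
            (("regular", "hot"), 7, 1.51),
            (("regular", "extremely hot"), 3, 5.60),
            (("cup", "hot"), 7, 1.91),
        ],
    )
    def test_per_packet_means(self, means, key, n, per_packet):
        assert means[key].n == n
        assert round_half_up(means[key].per_packet, 2) == per_packet

    def test_component_means_regular_hot(self, means):
        m = means[("regular", "hot")]
        assert round_half_up(m.capsaicin, 2) == 7.66
        assert round_half_up(m.dihydrocapsaicin, 2) == 4.77
        assert round_half_up(m.total, 2) == 12.43

    def test_cup_summary_is_the_hot_category(self, means):
        m = means[("cup", "hot")]
        assert round_half_up(m.total, 2) == 13.18
        assert round_half_up(m.capsaicin, 2) == 8.48
        assert round_half_up(m.dihydrocapsaicin, 2) == 4.71
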