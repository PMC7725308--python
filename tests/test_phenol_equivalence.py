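import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from honeyassay.phenol_equivalence import (
    CurveQCError,
    StandardCurve,
    ZoneMeasurement,
    fit_standard_curve,
    pe_from_measurements,
    pe_limit_of_detection,
    pe_value,
    qc_control_disc,
    read_zones_csv,
    summarize_zone,
    write_zones_csv,
)
from honeyassay.synthetic import (
    DEFAULT_ZONE_CURVE,
    HoneyPotency,
    ZoneCurve,
    simulate_zone_dataset,
)


def well(sample, *diameters, rep="w1", no_zone=False):
    return ZoneMeasurement(
        sample=sample, replicate_id=rep,
        diameters=tuple(float(d) for d in diameters), no_zone=no_zone,
    )


def test_zone_summary_is_mean_of_well_means():
    s = summarize_zone([well("h", 14, 16), well("h", 14, 16, rep="w2")])
    assert s.mean_diameter == pytest.approx(15.0)
    assert s.flags == ()


def test_single_well_accepted_with_warning():
    s = summarize_zone([well("h", 20, 20)])
    assert s.mean_diameter == pytest.approx(20.0)
    assert "single_well" in s.flags


def test_mixed_duplicates_flagged_and_averaged_over_measurable_wells():
    s = summarize_zone([well("h", 12, 14), well("h", no_zone=True, rep="w2")])
    assert s.mean_diameter == pytest.approx(13.0)
    assert "mixed_duplicates" in s.flags


def test_all_no_zone_summary():
    s = summarize_zone([well("h", no_zone=True), well("h", no_zone=True, rep="w2")])
    assert s.mean_diameter is None and "no_zone" in s.flags


def test_mean_then_square_never_square_then_mean():
    """On unequal duplicates the two orders differ; the assay means first."""
    a, b = 14.0, 16.0
    s = summarize_zone([well("h", a), well("h", b, rep="w2")])
    mean_then_square = ((a + b) / 2) ** 2
    square_then_mean = (a**2 + b**2) / 2
    assert mean_then_square != square_then_mean
    assert s.mean_diameter**2 == pytest.approx(mean_then_square)


def test_exact_linear_standards_recovered():
    concs = [2, 3, 4, 5, 6, 7]
    diameters = [math.sqrt(100 + 20 * c) for c in concs]
    curve = fit_standard_curve(concs, diameters)
    assert curve.slope == pytest.approx(20.0)
    assert curve.intercept == pytest.approx(100.0)
    assert curve.r_squared == pytest.approx(1.0)
    assert curve.is_valid


def test_perturbed_fit_matches_closed_form_ols():
    concs = [2.0, 3.0, 4.0, 5.0, 6.0, 7.0]
    d2 = [100 + 20 * c for c in concs]
    d2[2] += 5.0  # one perturbed point
    diameters = [math.sqrt(v) for v in d2]
    curve = fit_standard_curve(concs, diameters)
    # textbook least squares, computed independently
    n = len(concs)
    sx, sy = sum(concs), sum(d2)
    sxx = sum(x * x for x in concs)
    sxy = sum(x * y for x, y in zip(concs, d2))
    slope = (n * sxy - sx * sy) / (n * sxx - sx * sx)
    intercept = (sy - slope * sx) / n
    assert curve.slope == pytest.approx(slope, abs=1e-10)
    assert curve.intercept == pytest.approx(intercept, abs=1e-10)


def test_constant_diameters_fail_curve_qc():
    curve = fit_standard_curve([2, 3, 4, 5], [15, 15, 15, 15])
    assert not curve.is_valid
    with pytest.raises(CurveQCError):
        curve.require_valid()


def test_pe_value_inversion_and_correction():
    curve = StandardCurve(slope=20.0, intercept=100.0, r_squared=1.0, points=())
    # d² = 200 -> c = 5 -> PE = 5 x 4.69
    r = pe_value(math.sqrt(200.0), curve)
    assert r.pe_value == pytest.approx(23.45)
    assert pe_value(None, curve).pe_value == 0.0  # no zone
    below = pe_value(9.0, curve)  # d² = 81 < intercept
    assert below.pe_value == 0.0 and "below_curve_intercept" in below.flags


def test_pe_withheld_when_curve_invalid():
    bad = StandardCurve(slope=20.0, intercept=100.0, r_squared=0.90, points=())
    with pytest.raises(CurveQCError):
        pe_value(15.0, bad)


def test_pe_limit_of_detection():
    curve = StandardCurve(slope=30.0, intercept=60.0, r_squared=1.0, points=())
    assert pe_limit_of_detection(curve) == pytest.approx(0.7 * 4.69)
    degenerate = StandardCurve(slope=30.0, intercept=90.0, r_squared=1.0, points=())
    assert pe_limit_of_detection(degenerate) == 0.0


@pytest.mark.parametrize("diameter,passed", [(21, True), (18, False), (26, True), (19, True)])
def test_trimethoprim_control_disc_qc(diameter, passed):
    assert qc_control_disc(diameter)["passed"] is passed


@given(st.floats(9.0, 40.0), st.floats(9.0, 40.0))
def test_pe_monotone_in_diameter(d1, d2):
    curve = StandardCurve(slope=55.8, intercept=9.4, r_squared=1.0, points=())
    lo, hi = sorted([d1, d2])
    assert pe_value(lo, curve).pe_value <= pe_value(hi, curve).pe_value


def test_noise_free_simulated_zones_recover_generating_curve():
    honeys = [HoneyPotency(potency=1.0, phenol_equivalent=23.45, label="h1")]
    curve_params = ZoneCurve(intercept=9.4, slope=55.8, noise_sd=0.0)
    # rounding suppressed by measuring on the exact diameters
    zones = simulate_zone_dataset(honeys, curve=curve_params, seed=0, noise_scale=0.0)
    # with zero noise the only distortion left is the 1 mm rounding
    curve, results = pe_from_measurements(zones)
    assert curve.r_squared > 0.99
    (pe_h1,) = [r for r in results if r.honey == "h1"]
    assert pe_h1.pe_value == pytest.approx(23.45, abs=1.0)


def test_zones_csv_round_trip(tmp_path):
    zones = simulate_zone_dataset(
        [HoneyPotency(1.0, phenol_equivalent=30.0, label="h1")], seed=5
    )
    path = tmp_path / "zones.csv"
    write_zones_csv(zones, path)
    back = read_zones_csv(path)
    assert set(back) == set(zones)
    for sample in zones:
        orig = sorted(
            (m.replicate_id, m.no_zone, m.diameters) for m in zones[sample]
        )
        rt = sorted((m.replicate_id, m.no_zone, m.diameters) for m in back[sample])
        assert rt == orig
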