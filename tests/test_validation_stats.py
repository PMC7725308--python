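import math
from statistics import fmean

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from honeyassay.plate_model import AssayError
from honeyassay.validation_stats import (
    instrument_loq_check,
    limit_of_detection,
    one_way_anova,
    pearson,
    percent_rsd,
    two_sample_t,
)


def blank_set(mean, sd):
    """Three blanks with exactly the requested sample mean and SD."""
    return [mean - sd, mean, mean + sd]


def test_lod_is_mean_plus_three_sd():
    assert limit_of_detection(blank_set(37.9, 4.95)) == pytest.approx(52.75)
    assert limit_of_detection([40.0, 40.0, 40.0]) == pytest.approx(40.0)
    assert limit_of_detection([30, 40, 50]) == pytest.approx(70.0)
    with pytest.raises(AssayError):
        limit_of_detection([40, 41])


@given(st.floats(-100, 100))
def test_lod_translation_equivariant(c):
    base = [30.0, 40.0, 50.0]
    assert limit_of_detection([v + c for v in base]) == pytest.approx(
        limit_of_detection(base) + c, abs=1e-9
    )


def test_percent_rsd():
    assert percent_rsd([5.0, 5.0, 5.0]) == 0.0
    assert percent_rsd([1.0, 3.0]) == pytest.approx(100 * math.sqrt(2) / 2)
    with pytest.raises(AssayError):
        percent_rsd([-1.0, 1.0])  # zero mean


def textbook_t(a, b):
    na, nb = len(a), len(b)
    va = sum((x - fmean(a)) ** 2 for x in a) / (na - 1)
    vb = sum((x - fmean(b)) ** 2 for x in b) / (nb - 1)
    sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    t = (fmean(a) - fmean(b)) / math.sqrt(sp2 * (1 / na + 1 / nb))
    from scipy.stats import t as tdist

    return t, 2 * tdist.sf(abs(t), na + nb - 2)


def textbook_anova(groups):
    all_vals = [v for g in groups for v in g]
    grand = fmean(all_vals)
    ss_between = sum(len(g) * (fmean(g) - grand) ** 2 for g in groups)
    ss_within = sum((v - fmean(g)) ** 2 for g in groups for v in g)
    df_b = len(groups) - 1
    df_w = len(all_vals) - len(groups)
    f = (ss_between / df_b) / (ss_within / df_w)
    from scipy.stats import f as fdist

    return f, fdist.sf(f, df_b, df_w)


A = [596.0, 601.0, 588.0, 605.0, 592.0]
B = [578.0, 585.0, 590.0, 571.0, 582.0, 588.0]
C = [540.0, 545.0, 552.0, 538.0]


def test_t_test_matches_textbook_formula():
    t, p = two_sample_t(A, B)
    t0, p0 = textbook_t(A, B)
    assert t == pytest.approx(t0, abs=1e-10)
    assert p == pytest.approx(p0, abs=1e-10)


def test_t_test_degenerate_and_limits():
    assert two_sample_t([3.0, 3.0], [3.0, 3.0]) == (0.0, 1.0)
    _, p = two_sample_t([1.0, 2.0, 3.0], [1001.0, 1002.0, 1003.0])
    assert p < 1e-6
    t, p = two_sample_t([5.0, 5.0], [2.0, 2.0])  # zero variance, distinct means
    assert math.isinf(t) and p == 0.0


def test_anova_matches_textbook_formula():
    f, p = one_way_anova(A, B, C)
    f0, p0 = textbook_anova([A, B, C])
    assert f == pytest.approx(f0, abs=1e-10)
    assert p == pytest.approx(p0, abs=1e-10)


def test_two_group_anova_is_t_squared():
    f, pf = one_way_anova(A, B)
    t, pt = two_sample_t(A, B)
    assert f == pytest.approx(t**2, abs=1e-10)
    assert pf == pytest.approx(pt, abs=1e-10)


def test_anova_degenerate():
    assert one_way_anova([2.0, 2.0], [2.0, 2.0], [2.0, 2.0]) == (0.0, 1.0)


def test_pearson_basics_and_textbook_p():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    r, p, r2 = pearson(x, x)
    assert r == pytest.approx(1.0) and r2 == pytest.approx(1.0)
    r, _, _ = pearson(x, [-v for v in x])
    assert r == pytest.approx(-1.0)

    y = [2.0, 1.0, 4.0, 3.0, 6.0]
    r, p, r2 = pearson(x, y)
    # independent computation: r from covariances, p via the t transform
    mx, my = fmean(x), fmean(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r0 = sxy / math.sqrt(sxx * syy)
    t0 = r0 * math.sqrt((len(x) - 2) / (1 - r0**2))
    from scipy.stats import t as tdist

    assert r == pytest.approx(r0, abs=1e-10)
    assert p == pytest.approx(2 * tdist.sf(abs(t0), len(x) - 2), abs=1e-10)
    assert r2 == pytest.approx(r0**2, abs=1e-10)

    with pytest.raises(AssayError):
        pearson(x, [1.0] * 5)


@given(
    st.floats(0.1, 10.0),
    st.floats(-5.0, 5.0),
)
def test_pearson_affine_invariance(scale, shift):
    x = [1.0, 2.0, 4.0, 7.0, 11.0]
    y = [3.0, 1.0, 4.0, 9.0, 8.0]
    r, _, _ = pearson(x, y)
    r_pos, _, _ = pearson(x, [scale * v + shift for v in y])
    r_neg, _, _ = pearson(x, [-scale * v + shift for v in y])
    assert r_pos == pytest.approx(r, abs=1e-9)
    assert r_neg == pytest.approx(-r, abs=1e-9)


def dilution_series(offset=0.0, noise_sd=0.001, seed=0):
    rng = np.random.default_rng(seed)
    series = {}
    for step in range(0, 101, 10):
        true_od = 1.0 * step / 100.0 + (offset if step > 0 else 0.0)
        series[float(step)] = [
            float(true_od + rng.normal(0, noise_sd)) for _ in range(4)
        ]
    return series


def test_loq_noise_free_series_fully_discriminable():
    check = instrument_loq_check(dilution_series(noise_sd=1e-6))
    assert check.all_steps_discriminable
    assert check.r_squared > 0.999
    assert all(abs(b) < 0.1 for b in check.bias_percent.values())


def test_loq_inflated_readings_report_positive_bias_but_stay_linear():
    # light scattering adds a small constant to every culture-containing well
    check = instrument_loq_check(dilution_series(offset=0.05, noise_sd=1e-6))
    assert check.r_squared > 0.99
    mid_bias = [check.bias_percent[s] for s in (10.0, 30.0, 50.0, 70.0, 90.0)]
    assert all(b > 0 for b in mid_bias)
    assert check.all_steps_discriminable


def test_loq_noise_exceeding_step_size_fails_discrimination():
    check = instrument_loq_check(dilution_series(noise_sd=0.5, seed=3))
    assert not check.all_steps_discriminable


def test_loq_missing_step_rejected():
    series = dilution_series()
    del series[50.0]
    with pytest.raises(AssayError, match="missing steps"):
        instrument_loq_check(series)
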