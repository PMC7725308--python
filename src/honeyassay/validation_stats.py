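"""Assay-validation statistics: LOD, %RSD, t-test, ANOVA, Pearson, LOQ check.

Conventions: the sample (n−1) standard deviation is used throughout, and
degenerate inputs (zero variance everywhere with equal means) fail safe with
p = 1.  The limit of detection follows the classic blank-based definition,
mean + 3 SD, applied to full assay runs where sterile distilled water stands
in for honey (water has no detectable antibacterial activity, so the nine
water runs behave as procedural blanks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import fmean, stdev
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .plate_model import AssayError

__all__ = [
    "ValidationReport",
    "limit_of_detection",
    "percent_rsd",
    "two_sample_t",
    "one_way_anova",
    "pearson",
    "instrument_loq_check",
]


def limit_of_detection(blank_values: Sequence[float]) -> float:
    """Blank mean plus three sample standard deviations.

    ``blank_values`` are activity values from running the full scoring
    pipeline with water in place of honey.
    """
    if len(blank_values) < 3:
        raise AssayError(f"need >=3 blank replicates, got {len(blank_values)}")
    return fmean(blank_values) + 3.0 * stdev(blank_values)


def percent_rsd(values: Sequence[float]) -> float:
    """Coefficient of variation: 100 x sample SD / mean."""
    if len(values) < 2:
        raise AssayError("need >=2 values for %RSD")
    mean = fmean(values)
    if mean == 0:
        raise AssayError("%RSD undefined for zero mean")
    return 100.0 * stdev(values) / mean


def _all_identical(*groups: Sequence[float]) -> bool:
    flat = [v for g in groups for v in g]
    return len(set(flat)) == 1


def two_sample_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float]:
    """Student's t-test, two-tailed, pooled (equal) variance.

    Degenerate input — every value identical across both groups — returns
    (0, 1) by convention; zero within-group variance with different means
    returns (±inf, 0).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise AssayError("each group needs >=2 values")
    if _all_identical(group_a, group_b):
        return 0.0, 1.0
    if np.var(group_a, ddof=1) == 0 and np.var(group_b, ddof=1) == 0:
        sign = 1.0 if fmean(group_a) > fmean(group_b) else -1.0
        return sign * math.inf, 0.0
    t, p = stats.ttest_ind(group_a, group_b, equal_var=True)
    return float(t), float(p)


def one_way_anova(*groups: Sequence[float]) -> tuple[float, float]:
    """One-way ANOVA F-test across >=2 groups (each >=2 values)."""
    if len(groups) < 2:
        raise AssayError("ANOVA needs >=2 groups")
    if any(len(g) < 2 for g in groups):
        raise AssayError("each group needs >=2 values")
    if _all_identical(*groups):
        return 0.0, 1.0
    if all(np.var(g, ddof=1) == 0 for g in groups):
        return math.inf, 0.0
    f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def pearson(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson product-moment correlation: (r, two-tailed p, r²)."""
    if len(x) != len(y) or len(x) < 3:
        raise AssayError("pearson needs paired vectors with n >= 3")
    if np.var(x) == 0 or np.var(y) == 0:
        raise AssayError("correlation undefined: zero variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p), float(r) ** 2


@dataclass(frozen=True)
class LoqCheck:
    """Instrumental limit-of-quantitation diagnostic for the plate reader."""

    relative_concentrations: dict[float, float]  # nominal fraction -> measured mean %
    bias_percent: dict[float, float]  # measured minus nominal, percentage points
    discriminable: dict[tuple[float, float], bool]  # adjacent-step separation
    r_squared: float

    @property
    def all_steps_discriminable(self) -> bool:
        return all(self.discriminable.values())


def instrument_loq_check(
    measured_ods: Mapping[float, Sequence[float]],
) -> LoqCheck:
    """Can the reader discriminate 10 % steps in bacterial cell density?

    ``measured_ods`` maps nominal culture fractions (0, 10, …, 100 %) to
    blank-subtracted OD replicates (>=4 per step).  Each step's mean OD is
    expressed relative to the 100 % culture; the bias versus nominal is
    reported, adjacent steps are flagged discriminable when their mean
    separation exceeds the pooled replicate SD, and the linear trend of OD
    on nominal fraction is summarised by r².
    """
    steps = sorted(measured_ods)
    expected = [10.0 * k for k in range(11)]
    missing = [s for s in expected if s not in steps]
    if missing:
        raise AssayError(f"incomplete dilution series; missing steps {missing}")
    if any(len(measured_ods[s]) < 4 for s in steps):
        raise AssayError("each dilution step needs >=4 replicates")

    means = {s: fmean(measured_ods[s]) for s in steps}
    sds = {s: stdev(measured_ods[s]) for s in steps}
    top = means[100.0]
    if top <= 0:
        raise AssayError("100% culture step has non-positive mean OD")
    relative = {s: 100.0 * means[s] / top for s in steps}
    bias = {s: relative[s] - s for s in steps}

    discriminable: dict[tuple[float, float], bool] = {}
    for lo, hi in zip(steps, steps[1:]):
        pooled_sd = math.sqrt((sds[lo] ** 2 + sds[hi] ** 2) / 2.0)
        discriminable[(lo, hi)] = abs(means[hi] - means[lo]) > pooled_sd

    x = [s for s in steps for _ in measured_ods[s]]
    y = [v for s in steps for v in measured_ods[s]]
    fit = stats.linregress(x, y)
    return LoqCheck(
        relative_concentrations=relative,
        bias_percent=bias,
        discriminable=discriminable,
        r_squared=float(fit.rvalue) ** 2,
    )


@dataclass(frozen=True)
class ValidationReport:
    """Bundle of the validation outputs for one study.

    ``lod`` is in activity units; ``measuring_interval`` is (ceil(lod), 768);
    ``repeatability`` maps honey label -> %RSD; ``reproducibility`` maps
    honey label -> two-operator t-test p-value; ``correlations`` maps a pair
    label (e.g. ``"activity_vs_mean_mic"``) -> (r, p, r²).
    """

    lod: float
    measuring_interval: tuple[int, int]
    repeatability: dict[str, float]
    reproducibility: dict[str, float]
    correlations: dict[str, tuple[float, float, float]]
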