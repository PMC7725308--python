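"""Phenol-equivalence (PE) agar-diffusion calculation.

A 25 % w/v honey solution and phenol standards (2–7 % w/v) are placed in
8 mm wells cut into seeded agar; zone-of-inhibition diameters are measured
to the nearest millimetre, at least twice per well.  Zone processing follows
the assay convention exactly: readings are averaged per well, well means are
averaged across duplicate wells, and only then is the mean diameter squared.
A linear standard curve of mean squared diameter on phenol concentration is
fitted by ordinary least squares and is valid only when r² > 0.95.  A
honey's PE value inverts the curve at its squared mean diameter and applies
a fixed ×4.69 correction for the 1-in-4 honey dilution and an assumed honey
density of 1.35 g/mL (the factor is inherited from the originating assay
protocol and is configuration, never recomputed).

Diameters include the 8 mm well itself, so the smallest measurable zone is
9 mm; a honey with no visible zone has PE 0 by definition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .plate_model import AssayError

__all__ = [
    "WELL_DIAMETER_MM",
    "MIN_MEASURABLE_DIAMETER_MM",
    "DEFAULT_CORRECTION_FACTOR",
    "PHENOL_STANDARDS",
    "R_SQUARED_GATE",
    "ZoneMeasurement",
    "ZoneSummary",
    "StandardCurve",
    "PEResult",
    "CurveQCError",
    "summarize_zone",
    "fit_standard_curve",
    "pe_value",
    "pe_limit_of_detection",
    "qc_control_disc",
]

WELL_DIAMETER_MM = 8.0
MIN_MEASURABLE_DIAMETER_MM = 9.0
#: Correction for the 1-in-4 honey dilution and assumed 1.35 g/mL density.
DEFAULT_CORRECTION_FACTOR = 4.69
#: Phenol standard concentrations, % w/v.
PHENOL_STANDARDS: tuple[int, ...] = (2, 3, 4, 5, 6, 7)
R_SQUARED_GATE = 0.95
#: CLSI acceptable zone range (mm, inclusive) for the trimethoprim 5 ug
#: control disc against the assay's control strain; overridable via config.
DEFAULT_CONTROL_DISC_RANGE = (19.0, 26.0)


class CurveQCError(AssayError):
    """Standard-curve r² <= 0.95 (or non-positive slope): PE values withheld."""


@dataclass(frozen=True)
class ZoneMeasurement:
    """Ruler readings (mm, >=2 per well preferred) for one well of one sample."""

    sample: str
    replicate_id: str
    diameters: tuple[float, ...] = ()
    no_zone: bool = False

    def __post_init__(self) -> None:
        if self.no_zone and self.diameters:
            raise AssayError(
                f"{self.sample}/{self.replicate_id}: no_zone excludes diameters"
            )
        if not self.no_zone:
            if not self.diameters:
                raise AssayError(f"{self.sample}/{self.replicate_id}: no readings")
            for d in self.diameters:
                # an 8 mm reading is the bare well: record it as no_zone instead
                if d < MIN_MEASURABLE_DIAMETER_MM:
                    raise AssayError(
                        f"{self.sample}/{self.replicate_id}: diameter {d} mm below the "
                        f"{MIN_MEASURABLE_DIAMETER_MM:g} mm minimum measurable zone; "
                        "use no_zone for a bare well"
                    )


@dataclass(frozen=True)
class ZoneSummary:
    sample: str
    mean_diameter: float | None  # None when every duplicate well shows no zone
    flags: tuple[str, ...] = field(default=())


def summarize_zone(measurements: Iterable[ZoneMeasurement]) -> ZoneSummary:
    """Mean zone diameter for one sample: per-well mean, then across wells.

    Squaring is deferred to the curve fit / PE inversion so the order of
    operations is always mean-then-square.  Mixed duplicates (one well with
    a zone, one without) are flagged and averaged over measurable wells
    only; a single reading or a single well is accepted with a warning flag.
    """
    ms = list(measurements)
    if not ms:
        raise AssayError("no zone measurements supplied")
    sample = ms[0].sample
    if any(m.sample != sample for m in ms):
        raise AssayError("summarize_zone mixes samples")

    flags: list[str] = []
    well_means = []
    for m in ms:
        if m.no_zone:
            continue
        if len(m.diameters) < 2:
            flags.append("single_reading")
        well_means.append(sum(m.diameters) / len(m.diameters))
    if not well_means:
        return ZoneSummary(sample=sample, mean_diameter=None, flags=("no_zone",))
    if any(m.no_zone for m in ms):
        flags.append("mixed_duplicates")
    if len(well_means) < 2:
        flags.append("single_well")
    return ZoneSummary(
        sample=sample,
        mean_diameter=sum(well_means) / len(well_means),
        flags=tuple(dict.fromkeys(flags)),
    )


@dataclass(frozen=True)
class StandardCurve:
    """OLS line of mean squared zone diameter (mm²) on phenol % w/v."""

    slope: float
    intercept: float
    r_squared: float
    points: tuple[tuple[float, float], ...]

    @property
    def is_valid(self) -> bool:
        return self.slope > 0 and self.r_squared > R_SQUARED_GATE

    def require_valid(self) -> None:
        if self.slope <= 0:
            raise CurveQCError(f"non-positive slope {self.slope:g}: degenerate curve")
        if self.r_squared <= R_SQUARED_GATE:
            raise CurveQCError(
                f"standard curve r² {self.r_squared:.4f} <= {R_SQUARED_GATE}"
            )


def fit_standard_curve(
    concentrations: Sequence[float], mean_diameters: Sequence[float]
) -> StandardCurve:
    """Least-squares standard curve from phenol standards.

    ``mean_diameters`` are the per-standard mean zone diameters (mm); they
    are squared here, then regressed on concentration.
    """
    if len(concentrations) != len(mean_diameters):
        raise AssayError("concentrations and diameters differ in length")
    if len(set(concentrations)) < 4:
        raise AssayError("need >=4 distinct phenol concentrations for a standard curve")
    d2 = [d * d for d in mean_diameters]
    if len(set(d2)) == 1:
        # zero response variance: r² undefined, slope 0 -> QC failure downstream
        return StandardCurve(
            slope=0.0,
            intercept=d2[0],
            r_squared=0.0,
            points=tuple(zip(map(float, concentrations), d2)),
        )
    fit = stats.linregress(concentrations, d2)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        points=tuple(zip(map(float, concentrations), d2)),
    )


@dataclass(frozen=True)
class PEResult:
    honey: str
    mean_diameter: float | None
    pe_value: float
    correction_factor: float = DEFAULT_CORRECTION_FACTOR
    flags: tuple[str, ...] = field(default=())


def pe_value(
    mean_diameter: float | None,
    curve: StandardCurve,
    correction_factor: float = DEFAULT_CORRECTION_FACTOR,
    honey: str = "",
) -> PEResult:
    """Phenol equivalence of a 25 % w/v honey solution.

    Inverts the standard curve at the squared mean diameter,
    ``c = (d² − intercept) / slope``, clamps a negative phenol concentration
    to 0 and multiplies by the correction factor.  A honey with no zone has
    PE 0.
    """
    curve.require_valid()
    if mean_diameter is None:
        return PEResult(honey=honey, mean_diameter=None, pe_value=0.0,
                        correction_factor=correction_factor, flags=("no_zone",))
    c = (mean_diameter**2 - curve.intercept) / curve.slope
    flags: tuple[str, ...] = ()
    if c < 0:
        c, flags = 0.0, ("below_curve_intercept",)
    return PEResult(
        honey=honey,
        mean_diameter=float(mean_diameter),
        pe_value=c * correction_factor,
        correction_factor=correction_factor,
        flags=flags,
    )


def pe_limit_of_detection(
    curve: StandardCurve,
    min_measurable_diameter: float = MIN_MEASURABLE_DIAMETER_MM,
    correction_factor: float = DEFAULT_CORRECTION_FACTOR,
) -> float:
    """PE of the smallest theoretically measurable zone (9 mm, 25 % honey)."""
    return pe_value(min_measurable_diameter, curve, correction_factor).pe_value


def qc_control_disc(
    zone_diameter_mm: float,
    acceptable_range: tuple[float, float] = DEFAULT_CONTROL_DISC_RANGE,
) -> dict:
    """Antibiotic control disc QC: zone inside the inclusive acceptable range."""
    lo, hi = acceptable_range
    return {
        "diameter_mm": float(zone_diameter_mm),
        "range_mm": (float(lo), float(hi)),
        "passed": lo <= zone_diameter_mm <= hi,
    }


def pe_from_measurements(
    zones: Mapping[str, Sequence[ZoneMeasurement]],
    phenol_samples: Mapping[str, float] | None = None,
    correction_factor: float = DEFAULT_CORRECTION_FACTOR,
) -> tuple[StandardCurve, list[PEResult]]:
    """End-to-end PE: summarize zones, fit the curve, convert honey samples.

    ``phenol_samples`` maps sample labels to phenol concentrations; labels of
    the form ``phenol_<c>`` are recognised by default.  Every other sample is
    treated as a honey and converted.
    """
    summaries = {s: summarize_zone(ms) for s, ms in zones.items()}
    if phenol_samples is None:
        phenol_samples = {
            s: float(s.split("_", 1)[1]) for s in zones if s.startswith("phenol_")
        }
    concs, diams = [], []
    for s, c in sorted(phenol_samples.items(), key=lambda kv: kv[1]):
        summ = summaries[s]
        if summ.mean_diameter is None:
            raise AssayError(f"phenol standard {s} produced no zone")
        concs.append(c)
        diams.append(summ.mean_diameter)
    curve = fit_standard_curve(concs, diams)
    curve.require_valid()
    results = [
        pe_value(summaries[s].mean_diameter, curve, correction_factor, honey=s)
        for s in zones
        if s not in phenol_samples and not s.startswith(("water", "trimethoprim"))
    ]
    if math.isnan(curve.r_squared):  # pragma: no cover - defensive
        raise CurveQCError("r² undefined")
    return curve, results


_ZONE_COLUMNS = ["sample", "replicate", "measurement_mm"]


def read_zones_csv(path: str | Path) -> dict[str, list[ZoneMeasurement]]:
    """Read zone measurements: columns ``sample,replicate,measurement_mm``.

    Repeated (sample, replicate) rows are the >=2 ruler readings of one
    well; the token ``none`` marks a well with no zone of inhibition.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _ZONE_COLUMNS if c not in df.columns]
    if missing:
        raise AssayError(f"{path}: missing columns {missing}")
    grouped: dict[tuple[str, str], list[str]] = {}
    for row in df.itertuples(index=False):
        grouped.setdefault((str(row.sample), str(row.replicate)), []).append(
            str(row.measurement_mm).strip().lower()
        )
    zones: dict[str, list[ZoneMeasurement]] = {}
    for (sample, rep), tokens in grouped.items():
        if all(t == "none" for t in tokens):
            zm = ZoneMeasurement(sample=sample, replicate_id=rep, no_zone=True)
        else:
            zm = ZoneMeasurement(
                sample=sample,
                replicate_id=rep,
                diameters=tuple(float(t) for t in tokens if t != "none"),
            )
        zones.setdefault(sample, []).append(zm)
    return zones


def write_zones_csv(
    zones: Mapping[str, Sequence[ZoneMeasurement]], path: str | Path
) -> None:
    rows = []
    for sample, wells in zones.items():
        for well in wells:
            if well.no_zone:
                rows.append(
                    {"sample": sample, "replicate": well.replicate_id,
                     "measurement_mm": "none"}
                )
            else:
                rows.extend(
                    {"sample": sample, "replicate": well.replicate_id,
                     "measurement_mm": d}
                    for d in well.diameters
                )
    pd.DataFrame(rows, columns=_ZONE_COLUMNS).to_csv(path, index=False)
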