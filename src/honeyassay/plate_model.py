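"""Microplate OD600 data model, CSV I/O and relative-growth computation.

The assay reads every well of a 96-well plate at 600 nm immediately after
inoculation (time zero) and again at the end of a 20 h (± 2 h) incubation.
The time-zero reading is the well's own blank: subtracting it from the
end-of-incubation reading gives a *net optical density* that reflects
bacterial growth only, independent of the colour of the honey solution.

Honey is tested at six concentrations (5–30 % w/v in 5 % steps) against four
reference organisms, with one untreated positive growth control per organism
defining 100 % growth.  Growth in each honey well is expressed as a
percentage of that control; a clamped copy (restricted to [0, 100]) feeds
the activity-unit scoring while the raw value is retained for descriptive
summaries, which can legitimately exceed 100 % (low-dose growth
stimulation) or fall below 0 % (blank noise).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ORGANISMS",
    "HONEY_CONCENTRATIONS",
    "Role",
    "PlateReading",
    "RelativeGrowthGrid",
    "AssayError",
    "InvalidReadingError",
    "GrowthControlError",
    "LayoutError",
    "SchemaError",
    "net_od",
    "relative_growth",
    "clamp_percent",
    "grid_from_readings",
    "read_plate_csv",
    "write_plate_csv",
]

#: The four broth-microdilution quality-control reference organisms.
ORGANISMS: tuple[str, ...] = (
    "S. aureus",
    "E. faecalis",
    "E. coli",
    "P. aeruginosa",
)

#: Final in-well honey concentrations, % w/v.
HONEY_CONCENTRATIONS: tuple[int, ...] = (5, 10, 15, 20, 25, 30)

#: Nominal incubation and tolerance, hours.  Readings outside the tolerance
#: are flagged in :class:`PlateReading.flags`, never rejected.
NOMINAL_INCUBATION_H = 20.0
INCUBATION_TOLERANCE_H = 2.0


class AssayError(ValueError):
    """Base class for assay data errors."""


class InvalidReadingError(AssayError):
    """An absorbance is missing, non-finite or negative."""


class GrowthControlError(AssayError):
    """The positive growth control failed (net OD <= 0): occasion invalid."""


class LayoutError(AssayError):
    """The plate layout is incomplete or inconsistent."""


class SchemaError(AssayError):
    """A CSV field has a value outside the assay vocabulary."""


class Role(str, Enum):
    HONEY = "honey"
    POSITIVE_CONTROL = "positive_control"
    ANTIBIOTIC_CONTROL = "antibiotic_control"
    BLANK = "blank"


@dataclass(frozen=True)
class PlateReading:
    """One well's paired absorbances plus its layout assignment.

    Parameters
    ----------
    well_id
        Plate coordinate (``A1`` … ``H12``); case-insensitive, stored upper.
    organism
        One of :data:`ORGANISMS`, or ``None`` for uninoculated blanks.
    honey_concentration
        % w/v from :data:`HONEY_CONCENTRATIONS`; ``None`` for control wells.
    role
        Well role; honey wells require both organism and concentration.
    od_t0, od_end
        Absorbance at 600 nm at time zero and end of incubation.
    incubation_h
        Actual incubation time; values outside 20 ± 2 h add an
        ``incubation_out_of_tolerance`` flag.
    """

    well_id: str
    organism: str | None
    honey_concentration: float | None
    role: Role
    od_t0: float
    od_end: float
    incubation_h: float | None = None
    flags: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "well_id", str(self.well_id).upper())
        for name in ("od_t0", "od_end"):
            v = getattr(self, name)
            if v is None or not math.isfinite(v):
                raise InvalidReadingError(
                    f"well {self.well_id}: {name}={v!r} is not a finite number"
                )
            if v < 0:
                raise InvalidReadingError(
                    f"well {self.well_id}: {name}={v} is negative"
                )
        if self.role is Role.HONEY:
            if self.organism is None or self.honey_concentration is None:
                raise SchemaError(
                    f"well {self.well_id}: honey wells need organism and concentration"
                )
            if self.honey_concentration not in HONEY_CONCENTRATIONS:
                raise SchemaError(
                    f"well {self.well_id}: concentration "
                    f"{self.honey_concentration} not in {HONEY_CONCENTRATIONS}"
                )
        if (
            self.incubation_h is not None
            and abs(self.incubation_h - NOMINAL_INCUBATION_H) > INCUBATION_TOLERANCE_H
            and "incubation_out_of_tolerance" not in self.flags
        ):
            object.__setattr__(
                self, "flags", self.flags + ("incubation_out_of_tolerance",)
            )


def net_od(reading: PlateReading) -> float:
    """End-of-incubation absorbance minus the same well's time-zero blank.

    May be negative (blank noise); clamping happens only downstream, on the
    relative-growth percentage.
    """
    return reading.od_end - reading.od_t0


def relative_growth(net_honey: float, net_control: float) -> float:
    """Growth in a honey well as a percentage of the positive control.

    Returns the *unclamped* value; use :func:`clamp_percent` before scoring.

    Raises
    ------
    GrowthControlError
        If ``net_control <= 0`` — a positive control that failed to grow
        invalidates the whole test occasion.
    """
    if not math.isfinite(net_control) or net_control <= 0:
        raise GrowthControlError(
            f"positive control net OD {net_control} <= 0: occasion invalid"
        )
    return 100.0 * net_honey / net_control


def clamp_percent(value: float) -> float:
    """Restrict a relative-growth percentage to [0, 100]."""
    return min(100.0, max(0.0, value))


@dataclass(frozen=True)
class RelativeGrowthGrid:
    """The 4 x 6 grid of relative-growth percentages for one test occasion.

    ``values`` holds unclamped percentages keyed by ``(organism,
    concentration)``; ``clamped_values`` restricts each entry to [0, 100].
    """

    values: Mapping[tuple[str, float], float]
    occasion_id: str = ""

    @property
    def clamped_values(self) -> dict[tuple[str, float], float]:
        return {k: clamp_percent(v) for k, v in self.values.items()}

    def missing_conditions(
        self,
        organisms: Iterable[str] = ORGANISMS,
        concentrations: Iterable[float] = HONEY_CONCENTRATIONS,
    ) -> list[tuple[str, float]]:
        return [
            (org, float(c))
            for org in organisms
            for c in concentrations
            if (org, float(c)) not in self.values
        ]

    @property
    def is_complete(self) -> bool:
        return len(self.values) == 24 and not self.missing_conditions()


def grid_from_readings(
    readings: Iterable[PlateReading], occasion_id: str = ""
) -> RelativeGrowthGrid:
    """Compute the relative-growth grid from one plate occasion's readings.

    One positive control per organism divides all six of that organism's
    honey concentrations.  Antibiotic-control and blank wells are ignored.
    """
    readings = list(readings)
    controls: dict[str, float] = {}
    for r in readings:
        if r.role is Role.POSITIVE_CONTROL:
            if r.organism is None:
                raise LayoutError(f"well {r.well_id}: positive control without organism")
            if r.organism in controls:
                raise LayoutError(f"duplicate positive control for {r.organism}")
            controls[r.organism] = net_od(r)

    values: dict[tuple[str, float], float] = {}
    for r in readings:
        if r.role is not Role.HONEY:
            continue
        assert r.organism is not None and r.honey_concentration is not None
        if r.organism not in controls:
            raise LayoutError(f"no positive control for {r.organism}")
        key = (r.organism, float(r.honey_concentration))
        if key in values:
            raise LayoutError(f"duplicate honey condition {key}")
        values[key] = relative_growth(net_od(r), controls[r.organism])
    return RelativeGrowthGrid(values=values, occasion_id=occasion_id)


_CSV_COLUMNS = ["well", "organism", "conc_pct", "role", "od_t0", "od_end"]


def read_plate_csv(path: str | Path, layout_config: Mapping[str, Mapping] | None = None):
    """Read a long-format plate CSV into validated :class:`PlateReading`\\ s.

    Expected columns: ``well,organism,conc_pct,role,od_t0,od_end`` with the
    role vocabulary ``{honey, positive_control, antibiotic_control, blank}``.
    ``layout_config`` may map well coordinates to ``organism`` /
    ``conc_pct`` / ``role`` assignments, overriding blank fields in the file.

    Raises
    ------
    SchemaError
        Unknown role or off-grid concentration.
    LayoutError
        Duplicate wells, or a missing positive control for an organism that
        has honey wells.
    """
    df = pd.read_csv(path, dtype={"well": str, "organism": str, "role": str})
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")

    wells = df["well"].str.upper()
    dupes = wells[wells.duplicated()].tolist()
    if dupes:
        raise LayoutError(f"{path}: duplicate well ids {sorted(set(dupes))}")

    readings: list[PlateReading] = []
    for row in df.itertuples(index=False):
        well = str(row.well).upper()
        organism = None if pd.isna(row.organism) else str(row.organism)
        conc = None if pd.isna(row.conc_pct) else float(row.conc_pct)
        role_token = None if pd.isna(row.role) else str(row.role)
        if layout_config and well in {k.upper() for k in layout_config}:
            cfg = {k.upper(): v for k, v in layout_config.items()}[well]
            organism = cfg.get("organism", organism)
            conc = cfg.get("conc_pct", conc)
            role_token = cfg.get("role", role_token)
        try:
            role = Role(role_token)
        except ValueError:
            raise SchemaError(f"{path}: well {well}: unknown role {role_token!r}") from None
        readings.append(
            PlateReading(
                well_id=well,
                organism=organism,
                honey_concentration=conc,
                role=role,
                od_t0=float(row.od_t0),
                od_end=float(row.od_end),
            )
        )

    organisms_present = {r.organism for r in readings if r.role is Role.HONEY}
    controls = {r.organism for r in readings if r.role is Role.POSITIVE_CONTROL}
    without_control = sorted(organisms_present - controls)
    if without_control:
        raise LayoutError(f"{path}: no positive control for {without_control}")
    return readings


def write_plate_csv(readings: Iterable[PlateReading], path: str | Path) -> None:
    """Write readings back to the long-format plate CSV."""
    rows = [
        {
            "well": r.well_id,
            "organism": r.organism,
            "conc_pct": r.honey_concentration,
            "role": r.role.value,
            "od_t0": r.od_t0,
            "od_end": r.od_end,
        }
        for r in readings
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
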