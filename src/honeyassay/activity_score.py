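"""Antibacterial activity value: bin relative growth, sum over 24 conditions.

The assay's endpoint is a single integer per honey.  Each of the 24
conditions (4 organisms x 6 concentrations) is assigned *activity units*
from its clamped relative-growth percentage — more growth inhibition earns
more units — and the 24 unit values are summed:

    relative growth  <10%            -> 32 units
    >=10% to <30%                    -> 16
    >=30% to <50%                    ->  8
    >=50% to <70%                    ->  4
    >=70% to <90%                    ->  2
    >=90%                            ->  1

The sum therefore ranges from 24 (no inhibition anywhere) to 768 (complete
inhibition everywhere).  The usable range is bounded below by the limit of
detection (53 units under the validation conditions), giving the measuring
interval 53–768.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from statistics import fmean
from typing import Sequence

from .plate_model import (
    HONEY_CONCENTRATIONS,
    ORGANISMS,
    AssayError,
    RelativeGrowthGrid,
)

__all__ = [
    "ActivityUnitTable",
    "DEFAULT_UNIT_TABLE",
    "HoneyActivityResult",
    "ReplicateSummary",
    "MissingConditionError",
    "assign_units",
    "activity_value",
    "aggregate_replicates",
    "measuring_interval",
    "THEORETICAL_MIN",
    "THEORETICAL_MAX",
]

THEORETICAL_MIN = 24
THEORETICAL_MAX = 768


class MissingConditionError(AssayError):
    """The 4x6 grid is incomplete; message lists the absent conditions."""


@dataclass(frozen=True)
class ActivityUnitTable:
    """Ordered half-open bins ``[lower, upper) -> units`` partitioning [0, 100].

    The top bin is closed on the right so that 100 % growth maps to 1 unit.
    """

    bins: tuple[tuple[float, float, int], ...] = (
        (0.0, 10.0, 32),
        (10.0, 30.0, 16),
        (30.0, 50.0, 8),
        (50.0, 70.0, 4),
        (70.0, 90.0, 2),
        (90.0, 100.0, 1),
    )

    def __post_init__(self) -> None:
        lo = 0.0
        prev_units = math.inf
        for lower, upper, units in self.bins:
            if lower != lo or upper <= lower:
                raise ValueError("bins must partition [0, 100] without gaps or overlaps")
            if units >= prev_units:
                raise ValueError("units must strictly decrease as growth increases")
            lo, prev_units = upper, units
        if lo != 100.0:
            raise ValueError("bins must end at 100")


DEFAULT_UNIT_TABLE = ActivityUnitTable()


def assign_units(
    relative_growth_clamped: float, table: ActivityUnitTable = DEFAULT_UNIT_TABLE
) -> int:
    """Activity units for one clamped relative-growth percentage.

    Bins are half-open ``[lower, upper)``; the boundary value belongs to the
    higher bin (10 % -> 16 units, not 32).  Exactly 100 % falls in the top
    (>=90 %) bin.  Values are compared at full precision, never rounded.
    """
    if not math.isfinite(relative_growth_clamped) or not (
        0.0 <= relative_growth_clamped <= 100.0
    ):
        raise ValueError(
            f"relative growth {relative_growth_clamped} outside [0, 100]; clamp first"
        )
    for lower, upper, units in table.bins:
        if lower <= relative_growth_clamped < upper:
            return units
    return table.bins[-1][2]  # exactly 100.0


@dataclass(frozen=True)
class HoneyActivityResult:
    """Scored occasion: the grid, per-condition units and their sum."""

    grid: RelativeGrowthGrid
    units: dict[tuple[str, float], int]
    activity_value: int
    occasion_id: str = ""


def activity_value(
    grid: RelativeGrowthGrid, table: ActivityUnitTable = DEFAULT_UNIT_TABLE
) -> HoneyActivityResult:
    """Assign units to all 24 conditions and sum them.

    Raises
    ------
    MissingConditionError
        If any of the 24 (organism, concentration) conditions is absent;
        the message lists the missing pairs.
    """
    missing = grid.missing_conditions(ORGANISMS, HONEY_CONCENTRATIONS)
    if missing:
        raise MissingConditionError(f"incomplete grid; missing conditions: {missing}")
    units = {k: assign_units(v, table) for k, v in grid.clamped_values.items()}
    total = sum(units.values())
    return HoneyActivityResult(
        grid=grid, units=units, activity_value=total, occasion_id=grid.occasion_id
    )


def _round_half_up(x: float, step: int) -> int:
    return int(math.floor(x / step + 0.5)) * step


@dataclass(frozen=True)
class ReplicateSummary:
    """Mean activity value over test occasions, plus a reporting-scale copy.

    The unrounded mean is always retained; ``reporting_value`` rounds
    half-up to the nearest ``reporting_step`` (50 by default, 100
    configurable) for consumer-facing labels.
    """

    per_occasion: tuple[int, ...]
    mean_value: float
    reporting_value: int
    reporting_step: int = 50
    flags: tuple[str, ...] = field(default=())


def aggregate_replicates(
    results: Sequence[HoneyActivityResult | int], reporting_step: int = 50
) -> ReplicateSummary:
    """Mean activity value across >=2 test occasions of the same honey.

    A single occasion is still summarised but flagged
    ``insufficient_replication`` — the assay protocol requires at least two
    independent occasions.
    """
    values = tuple(
        r.activity_value if isinstance(r, HoneyActivityResult) else int(r)
        for r in results
    )
    if not values:
        raise ValueError("no occasions supplied")
    flags: tuple[str, ...] = ()
    if len(values) < 2:
        flags = ("insufficient_replication",)
    mean = fmean(values)
    return ReplicateSummary(
        per_occasion=values,
        mean_value=mean,
        reporting_value=_round_half_up(mean, reporting_step),
        reporting_step=reporting_step,
        flags=flags,
    )


def measuring_interval(lod: float) -> tuple[int, int]:
    """Usable range of the assay: (limit of detection rounded up, 768).

    The theoretical floor of 24 is a property of the scoring, not of the
    measuring interval; report it separately via :data:`THEORETICAL_MIN`.
    """
    return (math.ceil(lod), THEORETICAL_MAX)
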