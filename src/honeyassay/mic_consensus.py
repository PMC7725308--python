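"""Broth-microdilution MIC reading, off-scale ascription and replicate consensus.

MICs are read visually on a 2 % w/v honey grid from 2 % to 30 %.  Results
below the lowest tested concentration are ascribed 1 % and results above the
highest are ascribed 32 % so that arithmetic on replicate sets is possible.
Replicates from separate occasions are combined by fixed rules:

* two identical values  -> that value (``mode_two``);
* two values differing by <=4 % honey -> their arithmetic mean (``mean_le4``);
* two values differing by >=6 % honey -> a third replicate is required, then
  the mode of the three (``third_mode``), or the mean if all three differ
  (``all_differ_mean``).

A difference of exactly 5 can only arise between an ascribed 1 and an
on-grid 6; it is treated like >=6 (request a third replicate), the
conservative reading.  The honey's overall susceptibility summary is the
arithmetic mean of the four organisms' final MICs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from statistics import fmean
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .plate_model import ORGANISMS, AssayError

__all__ = [
    "MIC_GRID",
    "OFF_SCALE_LOW",
    "OFF_SCALE_HIGH",
    "ASCRIBED_LOW",
    "ASCRIBED_HIGH",
    "ConsensusRule",
    "MicReading",
    "MicReplicateSet",
    "NeedsThirdReplicateError",
    "IncompletePanelError",
    "ascribe_off_scale",
    "consensus_mic",
    "mean_mic",
    "mic_from_net_ods",
    "read_mic_csv",
    "write_mic_csv",
]

#: Tested honey concentrations, % w/v.
MIC_GRID: tuple[int, ...] = tuple(range(2, 31, 2))

OFF_SCALE_LOW = "<2"
OFF_SCALE_HIGH = ">30"
ASCRIBED_LOW = 1.0
ASCRIBED_HIGH = 32.0

#: Default net-OD threshold below which a well is called "no growth" when
#: deriving a visual-style MIC from simulated optical densities.
NO_GROWTH_OD_THRESHOLD = 0.05


class NeedsThirdReplicateError(AssayError):
    """Two replicates differ by >=5 % honey: a third occasion is required."""


class IncompletePanelError(AssayError):
    """Mean MIC requires a final MIC for all four organisms."""


class ConsensusRule(str, Enum):
    MODE_TWO = "mode_two"
    MEAN_LE4 = "mean_le4"
    THIRD_MODE = "third_mode"
    ALL_DIFFER_MEAN = "all_differ_mean"


@dataclass(frozen=True)
class MicReading:
    """One visually read MIC for one honey x organism x occasion."""

    organism: str
    occasion_id: str
    mic: float | str  # on-grid value, OFF_SCALE_LOW or OFF_SCALE_HIGH

    def __post_init__(self) -> None:
        m = self.mic
        if isinstance(m, str):
            if m not in (OFF_SCALE_LOW, OFF_SCALE_HIGH):
                raise AssayError(f"unknown MIC token {m!r}")
        elif m not in MIC_GRID:
            raise AssayError(f"MIC {m} not on the 2% grid {MIC_GRID}")


def ascribe_off_scale(reading: MicReading | float | str) -> float:
    """Numeric copy of a MIC: ``<2`` -> 1, ``>30`` -> 32, on-grid unchanged."""
    mic = reading.mic if isinstance(reading, MicReading) else reading
    if mic == OFF_SCALE_LOW:
        return ASCRIBED_LOW
    if mic == OFF_SCALE_HIGH:
        return ASCRIBED_HIGH
    return float(mic)


def consensus_mic(values: Sequence[float]) -> tuple[float, ConsensusRule]:
    """Final MIC from 2 (or, after a repeat, 3) ascribed replicate values.

    Raises
    ------
    NeedsThirdReplicateError
        When exactly two values differ by more than 4 % honey — the assay
        must be repeated; the pair is never silently averaged.
    """
    vals = [float(v) for v in values]
    if len(vals) == 2:
        a, b = vals
        if a == b:
            return a, ConsensusRule.MODE_TWO
        if abs(a - b) <= 4.0:
            return fmean(vals), ConsensusRule.MEAN_LE4
        raise NeedsThirdReplicateError(
            f"replicates {sorted(vals)} differ by {abs(a - b):g}% honey; "
            "a third occasion is required"
        )
    if len(vals) == 3:
        counts = Counter(vals)
        (top, n), *_ = counts.most_common(1)
        if n >= 2:
            return top, ConsensusRule.THIRD_MODE
        return fmean(vals), ConsensusRule.ALL_DIFFER_MEAN
    raise AssayError(f"consensus needs 2 or 3 replicate values, got {len(vals)}")


@dataclass(frozen=True)
class MicReplicateSet:
    """Replicate MIC readings for one honey x organism and their consensus."""

    readings: tuple[MicReading, ...]
    ascribed_values: tuple[float, ...]
    final_mic: float
    rule_applied: ConsensusRule

    @classmethod
    def from_readings(cls, readings: Iterable[MicReading]) -> "MicReplicateSet":
        readings = tuple(readings)
        ascribed = tuple(ascribe_off_scale(r) for r in readings)
        final, rule = consensus_mic(ascribed)
        return cls(readings, ascribed, final, rule)


def mean_mic(final_mics: Mapping[str, float]) -> float:
    """Arithmetic mean of the four organism-level final MICs, full precision."""
    missing = [org for org in ORGANISMS if org not in final_mics]
    if missing:
        raise IncompletePanelError(f"missing organisms: {missing}")
    return fmean(final_mics[org] for org in ORGANISMS)


def mic_from_net_ods(
    net_ods: Mapping[float, float], threshold: float = NO_GROWTH_OD_THRESHOLD
) -> float | str:
    """Visual-style MIC from per-concentration net ODs (for simulated plates).

    The MIC is the lowest concentration from which growth stays suppressed
    (net OD below ``threshold``) at all higher concentrations.  Suppression
    at the lowest tested concentration is reported off-scale low — the true
    MIC could lie below the grid — and growth at the highest concentration
    is off-scale high.
    """
    concs = sorted(net_ods)
    inhibited = {c: net_ods[c] < threshold for c in concs}
    mic = None
    for c in reversed(concs):
        if inhibited[c]:
            mic = c
        else:
            break
    if mic is None:
        return OFF_SCALE_HIGH
    if mic == concs[0]:
        return OFF_SCALE_LOW
    return float(mic)


_MIC_COLUMNS = ["honey", "organism", "occasion", "mic"]


def read_mic_csv(path: str | Path) -> dict[tuple[str, str], list[MicReading]]:
    """Read MIC readings keyed by (honey, organism).

    Columns ``honey,organism,occasion,mic`` with tokens ``<2`` / ``>30`` for
    off-scale results.
    """
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _MIC_COLUMNS if c not in df.columns]
    if missing:
        raise AssayError(f"{path}: missing columns {missing}")
    out: dict[tuple[str, str], list[MicReading]] = {}
    for row in df.itertuples(index=False):
        token = str(row.mic).strip()
        mic: float | str = token if token in (OFF_SCALE_LOW, OFF_SCALE_HIGH) else float(token)
        if isinstance(mic, float) and mic.is_integer():
            mic = int(mic)
        out.setdefault((str(row.honey), str(row.organism)), []).append(
            MicReading(organism=str(row.organism), occasion_id=str(row.occasion), mic=mic)
        )
    return out


def write_mic_csv(
    readings: Mapping[tuple[str, str], Sequence[MicReading]], path: str | Path
) -> None:
    rows = [
        {"honey": honey, "organism": org, "occasion": r.occasion_id, "mic": r.mic}
        for (honey, org), reps in readings.items()
        for r in reps
    ]
    pd.DataFrame(rows, columns=_MIC_COLUMNS).to_csv(path, index=False)
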