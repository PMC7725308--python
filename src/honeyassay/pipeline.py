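"""Convenience pipeline: from raw readings (real or simulated) to study tables.

Thin glue over the scoring, MIC-consensus and phenol-equivalence modules so
the CLI, the tests and whole-study analyses share one code path.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import pandas as pd

from . import mic_consensus as mc
from .activity_score import (
    ActivityUnitTable,
    DEFAULT_UNIT_TABLE,
    HoneyActivityResult,
    ReplicateSummary,
    activity_value,
    aggregate_replicates,
)
from .mic_consensus import MicReading, NeedsThirdReplicateError
from .phenol_equivalence import PEResult, StandardCurve, pe_from_measurements
from .plate_model import PlateReading, grid_from_readings
from .synthetic import PanelBundle
from .validation_stats import pearson

__all__ = [
    "score_plate",
    "score_occasions",
    "resolve_mic",
    "panel_results",
    "panel_correlations",
]


def score_plate(
    readings: Iterable[PlateReading],
    table: ActivityUnitTable = DEFAULT_UNIT_TABLE,
    occasion_id: str = "",
) -> HoneyActivityResult:
    """Relative-growth grid and activity value for one plate occasion."""
    return activity_value(grid_from_readings(readings, occasion_id), table)


def score_occasions(
    occasions: Sequence[Iterable[PlateReading]],
    table: ActivityUnitTable = DEFAULT_UNIT_TABLE,
    reporting_step: int = 50,
) -> ReplicateSummary:
    """Score each occasion's plate and aggregate into the final value."""
    results = [
        score_plate(readings, table, occasion_id=f"occ{k + 1}")
        for k, readings in enumerate(occasions)
    ]
    return aggregate_replicates(results, reporting_step=reporting_step)


def resolve_mic(occasions: Sequence[MicReading]) -> tuple[float, mc.ConsensusRule]:
    """Consensus MIC for one organism from sequential occasions.

    The first two occasions are read; a third (when available) is consumed
    only if the two differ by more than 4 % honey, mirroring the repeat-assay
    protocol.
    """
    ascribed = [mc.ascribe_off_scale(r) for r in occasions]
    if len(ascribed) < 2:
        raise mc.AssayError("need >=2 MIC occasions")
    try:
        return mc.consensus_mic(ascribed[:2])
    except NeedsThirdReplicateError:
        if len(ascribed) < 3:
            raise
        return mc.consensus_mic(ascribed[:3])


def _honey_mean_mic(occasions: Sequence[Sequence[MicReading]]) -> float:
    by_org: dict[str, list[MicReading]] = {}
    for occ in occasions:
        for r in occ:
            by_org.setdefault(r.organism, []).append(r)
    finals = {org: resolve_mic(reps)[0] for org, reps in by_org.items()}
    return mc.mean_mic(finals)


def panel_results(bundle: PanelBundle) -> tuple[pd.DataFrame, StandardCurve]:
    """Per-honey study table for a simulated panel.

    Columns: honey, true_potency, activity_value (mean over occasions),
    reporting_value, mean_mic, pe_value.
    """
    curve, pe_results = pe_from_measurements(bundle.zones)
    pe_by_honey: dict[str, PEResult] = {r.honey: r for r in pe_results}
    rows = []
    for honey in bundle.honeys:
        summary = score_occasions(bundle.plates[honey.label])
        rows.append(
            {
                "honey": honey.label,
                "true_potency": honey.potency,
                "activity_value": summary.mean_value,
                "reporting_value": summary.reporting_value,
                "mean_mic": _honey_mean_mic(bundle.mic_occasions[honey.label]),
                "pe_value": pe_by_honey[honey.label].pe_value,
            }
        )
    return pd.DataFrame(rows), curve


def panel_correlations(results: pd.DataFrame) -> dict[str, tuple[float, float, float]]:
    """Pairwise Pearson (r, p, r²) among activity value, PE and mean MIC."""
    pairs = {
        "activity_vs_mean_mic": ("activity_value", "mean_mic"),
        "activity_vs_pe": ("activity_value", "pe_value"),
        "pe_vs_mean_mic": ("pe_value", "mean_mic"),
    }
    return {
        name: pearson(results[a].to_numpy(), results[b].to_numpy())
        for name, (a, b) in pairs.items()
    }
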