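"""Seedable generator of microplate OD, MIC and agar-diffusion datasets.

No raw plate data are deposited for this assay, so the package ships a
simulator that reproduces the *statistical shape* of the study: four
organisms with distinct susceptibilities, six honey concentrations,
low-concentration growth stimulation (hormesis), plate-reader noise, a 2 %
MIC grid with off-scale results, and inhibition zones consistent with a
linear squared-diameter phenol standard curve.

The expected relative growth of an organism at honey concentration ``c``
(% w/v) for a honey of latent potency ``p`` is

    g(c) = (1 + stim_amp * exp(-c / stim_decay)) / (1 + (p * c / ic50)**hill)

a Hill-type inhibition curve modulated by an exponentially decaying
stimulation term.  This functional form is this package's own minimal model
of the observed dose-response shape, not a mechanistic claim.  The
positive-control net OD distributions are the study's printed per-organism
means and SDs; ic50 / hill / stimulation defaults are calibrated once so
that simulated MIC summaries land near the printed per-organism MIC means
(S. aureus ~5, P. aeruginosa ~10, E. coli ~12, E. faecalis ~17 % w/v) and so
that P. aeruginosa and E. faecalis show >100 % relative growth at 5 % honey.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np

from .mic_consensus import MIC_GRID, MicReading, mic_from_net_ods
from .phenol_equivalence import (
    DEFAULT_CORRECTION_FACTOR,
    MIN_MEASURABLE_DIAMETER_MM,
    PHENOL_STANDARDS,
    ZoneMeasurement,
)
from .plate_model import HONEY_CONCENTRATIONS, ORGANISMS, PlateReading, Role

__all__ = [
    "OrganismProfile",
    "HoneyPotency",
    "DEFAULT_PROFILES",
    "DEFAULT_ZONE_CURVE",
    "expected_relative_growth",
    "simulate_growth_plate",
    "simulate_mic_panel",
    "simulate_zone_dataset",
    "simulate_panel",
    "PanelBundle",
]


@dataclass(frozen=True)
class OrganismProfile:
    """Simulator parameters for one test organism.

    ``baseline_net_od`` is the (mean, sd) of the positive-control net OD;
    ``ic50`` the honey % w/v at half-maximal growth for a reference-potency
    honey; ``hill`` the inhibition steepness; ``stim_amp`` the maximal
    fractional growth stimulation as concentration approaches zero;
    ``stim_decay`` the concentration scale (% w/v) over which stimulation
    fades; ``od_noise_sd`` the additive absorbance noise per well.
    """

    name: str
    baseline_net_od: tuple[float, float]
    ic50: float
    hill: float
    stim_amp: float
    stim_decay: float
    od_noise_sd: float = 0.02

    def __post_init__(self) -> None:
        if self.baseline_net_od[0] <= 0 or self.ic50 <= 0 or self.hill <= 0:
            raise ValueError("baseline mean, ic50 and hill must be positive")
        if self.stim_amp < 0 or self.stim_decay <= 0:
            raise ValueError("stimulation parameters must be non-negative")


#: Baselines are the printed positive-control net OD means/SDs; the
#: dose-response parameters are package calibrations (see module docstring).
DEFAULT_PROFILES: dict[str, OrganismProfile] = {
    "S. aureus": OrganismProfile(
        "S. aureus", (0.57, 0.17), ic50=2.2, hill=4.0, stim_amp=0.3, stim_decay=2.0
    ),
    "E. faecalis": OrganismProfile(
        "E. faecalis", (0.34, 0.15), ic50=12.0, hill=4.0, stim_amp=0.8, stim_decay=8.0
    ),
    "E. coli": OrganismProfile(
        "E. coli", (0.81, 0.09), ic50=6.5, hill=4.0, stim_amp=0.3, stim_decay=4.0
    ),
    "P. aeruginosa": OrganismProfile(
        "P. aeruginosa", (1.02, 0.11), ic50=4.5, hill=6.0, stim_amp=5.0, stim_decay=6.0
    ),
}


@dataclass(frozen=True)
class HoneyPotency:
    """Latent "true activity" of a simulated honey.

    ``potency`` multiplies the effective honey concentration seen by every
    organism (1 = reference honey, 0 = inert); ``phenol_equivalent`` drives
    the zone simulator.
    """

    potency: float
    phenol_equivalent: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if self.potency < 0:
            raise ValueError("potency must be >= 0")


def expected_relative_growth(
    profile: OrganismProfile, concentration: float, potency: float
) -> float:
    """Noise-free expected growth fraction g(c) for one organism/honey."""
    stim = 1.0 + profile.stim_amp * math.exp(-concentration / profile.stim_decay)
    inhib = 1.0 + (potency * concentration / profile.ic50) ** profile.hill
    return stim / inhib


# Media/honey colour gives a small positive time-zero absorbance.
_T0_MEAN, _T0_SD = 0.08, 0.005
# The protocol repeats any occasion whose positive control is not clearly
# turbid, so simulated control draws are floored at visible growth.
_CONTROL_FLOOR = 0.15


def _control_draw(profile: OrganismProfile, rng: np.random.Generator) -> float:
    mean, sd = profile.baseline_net_od
    return max(_CONTROL_FLOOR, float(rng.normal(mean, sd)))


def simulate_growth_plate(
    honey: HoneyPotency,
    profiles: Mapping[str, OrganismProfile] = DEFAULT_PROFILES,
    concentrations: Sequence[float] = HONEY_CONCENTRATIONS,
    seed: int | np.random.Generator = 0,
    noise_scale: float = 1.0,
    occasion_id: str = "occ1",
) -> list[PlateReading]:
    """One test occasion: 4 positive controls + 24 honey wells.

    The honey-well net OD is ``g(c) x control_draw + noise`` where the
    control draw is the same well that later normalises that organism's
    relative growth; absorbances are truncated at zero.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    readings: list[PlateReading] = []
    rows = "ABCDEFGH"
    for i, org in enumerate(ORGANISMS):
        profile = profiles[org]
        control_net = _control_draw(profile, rng)
        t0 = max(0.0, float(rng.normal(_T0_MEAN, _T0_SD)))
        readings.append(
            PlateReading(
                well_id=f"{rows[i]}1",
                organism=org,
                honey_concentration=None,
                role=Role.POSITIVE_CONTROL,
                od_t0=t0,
                od_end=max(0.0, t0 + control_net),
            )
        )
        for j, conc in enumerate(concentrations, start=2):
            g = expected_relative_growth(profile, conc, honey.potency)
            net = g * control_net + float(
                rng.normal(0.0, profile.od_noise_sd * noise_scale)
            )
            t0w = max(0.0, float(rng.normal(_T0_MEAN, _T0_SD)))
            readings.append(
                PlateReading(
                    well_id=f"{rows[i]}{j}",
                    organism=org,
                    honey_concentration=float(conc),
                    role=Role.HONEY,
                    od_t0=t0w,
                    od_end=max(0.0, t0w + net),
                )
            )
    return readings


#: Net OD of barely visible turbidity: a human reading MICs by eye calls a
#: well "growth" only above this, well clear of plate-reader noise.
VISUAL_TURBIDITY_OD = 0.1


def simulate_mic_panel(
    honey: HoneyPotency,
    profiles: Mapping[str, OrganismProfile] = DEFAULT_PROFILES,
    seed: int | np.random.Generator = 0,
    noise_scale: float = 1.0,
    occasion_id: str = "occ1",
    no_growth_threshold: float = VISUAL_TURBIDITY_OD,
) -> list[MicReading]:
    """Visual MICs on the 2 % grid, one reading per organism.

    Each well's net OD follows the same growth model; the MIC is read as the
    lowest concentration from which growth stays suppressed (net OD below
    the visual turbidity limit), with off-scale tokens when even 2 %
    inhibits (``<2``) or 30 % does not (``>30``).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    readings = []
    for org in ORGANISMS:
        profile = profiles[org]
        control_net = _control_draw(profile, rng)
        net_ods = {
            float(c): expected_relative_growth(profile, c, honey.potency) * control_net
            + float(rng.normal(0.0, profile.od_noise_sd * noise_scale))
            for c in MIC_GRID
        }
        readings.append(
            MicReading(
                organism=org,
                occasion_id=occasion_id,
                mic=mic_from_net_ods(net_ods, threshold=no_growth_threshold),
            )
        )
    return readings


@dataclass(frozen=True)
class ZoneCurve:
    """Linear squared-diameter relation used to generate zones (mm², % w/v)."""

    intercept: float = 9.4
    slope: float = 55.8
    noise_sd: float = 0.5  # mm, on the diameter scale, before 1 mm rounding

    def diameter(self, phenol_conc: float) -> float:
        return math.sqrt(max(0.0, self.intercept + self.slope * phenol_conc))


#: Calibrated so phenol standards span ~11-20 mm and a PE-34 honey gives a
#: ~20 mm zone, matching the printed zone ranges.
DEFAULT_ZONE_CURVE = ZoneCurve()


def _zone_wells(
    sample: str,
    true_diameter: float,
    curve: ZoneCurve,
    rng: np.random.Generator,
    noise_scale: float,
    n_wells: int = 2,
    n_readings: int = 2,
) -> list[ZoneMeasurement]:
    wells = []
    for w in range(n_wells):
        if true_diameter < MIN_MEASURABLE_DIAMETER_MM:
            wells.append(ZoneMeasurement(sample=sample, replicate_id=f"w{w+1}", no_zone=True))
            continue
        readings = tuple(
            float(
                max(
                    MIN_MEASURABLE_DIAMETER_MM,
                    round(true_diameter + rng.normal(0.0, curve.noise_sd * noise_scale)),
                )
            )
            for _ in range(n_readings)
        )
        wells.append(
            ZoneMeasurement(sample=sample, replicate_id=f"w{w+1}", diameters=readings)
        )
    return wells


def simulate_zone_dataset(
    honeys: Sequence[HoneyPotency],
    phenol_standards: Sequence[float] = PHENOL_STANDARDS,
    curve: ZoneCurve = DEFAULT_ZONE_CURVE,
    seed: int | np.random.Generator = 0,
    noise_scale: float = 1.0,
    correction_factor: float = DEFAULT_CORRECTION_FACTOR,
) -> dict[str, list[ZoneMeasurement]]:
    """Agar-diffusion plate: phenol standards, honeys, water and disc control.

    Honey wells receive 25 % w/v solutions, so a honey of phenol equivalence
    ``PE`` diffuses like phenol at ``PE / correction_factor`` % w/v.  Zone
    noise acts on the diameter scale before rounding to the nearest mm;
    diameters below 9 mm (the bare 8 mm well) are emitted as no_zone.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    zones: dict[str, list[ZoneMeasurement]] = {}
    for c in phenol_standards:
        zones[f"phenol_{c:g}"] = _zone_wells(
            f"phenol_{c:g}", curve.diameter(c), curve, rng, noise_scale
        )
    for k, honey in enumerate(honeys):
        label = honey.label or f"honey_{k + 1}"
        eff = honey.phenol_equivalent / correction_factor
        zones[label] = _zone_wells(label, curve.diameter(eff), curve, rng, noise_scale)
    zones["water_control"] = [
        ZoneMeasurement(sample="water_control", replicate_id="w1", no_zone=True)
    ]
    zones["trimethoprim_disc"] = [
        ZoneMeasurement(
            sample="trimethoprim_disc",
            replicate_id="d1",
            diameters=(float(round(rng.normal(21.0, 1.8))),) * 2,
        )
    ]
    return zones


@dataclass(frozen=True)
class PanelBundle:
    """A full simulated study: plates, MIC panels and zones per honey.

    ``plates`` and ``mic_occasions`` hold per-honey lists of occasions
    (plates: 2; MIC: 3, the third consumed only when the consensus rules
    demand a repeat).  ``truth`` records each honey's latent potency.
    """

    honeys: tuple[HoneyPotency, ...]
    plates: dict[str, list[list[PlateReading]]]
    mic_occasions: dict[str, list[list[MicReading]]]
    zones: dict[str, list[ZoneMeasurement]]
    seed: int = 0

    @property
    def truth(self) -> dict[str, float]:
        return {h.label: h.potency for h in self.honeys}


#: Default latent-potency sampler: log-normal spread around the reference
#: honey, spanning weakly active to strongly active samples.
def _default_potency_sampler(rng: np.random.Generator) -> float:
    return float(np.clip(rng.lognormal(mean=0.0, sigma=0.35), 0.05, 3.0))


#: Phenol equivalence per unit potency; a reference honey (potency 1) sits at
#: the printed panel mean PE of 34 % w/v phenol.
PE_PER_POTENCY = 34.0


def simulate_panel(
    n_honeys: int,
    seed: int = 0,
    potency_sampler: Callable[[np.random.Generator], float] | None = None,
    profiles: Mapping[str, OrganismProfile] = DEFAULT_PROFILES,
    noise_scale: float = 1.0,
    n_plate_occasions: int = 2,
) -> PanelBundle:
    """Simulate a whole study of ``n_honeys`` honeys.

    Each honey gets its own RNG sub-stream keyed by (seed, index) so bundles
    stay stable when ``n_honeys`` changes.  True potencies are retained for
    recovery tests.
    """
    if n_honeys < 2:
        raise ValueError("a panel needs at least 2 honeys")
    if potency_sampler is None:
        potency_sampler = _default_potency_sampler

    honeys: list[HoneyPotency] = []
    plates: dict[str, list[list[PlateReading]]] = {}
    mics: dict[str, list[list[MicReading]]] = {}
    for i in range(n_honeys):
        rng = np.random.default_rng([seed, i])
        potency = potency_sampler(rng)
        honey = HoneyPotency(
            potency=potency,
            phenol_equivalent=PE_PER_POTENCY * potency,
            label=f"honey_{i + 1:03d}",
        )
        honeys.append(honey)
        plates[honey.label] = [
            simulate_growth_plate(
                honey, profiles, seed=rng, noise_scale=noise_scale,
                occasion_id=f"occ{k + 1}",
            )
            for k in range(n_plate_occasions)
        ]
        mics[honey.label] = [
            simulate_mic_panel(
                honey, profiles, seed=rng, noise_scale=noise_scale,
                occasion_id=f"occ{k + 1}",
            )
            for k in range(3)
        ]
    zone_rng = np.random.default_rng([seed, n_honeys])
    zones = simulate_zone_dataset(honeys, seed=zone_rng, noise_scale=noise_scale)
    return PanelBundle(
        honeys=tuple(honeys), plates=plates, mic_occasions=mics, zones=zones, seed=seed
    )


def water_blank() -> HoneyPotency:
    """Sterile distilled water in place of honey: no antibacterial activity."""
    return HoneyPotency(potency=0.0, phenol_equivalent=0.0, label="water")
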