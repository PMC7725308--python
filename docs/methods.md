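# Methods

## The assay model

One test occasion of the optical-density assay produces, per honey, a 4 × 6
grid of wells: four reference organisms (*S. aureus*, *E. faecalis*,
*E. coli*, *P. aeruginosa*) by six final honey concentrations (5, 10, 15, 20,
25, 30 % w/v), plus one untreated positive growth control per organism. Every
well is read at 600 nm immediately after inoculation and again after the
20 ± 2 h incubation; the time-zero reading is the well's own blank, so the
net OD is insensitive to honey colour and media turbidity. Incubation times
outside the ± 2 h window are flagged on the reading, never rejected — the
flag travels with the data so a reviewer can discount the occasion.

Relative growth divides each honey well's net OD by its organism's control
net OD. One control per organism normalises all six of that organism's
concentrations: the plate protocol defines a single growth-control well
composition per organism, so a per-organism (rather than per-condition)
control is the only layout the data model accepts. The unclamped percentage
is retained — low-concentration stimulation legitimately exceeds 100 % and
blank noise can go below 0 % — and a clamped copy restricted to [0, 100]
feeds the scoring.

### Activity units and the activity value

Units are assigned by half-open bins on clamped relative growth:
[0, 10) → 32, [10, 30) → 16, [30, 50) → 8, [50, 70) → 4, [70, 90) → 2,
[90, 100] → 1. Boundary values belong to the upper bin (exactly 10 % earns
16 units) and 100 % earns 1 unit; comparisons use full floating-point
precision — percentages are never rounded before binning. The activity value
is the sum over the 24 conditions, so it is bounded by 24 and 768, is
invariant to relabelling conditions, and is monotone: lowering any relative
growth entry can only raise it. Replicate occasions (≥ 2 required; fewer is
flagged, not refused) are combined by the arithmetic mean of occasion-level
values. A reporting-scale copy rounds half-up to the nearest 50 (or 100)
units for consumer-facing labels; the unrounded mean is always stored.

### MIC consensus

MICs are read on the 2 % grid from 2 to 30 % w/v. Off-scale results are
ascribed 1 % (below scale) and 32 % (above scale) so replicate arithmetic is
possible. Consensus rules: two identical values → that value; two values
≤ 4 % apart → their mean; two values ≥ 6 % apart → a third occasion, then the
mode of three, or the mean when all three differ. A difference of exactly
5 % is achievable only between an ascribed 1 and an on-grid 6; it is handled
like the ≥ 6 branch (request a repeat), the conservative choice. The
two-value discordant case raises a typed error rather than silently
averaging, so a pipeline cannot skip the required repeat. The honey-level
summary is the arithmetic mean of the four organisms' final MICs at full
precision.

### Phenol equivalence

Zone diameters (including the 8 mm well; minimum measurable zone 9 mm;
recorded to the nearest millimetre) are averaged within a well, then across
duplicate wells, and only then squared — mean-then-square, the order the
protocol fixes, which differs from square-then-mean whenever duplicates are
unequal. The standard curve is an ordinary least-squares fit of mean squared
diameter on phenol concentration (2–7 % w/v), valid only when r² > 0.95 and
the slope is positive; an invalid curve withholds all PE values. A honey's
PE inverts the curve at its squared mean diameter, clamps a negative phenol
concentration to zero, and multiplies by 4.69 — the combined correction for
the 1-in-4 honey dilution and an assumed density of 1.35 g/mL, carried as a
configuration constant from the originating protocol (note that 4 × 1.35 =
5.4; the 4.69 is the protocol's value and is taken verbatim, never
recomputed). Mixed duplicates (one well with a zone, one without) are
averaged over measurable wells and flagged. The trimethoprim control disc
passes QC inside an inclusive, configurable range (default 19–26 mm).

### Validation statistics

The limit of detection is blank mean + 3 × sample SD, with blanks produced
by running the full scoring pipeline on water-in-place-of-honey occasions;
the measuring interval is (⌈LOD⌉, 768), with the theoretical floor of 24
reported separately. %RSD is 100 × sample SD / mean. The t-test is two-tailed
with pooled variance, ANOVA the standard between/within F; sample (n − 1)
standard deviations are used throughout, and fully degenerate inputs return
p = 1 (fail-safe). The instrumental LOQ diagnostic takes a 0–100 % culture
dilution series in 10 % steps (≥ 4 replicates each), reports each step's
measured concentration relative to the 100 % step, its bias versus nominal,
whether adjacent steps separate beyond the pooled replicate SD, and the r²
of the linear trend.

## The synthetic-data generator

No plate-level data are deposited, so testing uses a simulator. Its expected
relative growth is

    g(c) = (1 + stim_amp · exp(−c / stim_decay)) / (1 + (potency · c / ic50)^hill)

a Hill inhibition curve times an exponentially decaying stimulation factor —
the minimal form that reproduces the observed dose-response shape:
stimulation above 100 % at 5–10 % honey (most prominent in *P. aeruginosa*
and *E. faecalis*), a steep decline, and organism-ordered susceptibility. It
is a phenomenological choice, not a mechanistic model. A honey is a single
latent `potency` multiplying the effective concentration for every organism,
plus a `phenol_equivalent` driving the zone simulator (34 % w/v phenol per
unit potency, placing the reference honey at the panel-mean PE).

Per-organism defaults:

| organism | control net OD (mean ± SD) | ic50 | hill | stim_amp | stim_decay |
|---|---|---|---|---|---|
| *S. aureus* | 0.57 ± 0.17 | 2.2 | 4 | 0.3 | 2 |
| *E. faecalis* | 0.34 ± 0.15 | 12.0 | 4 | 0.8 | 8 |
| *E. coli* | 0.81 ± 0.09 | 6.5 | 4 | 0.3 | 4 |
| *P. aeruginosa* | 1.02 ± 0.11 | 4.5 | 6 | 5.0 | 6 |

The control distributions are the published per-organism positive-control
values. The dose-response parameters were calibrated once, before any
recovery experiments, to two fixed targets: simulated per-organism MIC means
near the published summaries (*S. aureus* ≈ 5, *P. aeruginosa* ≈ 10,
*E. coli* ≈ 12, *E. faecalis* ≈ 17 % w/v, preserving the strict
susceptibility ordering) and > 100 % relative growth at 5 % honey for
*P. aeruginosa* and *E. faecalis*. At reference potency they give MIC modes
4 / 8 / 12 / 16 and means 4.0 / 8.2 / 11.9 / 16.3. Additive per-well OD noise
defaults to 0.02 absorbance; time-zero blanks are 0.08 ± 0.005. Control
draws are floored at 0.15 net OD because the protocol repeats any occasion
whose growth control is not clearly turbid — without this floor the
*E. faecalis* control (SD nearly half its mean) occasionally produces
occasions a laboratory would discard.

Simulated MICs are read from the same growth model: the MIC is the lowest
concentration from which net OD stays below the visual turbidity limit
(0.1 absorbance — the level a human reader can reliably call by eye, above
plate-reader noise) at all higher concentrations. Suppression already at 2 %
is reported `<2` (the true MIC may lie below the grid) and growth at 30 % is
`>30`. The generic OD-threshold helper `mic_from_net_ods` defaults to 0.05
for instrument-read data; the simulator passes the visual limit explicitly.

Zone datasets draw phenol standards and honeys from a linear squared-diameter
relation (defaults d² = 9.4 + 55.8 · c, spanning ~11–20 mm over the 2–7 %
standards), add diameter-scale Gaussian noise (0.5 mm) and round to the
nearest millimetre; true diameters below 9 mm are emitted as `no_zone`.
Panels use one RNG sub-stream per honey keyed by (seed, index), so a bundle's
first honeys are identical whether 3 or 77 honeys are simulated; latent
potencies default to a log-normal (σ = 0.35) around the reference honey,
spanning weakly to strongly active samples. Three MIC occasions are generated
up front; the third is consumed only when the consensus rules demand a
repeat.

**What the simulator does not emulate:** trailing/indistinct visual
endpoints, honey-specific organism interactions (a single potency scalar
cannot make one honey selectively potent against one organism),
hydrogen-peroxide accumulation between solution preparation and inoculation
(representable only by adjusting potency), plate-position effects, and
inter-operator differences. Passing recovery tests therefore show the
*calculations* are correct and the pipeline recovers a one-dimensional latent
activity under realistic noise — not that the assay resolves
multi-dimensional activity profiles in real honeys.

## Numerical and design choices

- Reporting rounding is round-half-up (644 → 650 at step 50), with the
  unrounded mean always retained; the optional 100-to-750 display clamp is
  never applied to stored values.
- Curve fitting uses `scipy.stats.linregress`; degenerate (zero-variance)
  responses short-circuit to slope 0 / r² 0 so the QC gate trips rather than
  propagating NaN.
- Zero-variance t-test/ANOVA inputs with unequal means return (±inf, 0);
  fully identical inputs return (0, 1).
- The problem sizes exercised in tests (77-honey recovery panels, 10⁴-grid
  binning equivalence, exhaustive consensus-rule enumeration over the
  16-value ascribed set) were chosen as the smallest that exercise every
  code path and the published panel size.

## Known limitations

- The PE ↔ activity-value cross-calibration (trend-line extrapolation) is
  out of scope: the published trend-line equation is not available, and the
  simulator's linear potency→PE link would make any such fit circular.
- The consensus rules are applied to ascribed numeric values exactly as
  printed; whether discordances involving an ascribed 1 or 32 should instead
  force a retest is unresolved in the source protocol.
- Real plate-reader export formats are not parsed; inputs are long-format
  CSVs.
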