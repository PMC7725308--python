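# honeyassay

Assay informatics for quantifying the antibacterial activity of honey from
microplate optical-density data, for honey-testing laboratories and
antimicrobial researchers.

Honey's activity is traditionally measured by the agar-diffusion *phenol
equivalence* (PE) assay, which under-detects non-polar antibacterial
compounds and tests a single organism. The broth-microdilution alternative —
the optical-density activity score — cultures four reference organisms
(*S. aureus*, *E. faecalis*, *E. coli*, *P. aeruginosa*) in six honey
concentrations (5–30 % w/v) in a 96-well plate, reads every well at 600 nm at
time zero and after 20 ± 2 h, and condenses the 24 growth measurements into a
single integer. This package implements that scoring end to end, together
with classical MIC consensus reading, the PE standard-curve calculation, the
assay-validation statistics, and a seedable synthetic-data generator so the
whole pipeline runs and is testable without laboratory data.

## The activity value

For each well, the net optical density is the end-of-incubation absorbance
minus the same well's time-zero blank. Growth relative to the organism's
untreated positive control is

  g = 100 · ΔOD_honey / ΔOD_control  (%)

clamped to [0, 100] for scoring. Each of the 24 conditions is assigned
*activity units* by half-open bins — g < 10 % → 32 units, 10–30 % → 16,
30–50 % → 8, 50–70 % → 4, 70–90 % → 2, ≥ 90 % → 1 — and the antibacterial
activity value is the sum of the 24 unit values, ranging from 24 (no
inhibition) to 768 (complete inhibition everywhere). The limit of detection,
computed as blank mean + 3 SD from water-in-place-of-honey runs, bounds the
usable measuring interval (53–768 activity units under the validation
conditions). Replicate occasions are averaged, with an optional
round-half-up reporting scale (nearest 50 or 100 units).

Also implemented:

- **MIC consensus** — visual MICs on the 2 % grid (2–30 % w/v), off-scale
  ascription (`<2` → 1, `>30` → 32), and the replicate rules: mode of two,
  mean when two differ by ≤ 4 %, third replicate then mode (or mean of three
  when all differ) otherwise; mean MIC across the four organisms.
- **Phenol equivalence** — duplicate zone diameters are averaged *then*
  squared; an OLS standard curve of mean squared diameter on phenol
  concentration (valid only when r² > 0.95) is inverted for each honey and
  multiplied by 4.69 (dilution × density correction).
- **Validation statistics** — limit of detection, %RSD repeatability,
  pooled-variance t-tests, one-way ANOVA, Pearson correlation, and an
  instrumental limit-of-quantitation diagnostic for the plate reader.
- **Synthetic data** — a Hill-type dose-response with low-concentration
  growth stimulation (hormesis), per-organism control-OD distributions, and
  zone diameters consistent with a linear squared-diameter curve.

## Worked example

Simulate a small study, score one honey, and read its MICs and PE value:

```bash
$ honeyassay simulate --n 6 --seed 42 --outdir demo
simulated 6 honeys (seed 42) -> demo; standard curve r² = 0.9912

$ honeyassay score --plate demo/plates/honey_001_occ1.csv \
                   --plate demo/plates/honey_001_occ2.csv --out demo/score.json
activity value 625 (reported 650)

$ honeyassay mic --readings demo/mics.csv --out demo/mics_final.csv
wrote 24 consensus MICs to demo/mics_final.csv

$ honeyassay pe --zones demo/zones.csv --out demo/pe.csv
curve: d² = 19.09 + 52.79·c, r² = 0.9912
```

`score.json` contains, per occasion, the 24 relative-growth percentages and
their activity units, e.g. for occasion 1 of `honey_001` (value 635):

```
E. coli@5%   69.7 %  ->  4 units     (partial inhibition)
E. coli@10%   8.8 %  -> 32 units     (essentially complete inhibition)
E. coli@20%  -1.3 %  -> 32 units     (clamped to 0 before binning)
```

The two occasions (635 and 615) average to 625, reported as 650 on the
nearest-50 scale. In `mics_final.csv`, honey_001's *E. coli* replicates
agreed at 10 % (`mode_two`) while its *E. faecalis* replicates read 12 % and
18 % — a 6 % discordance that triggers a third occasion (14 %) and, with all
three values distinct, the mean-of-three rule (final MIC 14.7 %). In `pe.csv` the same honey's 21.75 mm mean zone converts to a PE of
40.3 % w/v phenol through the fitted curve.

In library form the same pipeline is three calls:

```python
from honeyassay import simulate_panel, panel_results, panel_correlations

bundle = simulate_panel(77, seed=1234, noise_scale=0.3)
results, curve = panel_results(bundle)       # per-honey activity, mean MIC, PE
r, p, r2 = panel_correlations(results)["activity_vs_mean_mic"]
```

On a 77-honey panel at low noise the activity value anti-correlates strongly
with the mean MIC (r ≈ −0.97) and recovers the latent potency ranking
(Spearman ρ > 0.99).

## Layout

```
src/honeyassay/
  plate_model.py          plate readings, CSV I/O, net OD, relative growth
  activity_score.py       unit bins, activity value, replicate aggregation
  mic_consensus.py        off-scale ascription, consensus rules, mean MIC
  phenol_equivalence.py   zone summaries, standard curve, PE, disc QC
  validation_stats.py     LOD, %RSD, t/ANOVA/Pearson, LOQ diagnostic
  synthetic.py            dose-response simulator, panels, zones
  pipeline.py             glue: plates -> scores -> study tables
  cli.py                  honeyassay {score|mic|pe|validate|simulate}
```

See `docs/methods.md` for the model, parameter defaults and limitations.
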