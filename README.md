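# nociscreen

Analysis pipeline for multiwell-MEA analgesic screening on
iPSC-derived sensory neuron-like cells — the hyperexcitable,
Naᵥ1.7-driven cultures used to model inherited erythromelalgia (IEM),
a chronic pain disorder caused by gain-of-function *SCN9A* mutations.
Patient-derived sensory neurons fire spontaneously; a compound is an
analgesic candidate if it suppresses that firing without killing the
cells and lets activity recover on washout.

The package covers the full funnel, plus a synthetic-data generator so
every stage is testable without recordings:

1. **Spike detection** — raw µV traces (20 kHz) are band-pass filtered
   (1–10 kHz, zero phase), thresholded at ±5 robust noise SDs
   (1.4826 × MAD) with a 1 ms + 2 ms dead time, and reduced to firing
   rates; channels above 0.33 Hz count as active.
2. **Hit calling** — per compound, paired before/after channel rates
   give normalised activity `100·mean(after)/mean(before)`, a
   BH-corrected Wilcoxon signed-rank p, a robust effect size
   `z′ = Δmedian / pooled MAD`, and Cohen's *d*. A hit needs activity
   < 50%, p_FDR < .01, |z′| > 1.96, |d| > 0.80 and ≥ 9 active
   channels, and is tiered high/moderate/low by its rate reduction
   (> 90 / 70–90 / 50–70%).
3. **Filters** — LDH cytotoxicity (background-subtracted A490−A680,
   normalised vehicle→positive control, toxic above 5% at any of
   1/6/24 h) and washout reversibility (recovered fraction of the
   inhibited gap).
4. **Concentration–response** — inhibitory Hill fits on MEA activity,
   `A(c) = 100/(1+(c/IC50)^n)`, on tiered concentration grids; and
   linear-concentration Boltzmann fits on patch-clamp inhibition
   fractions, `ΔI/ΔI_TTX = 1/(1+exp((IC50−c)/h))`. Candidates for
   patch clamp need IC50 ≤ 8 µM and recovery ≥ 60%.
5. **Patch clamp** — gap-free and current-step activity classes
   (quiet / attempting / spontaneous; single vs train), AP shape
   parameters (threshold from the third-derivative peak, half-height
   width, dV/dt extrema), and voltage-step Naᵥ/Kᵥ I–V curves with
   TTX-normalised compound inhibition at the −35 mV step.

See `docs/methods.md` for models, conventions and numerical choices.

## Worked example

Screen a synthetic 8-compound library (two true suppressors planted,
one of them irreversible; three wells of 12 electrodes per compound,
300 s phases):

```python
from nociscreen import synthgen as sg, pipeline as pl

spec, exposures, truths = pl.design_screen(
    n_compounds=8, n_hits=2, n_irreversible=1, seed=1)
rates = sg.simulate_rate_table(spec, exposures, truths)   # detect-level rates
ldh = sg.simulate_ldh(truths, seed=1)
report = pl.run_pipeline(rates, exposures, ldh_table=ldh, seed=1)
print(report.screen_table.round(4).to_string(index=False))
print(report.to_json())
```

The screen table shows the two planted suppressors passing every
criterion while the inert compounds sit at ~100% activity:

```
compound_id  normalised_activity  p_fdr  robust_z  cohen_d  n_active  is_hit tier
       C001               0.6975 0.0000   -4.3521  -3.0369        23    True high
       C002               0.9355 0.0000   -3.2703  -2.5006        30    True high
       C003              99.2643 0.8928   -0.0776  -0.0108        25   False none
       ...
```

and the funnel report prunes the irreversible hit:

```
"counts": {"compounds": 8, "hits": 2, "nontoxic_hits": 2,
           "reversible": 1, "candidates": 1}
```

`C001` and `C002` suppress firing to < 1% of baseline (high-intensity
hits, p_FDR ≈ 10⁻⁵ over ~2 dozen active channels); `C001` fails the
washout filter because its firing never recovers, leaving `C002` as
the patch-clamp candidate.

For voltage-trace-level work, `sg.simulate_plate(...)` renders full µV
traces (`nociscreen.pipeline.summarise_plate` runs the detector over
them), and the same steps are available from the shell:

```bash
nociscreen simulate --n-compounds 4 --n-hits 1 --duration 30 --out plate.h5
nociscreen detect --plate plate.h5 --out rates.csv
nociscreen fit --points points.csv --model boltzmann_linear --out fits.csv
nociscreen run --config screen.yaml
```

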