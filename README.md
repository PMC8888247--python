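# presspulse

Quantitative analysis of **press–pulse perturbation experiments** on
aquatic microbial communities.  The package targets the common mesocosm
setting in which a sustained pressure (*press*: stepwise phosphorus
enrichment, i.e. eutrophication) is crossed with transient shocks
(*pulses*: H₂O₂-induced mortality events applied to a volume fraction of
each mesocosm), and the community response is followed as a chlorophyll-a
timeseries.  It is written for ecologists who want a tested, reusable
implementation of the full chain: simulate or ingest the timeseries,
segment each perturbation cycle, compute stability indices, and estimate
treatment and repeated-perturbation effects.

## The indices

Each perturbation cycle is reduced to three levels of the response
variable: the **pre-response condition** C₀ (the least-variance moving
window — ≥2 sampling points spanning ≥3 days — before the response peak),
the **peak**, and the **post-event condition** (for interior cycles,
identically the next cycle's pre-response condition).  From these:

- **maximum displacement**  D₀ = |Peak − C₀|  (µg Chl-a/L)
- **resistance**  RS = 1 − 2·D₀/(C₀ + D₀)  ∈ (−1, 1];  RS = 1 means no
  change, RS = 0 a 100 % change relative to C₀
- **recovery**  RC = 2·D₀/(D₀ + Dₓ) − 1, with Dₓ = |post-event − C₀| the
  residual displacement;  RC = 1 is full return, RC = 0 no recovery,
  RC < 0 drift

Both indices are scale-invariant, so systems of different trophic state
compare directly.  For reporting they are rescaled onto [0, 10] by
strictly monotone maps anchored at RS: 1→10, 0→9, −1→0 and RC: 1→10,
0→1, −1→0.

Effects of eutrophication and of the number of sequential pulses on each
metric are estimated with linear mixed models (pulse count and treatment
as fixed effects with the control as reference; replicate intercepts and
the pulse-intensity level as variance components), reported with marginal
and conditional variance explained.

## Worked example

Simulate the default design — 3 treatments (control, mid-strong and
strong enrichment toward 0.41 / 0.82 mg TP/L) × 6 replicates, 105 days
sampled every other day, pulses at days 4/40/68 removing 50/15/30 % of
the community — then segment, score and model it:

```bash
presspulse run --out-dir demo --seed 7
# pipeline complete: 54 metric rows, 72 biovolume means -> demo
```

or equivalently in Python:

```python
import presspulse as pp

design = pp.ExperimentDesign.default()
ts = pp.simulate_experiment(design, pp.SimulationParams(seed=7))
windows = pp.CycleSegmenter(pulse_days=design.pulse_days).fit(ts).transform(ts)
metrics = pp.PerturbationIndices(design=design).fit(windows).transform(windows)
fits = pp.fit_metric_trends(metrics)
print(pp.estimate_displacement_ratio(metrics))   # 1.769
```

With seed 7 the 54 scored perturbations show the canonical press–pulse
pattern.  Per-cycle treatment means:

| treatment | cycle | C₀ | D₀ | RS (0–10) | RC (0–10) |
|---|---|---|---|---|---|
| control | 1 | 2.1 | 31.1 | 1.16 | 5.85 |
| control | 2 | 11.4 | 58.9 | 3.00 | 4.94 |
| control | 3 | 33.9 | 75.5 | 5.61 | 4.73 |
| mid     | 3 | 64.9 | 156.9 | 5.28 | 5.02 |
| strong  | 3 | 69.4 | 147.0 | 5.81 | 4.90 |

Baselines ratchet upward after every pulse (incomplete recovery),
rescaled resistance climbs from ≈1 to ≈6 across the three cycles in every
arm, and the enriched arms displace about twice as many absolute
chlorophyll units as the control (estimated enriched:control D₀ ratio
1.77) while their *relative* resistance is indistinguishable from the
control — the mixed-model treatment term for rescaled resistance is
non-significant (F ≈ 2.4, p ≈ 0.10) even though the same term for D₀ is
strong (F ≈ 29.8, p < 0.001; marginal R² 0.79, conditional 0.85).

The `demo/` directory holds every intermediate artifact: the tidy
timeseries, per-sample N:P limitation classes (16:1 / 25:1 molar bands),
response windows, the metrics table, cycle-averaged biovolumes, the
effects table and per-metric trend plots.

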