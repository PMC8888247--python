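# Methods

## Scope

`presspulse` implements a complete analysis chain for press–pulse
perturbation experiments on phytoplankton communities: a synthetic-data
generator with the statistical structure such experiments produce, the
dilution mass balance used to plan phosphorus dosing, automated
segmentation of perturbation cycles, the displacement / resistance /
recovery indices, and mixed-model estimation of treatment and
repeated-perturbation effects.  Everything operates on tidy long-format
tables (one row per replicate × day, or per replicate × cycle).

## Perturbation indices

A cycle runs from one pulse day to the next (the last to the series
end).  Within it we locate:

- **pre-response condition C₀** — the mean of the least-variance
  contiguous sample window with at least 2 points spanning at least
  3 calendar days (inclusive), searched before the cycle's peak.  With
  every-other-day sampling the minimal window is 2 samples spanning
  3 days, satisfying both window constraints simultaneously.  Ties break
  to the earliest start day, then the shortest window; variance is the
  unbiased sample variance of raw (untransformed) chlorophyll-a.
  Because responses lag the pulse, the search reaches back into the
  previous cycle's tail, by default from the midpoint between the
  previous peak and the pulse day; this also means C₀ does not
  necessarily describe the instant before the pulse but the moment
  before the system visibly reacts.
- **peak** — the maximum observed value after the pulse day.
- **post-event condition** — for interior cycles, identically the next
  cycle's pre-response window (the chaining identity holds exactly by
  construction).  For the final cycle, the least-variance window within
  the last quarter of the cycle, flagged *unrecovered* when its variance
  exceeds 5× the pre-response variance (configurable) and its
  coefficient of variation exceeds 0.02.  Under multiplicative
  observation noise this flag is conservative — the pre-response
  variance is a minimum over many candidate windows and plateaus sit at
  higher levels than C₀, so late cycles are over-flagged; the flag is
  diagnostic only and never enters the index values.

From the three levels: D₀ = |Peak − C₀|, Dₓ = |post-event − C₀|,
RS = 1 − 2D₀/(C₀+D₀) and RC = 2D₀/(D₀+Dₓ) − 1.  D₀ is taken as a
magnitude (responses here overshoot upward; a signed difference would
flip sign without changing the index content), and Dₓ is the *residual
displacement* of the post-event level from C₀ — the reading under which
the standard worked example (pre-response 10, peak 20, post-event 20 →
RC = 0) is consistent.  An undisplaced cycle (D₀ = Dₓ = 0) is defined as
full recovery and flagged `degenerate` rather than raised, so batch
processing never aborts.

The [0, 10] report scale uses the simplest strictly monotone
piecewise-linear maps through the published anchors — resistance 1→10,
0→9, −1→0 (expanding the low-resistance half) and recovery 1→10, 0→1,
−1→0 (expanding the high-recovery half).  Exponential alternatives
through the same anchors exist; both rescalers are injectable arguments
of `compute_metrics` / `PerturbationIndices` so they can be swapped
without touching callers.

## Dosing mass balance

`predict_tp` evaluates the three-solution dilution
TP = (c_c·v_c + c_r·v_r + c_s·v_s)/(v_c+v_r+v_s) with the volume-closure
invariant v_c+v_r+v_s = mesocosm volume (10 L by default).
`solve_dose_volume` inverts it for the stock volume, with the refill
volume absorbing the slack (refill water tops the vessel up); targets
outside [no-dose mixture, full-stock top-up] raise a dedicated
infeasibility error.  The stock concentration is a stand-in (40 mg P/L)
chosen so that a ~0.1 L dose reaches the mid-strong target from ambient
TP.  N:P limitation uses molar ratios (N 14.007, P 30.974 — molar
because the 16:1 Redfield bound is molar; constants configurable):
above 25:1 P-limited, below 16:1 N-limited, the closed band in between
co-limited (band edges inclusive — the bands' sources do not dictate the
boundary assignment).

## The synthetic generator

The generator is *structural*: it produces data with the features the
analysis assumes, with known ground truth for parameter-recovery tests.
It is not a calibrated ecosystem model.

Each mesocosm carries chlorophyll-a biomass `B` and a phosphorus ledger
(dissolved, dead-organic, sequestered, plus biomass P = B/chl_yield) and
a dissolved-nitrogen pool.  Between events, `B` follows the exact
discrete logistic map toward a time-varying target capacity

    K(t) = min( κ(t)·G + boost(t),  B + chl_yield·PO4,  DIN-capped ),

integrated in 0.5-day substeps.  All biomass increments draw phosphorus
from the dissolved pool and all decrements feed the dead pool, which
remineralizes at 0.1 /day — so with no dosing and no refill, total
phosphorus is conserved to machine precision (a tested invariant).  In a
constant-capacity, pulse-free configuration the trajectory equals the
logistic closed form exactly, because the integrator uses the exact
logistic step rather than an Euler approximation.

Events at each pulse day, in order: (i) sampling (the day's observation
precedes the pulse); (ii) instantaneous fractional mortality — a pulse
of fraction f kills exactly f of the biomass, moving its P and N to the
dead pools and leaving dissolved nutrients untouched at that instant;
(iii) the refill/dosing dilution step via the dilution equation above (refill
volume = accumulated sampling losses, 0.07 L per sampling); (iv) the
bloom response.

Three phenomenological controls give the tests known ground truth:

- **bloom boost.**  Each pulse injects a decaying capacity boost of
  amplitude `response_gain · hardening^(completed pulses) · f^¼ · κ·G`
  (decay 0.18 /day).  The gain (35) makes the first cycle violent —
  first-cycle peaks are an order of magnitude above baseline, matching
  the near-zero rescaled resistance such experiments report for a novel
  shock — and the hardening multiplier (0.3 per completed pulse) damps
  later responses, so rescaled resistance climbs cycle over cycle.  The
  ¼-power intensity dependence keeps displacement positively but weakly
  correlated with pulse fraction and vanishes at f = 0, preserving the
  pulse-free logistic limit.
- **recovery loss.**  After pulse p the equilibrium baseline G ratchets
  up by min(1, 0.15·p) of the bloom amplitude: each successive cycle
  retains a larger share of its displacement, so recovery declines
  across cycles and baselines rise (control ≈ ×16 over three cycles,
  enriched ≈ ×30 — the same order as mesocosm observations).
- **enrichment capacity multiplier.**  Enrichment multiplies the
  carrying capacity by `eutro_displacement_multiplier` (default 2) once
  total P passes a low saturation level (0.1 mg/L) — chlorophyll
  capacity saturates quickly in TP because nitrogen and light, not
  phosphorus, cap enriched blooms; this is also why the two enrichment
  levels respond nearly identically.  The multiplier engages along a
  lagged sigmoid (lag 12 d, width 2.5 d after the first dose),
  representing the community restructuring that realises the higher
  capacity.  The timing matters: κ is still ≈1 at the cycle-1 peak and
  fully saturated before the cycle-2 pre-response window, so from cycle
  2 onward baselines *and* bloom amplitudes scale together.  That makes
  absolute displacement ≈2× the control while D₀/C₀ — hence resistance —
  is treatment-free: the headline contrast the effect-estimation stage
  must recover.

Observation noise is multiplicative lognormal (CV 0.10), independent
across days, replicates and channels — concentrations are positive and
heteroscedastic; replicate baselines get a small persistent lognormal
spread (CV 0.03) so replicate random intercepts are estimable.  Group
chlorophyll fractions are deterministic shares of the observed total
(cyanobacteria gaining with enrichment), so they sum to the total
exactly.  Dissolved PO4 follows the ledger, with dosed surplus above the
ambient level sequestered at 0.25 /day (sorption/luxury uptake) — this
makes the mid-strong arm traverse the co-limitation band during its
second cycle while the strong arm jumps directly to N-limitation and
the control stays P-limited.  Biovolume is proportional to biomass
(2×10⁵ µm³/ml per µg Chl-a/L) with its own noise draw.

The nutrient pools are deliberately generous (70 µg P/L, 800 µg N/L
dissolved at start) so that the *imposed* capacity, not an accidental
ledger exhaustion, sets every bloom ceiling; the quota caps exist as
safeguards and as the mechanism for the conservation oracle, and the
starting TP (≈0.071 mg/L) remains below the first dose target so dosing
stays feasible.

What the generator does **not** emulate: taxon-resolved composition and
succession, grazing and top-down control, H₂O₂ chemistry and decay,
periphyton, within-day dynamics, autocorrelated observation error, and
any feedback from community structure to the response parameters.
Passing tests therefore certify the *pipeline* — segmentation, index
algebra, estimator calibration and power under the stated noise
structure — not ecological forecasts for real mesocosms.

One structural consequence worth knowing: because the first dose lands
inside cycle 1, the enrichment-driven baseline shift registers as
cycle-1 residual displacement for the enriched arms, so their cycle-1
recovery dips below the control's.  Recovery declines monotonically
within the control arm and from cycle 2 onward overall, but the
pooled-across-treatments cycle-1 mean sits below the cycle-2 mean.  This
is a faithful consequence of measuring recovery against a moving
baseline under a press, not an artifact of the segmentation.

## Effect estimation

`fit_metric_trends` fits, per metric (C₀, D₀, rescaled RS, rescaled RC),
a linear mixed model with the pulse count (continuous) and the treatment
(control as reference) as fixed effects — optionally their interaction —
and two variance components: replicate identity and pulse-intensity
level.  Smooth (additive) cycle terms are deliberately replaced by the
same linear structure: three cycle levels cannot support meaningful
smooths, and the artifact's purpose is effect estimation, not curve
shape.  REML fitting uses statsmodels' MixedLM; a singular or failed fit
falls back to a replicate-intercept-only model and then to OLS, recorded
in the result's `model_kind`.  Fixed-effect p-values use Wald t (1-df
terms) or Wald F (multi-level terms) statistics with n − k residual
degrees of freedom — a pragmatic approximation whose type-I error on
null metric tables is verified by simulation to sit at ≈5 % — and a
seeded permutation fallback (5000 draws; treatment labels permuted
across replicates, cycle order within replicates) is available for small
designs.  Variance explained is reported as marginal
var(Xβ)/(var(Xβ)+Σσ²ᵤ+σ²ₑ) and conditional
(var(Xβ)+Σσ²ᵤ)/(·) — marginal ≤ conditional by construction.

Because the pulse-intensity level varies only between cycles, a
3-level intensity component is nearly collinear with the trend term;
with systematic cycle-level curvature it absorbs part of the trend
signal.  This mirrors the design being emulated (intensities were
applied per cycle, not factorially) and is the reason the power and
type-I examples are run on metric-level tables with a controlled trend.

The enrichment fold-change on displacement
(`estimate_displacement_ratio`) is the ratio of model-estimated marginal
means (enriched arms averaged vs control, at the average pulse count) on
the raw µg/L scale — the scale on which "about twice the control" is the
natural statement.  Pooling includes cycle 1, where enrichment has not
yet differentiated the arms, so a generator multiplier of 2 yields an
estimate near 1.8.

`fit_chl_biovolume` regresses total chlorophyll on biovolume with a
treatment interaction (OLS); `log10='auto'` applies a joint log10
transform when a D'Agostino residual-normality screen rejects at 0.05.
`cycle_average_biovolume` averages biovolume per replicate over the
Baseline/P1/P2/P3 periods (3 treatments × 6 replicates × 4 periods = 72
records under the default design); `total_biovolume` averages technical
counts bin-wise before summing bins.

## Numerical and interface choices

- Days are integers from experiment start (day 0 = first sample); a
  pulse on a sampling day is applied after that day's sample.
- The integrator substep is 0.5 d; the logistic update is exact per
  substep, so only the piecewise-constant treatment of K within a
  substep limits accuracy.
- Window ties (equal variance) resolve deterministically (earliest,
  then shortest), making segmentation reproducible byte-for-byte.
- All tables are long-format CSV with `#` unit-header comments; configs
  are YAML with unknown-key rejection; every writer's output re-parses
  under the package's own readers.
- Identical config + seed reproduces every numeric output bit-for-bit;
  the RNG is a per-replicate spawn of one seed sequence.
- Analysis stages are scikit-learn-style estimators
  (`CycleSegmenter`, `PerturbationIndices`, `MetricTrendModel`,
  `ChlBiovolumeModel`) so they compose with sklearn pipelines and
  model-selection utilities; the module-level functions are thin
  wrappers over the same code.

## Problem sizes used in the checks

The behavioural test suite runs the full default design (18 mesocosms,
105 days): 100 seeded replications for the parameter-recovery check of
the enrichment contrast, 200 seeded null tables (×4 metrics) for type-I
calibration, 100 random fixtures for the window-search oracle, and 200
random dilution steps for the dosing round-trip — sizes at which the
binomial uncertainty of the checked rates is a small fraction of the
tolerance being asserted.
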