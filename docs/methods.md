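# Methods

`bulbwave` quantifies pharmacological suppression of spontaneous olfactory
bulb (OB) network activity in slice field recordings, and the behavioral
consequence of the same insult in a right-censored hidden-food assay.  It
pairs the analysis pipeline with a synthetic-data generator whose defaults
encode the study conditions the pipeline is meant to handle, so that every
estimator can be validated against exported ground truth.

## Signal model

The local field potential (LFP) recorded in the OB granule cell layer is
modelled as a zero-mean Gaussian process with one-sided power spectral
density

    S(f) = C · [ f^(-α) + ρ · L(f) ],   f ∈ [f_hp, f_lp]

where `f^(-α)` is the broadband 1/f background (α = 1 by default), `L(f)` is
a second-order (Lorentzian) resonance normalized to 1 at its center
`f0 = 13.3 Hz` with full bandwidth 4 Hz, and `ρ = 8` sets the resonance
height relative to the background at 1 Hz.  `C` scales the trace to a target
RMS of 50 µV at unit gain.  The pass band mimics the acquisition chain
(0.5 Hz highpass, 1.5 kHz lowpass); the default sampling rate is 3 kHz.
Traces are synthesized in the frequency domain (white Gaussian noise shaped
by `sqrt(S)`), which makes the expected spectrum exact and the trace a
deterministic function of the seed.

These choices are deliberate idealizations: the family (1/f plus a single
resonance) matches what broadband OB slice spectra look like — a decaying
background with one dominant hump in the beta range — but no claim is made
that real granule-layer LFPs are Gaussian, stationary within condition, or
single-peaked.  With `ρ = 8` the resonance carries most of the 1–50 Hz
variance, which is what makes the argmax peak-frequency estimator stable at
the paper-scale cohort size (n = 7); a weaker resonance would demand a
smoothed estimator the pipeline deliberately does not use.

## Drug effect model

Bath application of amyloid-beta oligomers is modelled as a
**frequency-uniform multiplicative attenuation of power**: a gain envelope
`g(t) ∈ [0, 1.5]` multiplies the expected PSD at every frequency, i.e. the
amplitude is scaled by `sqrt(g(t))`.  Power (not amplitude) is the natural
scale because every effect size of interest is an integrated-power ratio.
Frequency uniformity encodes the observed phenomenology — all bands are
suppressed proportionally and the peak frequency does not move.

Within a drug epoch the gain follows a dead time `d` and then an exponential
approach to the condition plateau with half-time `h`:

    g(t) = p + (g_entry − p) · 2^(−(t − t_epoch − d)/h),   t ≥ t_epoch + d

continuous at epoch boundaries (`g_entry` is the previous epoch's final
gain).  A single exponential cannot reproduce both printed time-course
anchors of the 30 nM condition (≈76% of control at 15 min and ≈59% at
25 min en route to a 40% plateau): the 15→25 min decay rate implies
`h ≈ 10.8 min`, which without a delay would put 15 min at ≈63%.  The
delayed-exponential with `d = 6.9 min, h = 10.8 min` passes through both
anchors exactly and approximates the sigmoidal onset such slow bath effects
show.  `d` defaults to 0 in the model type, so the pure-exponential closed
form holds unless a preset opts in.

Condition plateaus (fraction of control power) are taken per age group:

| condition  | 3 wk  | 6 wk  | 8 wk  |
|------------|-------|-------|-------|
| 3 nM       | 0.967 | 0.932 | 0.652 |
| 10 nM      | 0.804 | 0.542 | 0.546 |
| 30 nM      | 0.532 | 0.441 | 0.468 |

with inverse-sequence peptide fixed at 1.0 (inactive by construction),
washout relaxing to 1.0 with half-time 15 min, and lidocaine at 0.02
(near-total suppression, viability control).

## Between-slice variability

Raw recordings also carry a slow **Ornstein–Uhlenbeck log-power drift**
(stationary SD 0.08, correlation time 30 min), frequency-uniform like the
drug gain.  This is the one free noise knob the data do not pin: it was set
once so that cohort SEMs of normalized power land in the low single digits
of percent (the order the slice experiments report), and is not part of the
exported ground-truth envelope.  Setting `drift_log_sd = 0` gives a
recording whose only variability is periodogram sampling noise — useful for
exact scaling tests.

## Spectral quantification

- **Segments**: 20 s every 5 min, positioned at the start of each 5-min
  block; a segment belongs to a condition only if it lies wholly inside the
  condition's epoch; partial trailing segments are dropped.
- **Periodogram**: one Hamming-tapered periodogram per whole segment (no
  Welch sub-averaging — a `SegmentSchedule` is the place to add it if ever
  needed), mean detrended, divided by the taper's mean square so that the
  PSD integral equals the taper-weighted mean square of the segment (an
  exact identity; agreement with the plain sample variance is a large-N
  statement and is tested at the 1% level on long white segments).
  Frequency resolution is 1/20 s = 0.05 Hz; the spectrum is then restricted
  to 1–50 Hz, which also removes DC.
- **Condition spectrum**: bin-wise mean of the **last two** segments of the
  epoch (end-of-condition measure).
- **Bands**: theta 2–12 Hz, beta 13–35 Hz, gamma 35–50 Hz, full 1–50 Hz.
  The 12–13 Hz gap of the printed definitions is kept.  Band power is the
  trapezoidal integral with interpolated edges, so adjacent bands tile an
  interval without double counting (35 Hz contributes half-weight to beta
  and gamma each); at 0.05 Hz resolution the trapezoid-vs-bin-sum
  difference is far below every tolerance used.
- **Normalization**: integrated band power as percent of the same slice's
  control-condition integral; the control epoch used as reference is the
  *first* one, so a long control-only recording can be tracked against its
  own beginning.  Control normalizes to exactly 100.
- **Peak frequency**: argmax over 1–50 Hz, ties to the lowest frequency,
  NaN sentinel for an all-zero spectrum.  No smoothing.
- **Time-course**: per-segment (not pairwise-averaged) full-band power,
  normalized to the reference condition, at the 5-min cadence; times from
  drug onset or recording start.

A single 20-s periodogram of this resonance-dominated signal carries ≈10%
sampling noise on its 1–50 Hz integral (the resonance concentrates the
variance into ~100 spectral degrees of freedom); condition averages of two
segments carry ≈6–7%, and 7-slice cohort means ≈2–4%.  Test tolerances
follow from these scales.

## Rank statistics

All tests are implemented from their defining formulas (the only scipy
usage is the chi-square/normal reference distributions and `rankdata`):

- Kruskal–Wallis H with the `1 − Σ(t³−t)/(N³−N)` tie correction, p from
  χ²(k−1).  Degenerate all-equal input yields H = 0, p = 1 rather than an
  error.
- Dunn's pairwise z on mean ranks with the matching tie term; two-sided
  normal p; family-wise Bonferroni over all pairs by default (the
  unadjusted mode is one flag away, and both p's are reported).
- Friedman's within-block rank χ² with average ranks for ties and the
  standard tie-corrected denominator.
- Wilcoxon signed-rank: zeros dropped, W = min(W⁺, W⁻); exact two-sided p
  for n ≤ 15 by dynamic programming over all 2ⁿ sign patterns (tied
  absolute differences handled through their average ranks, doubled to
  integers), normal approximation with continuity and tie correction
  beyond.  n ≤ 15 exact keeps the paper-scale n = 6–10 comparisons exact.
- Summaries: mean ± SEM and median + IQR with linearly interpolated
  quantiles.  Censored latencies enter **at the cap** (600 s) in both the
  mean and the quantiles — the convention a truncated stopwatch assay
  imposes — and the median is flagged as a lower bound when more than half
  a cell is censored.  Kaplan–Meier-style estimates are out of scope.

The test suite cross-checks every statistic against independent oracles:
manual ranking by sorting, the rank-ANOVA identity for H, Conover's T1 form
for Friedman, full sign-pattern enumeration for Wilcoxon, and scipy where
scipy implements the same quantity.

## Behavioral model and analysis

Hidden-food search latencies are lognormal before censoring (a family
chosen for right-skewed positive reaction times; the data pin only
medians/means), with log-scale σ = 0.9, a per-animal intercept (σ = 0.3)
that makes repeated weeks pairable, and right-censoring at 600 s.  Default
medians: vehicle ≈120 s every week; treated animals 150 s at week 1, then
650/800/1000 s at weeks 2–4 — i.e. the deficit begins at week 2 and the
majority of the treated cell hits the cap, reproducing "k of n animals
failed" patterns.  Visible-food latencies (median 25 s), food intake at
30/120 min (8 g/15 g, SD 2 g), and weight gain (+2% of baseline per week,
SD 1.5) carry **no** group effect.

The analysis reports, per week: censoring-aware medians + IQR and
means ± SEM, failure counts, a two-group Kruskal–Wallis (equivalent to a
rank-sum test) between groups, and a paired Wilcoxon of each group against
its own week 1.  Controls (visible latency per feeding stratum, intake per
window, weight per week) run the same machinery.  The pipeline's
interpretation guard only reports "olfactory deficit" when the hidden-food
effect coexists with uniformly quiet controls; any significant control
demotes the verdict to "confounded".

What passing these tests shows — and does not.  The generator reproduces
the *statistical skeleton* of the assay (effect sizes, censoring rates,
paired structure, null controls).  It does not model corner choice, search
trajectories, odor concentration, habituation, or any correlation between
electrophysiological and behavioral outcomes, so passing says nothing about
those aspects of real data.

## Numerical and reproducibility choices

- One master seed per cohort; per-entity seeds derived with
  `numpy.random.SeedSequence` (counter-based, masked below 2³¹).  Identical
  seeds give bit-identical traces, tables, and files.
- Epochs are half-open in time: the boundary instant belongs to the next
  epoch.  Segment/epoch containment uses a 1 ns guard against float edges.
- Degenerate inputs prefer labeled results over exceptions where a
  degenerate value is statistically meaningful (all-tied test data, all-zero
  spectra) and labeled `ValueError`s otherwise (empty groups, bands outside
  the spectrum, timelines that do not start with control).
- The CSV interchange writes floats at 17 significant digits and reads them
  with round-trip parsing, so simulate → write → load is bit-exact.

## Problem sizes used in the test suite

The stability and inverse-peptide checks run at the full default
acquisition (3 kHz, 181 and 80 min).  The 20-master-seed recovery sweep
(3 plateaus × 7 slices) runs at 250 Hz sampling with a 100 Hz lowpass and a
15 + 30 min timeline with instant onset, sizes chosen because the recovery
property — normalized power estimates the plateau gain — is invariant to
sampling rate and epoch length once the measured segments sit on the
plateau.  Behavioral power/specificity use 200 replicates per arm.

## Known limitations

- The generative spectrum is stationary within an epoch up to the OU drift;
  real slices show richer nonstationarity (state switches, seizure-like
  events) that the stability analysis would flag as drift.
- Attenuation is exactly frequency-uniform; genuinely band-selective drug
  effects would violate the proportionality property the pipeline leans on.
- The censored-latency summaries are substitution-based, not survival
  estimates; with heavy censoring the reported medians are lower bounds and
  are flagged as such, but between-group rank tests treat cap ties exactly
  like any other tie.
- The Dunn family adjustment is plain Bonferroni; no stepwise or
  resampling-based multiplicity control is provided.
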