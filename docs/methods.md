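# Methods

## Poincaré variance decomposition

The analysis operates on the Poincaré plot of adjacent normal-to-normal
(NN) interval pairs (RRₙ, RRₙ₊₁), in milliseconds.  Each point is labelled
by the strict sign of RRₙ₊₁ − RRₙ: deceleration (above the identity line),
acceleration (below), or no-change (on it).  With dᵢ = (xᵢ − yᵢ)/√2 and
ℓᵢ = (xᵢ + yᵢ)/√2, ℓ̄ the mean of ℓ over all points, and n the number of
points:

- SD1d² = (1/n) Σ_decel dᵢ², SD1a² = (1/n) Σ_accel dᵢ²; no-change points
  have dᵢ = 0, so SD1² = SD1d² + SD1a² holds exactly.
- SD2d² = (1/n)[Σ_decel (ℓᵢ − ℓ̄)² + ½ Σ_nochange (ℓᵢ − ℓ̄)²], and
  symmetrically for SD2a², so SD2² = SD2d² + SD2a² holds exactly.
- SDNNd² = (SD1d² + SD2d²)/2 and likewise for SDNNa² and SDNN², making
  2·SDNN² = SD1² + SD2² an identity.

Three conventions deserve justification because the additive identities are
asserted to 1e−9 relative tolerance rather than approximately:

1. **Population normalisation.**  Every component variance divides by the
   total point count n.  Any n−1 convention would preserve the identities
   too, but mixing conventions (e.g., a sample-variance SD2² against
   population components) would not; one convention is used throughout.
2. **No-change points.**  Ties contribute nothing across the identity line
   and are split half-and-half along it.  This is the convention of the
   decomposition's standard methodology; for continuous synthetic data ties
   essentially never occur, but integer-rounded clinical exports produce
   them in quantity, and the halving rule keeps both SD2 parts unbiased
   between the two labels.
3. **SDNN² as (SD1² + SD2²)/2 over plot points.**  Defined this way (the
   mean of the two projected variances, equivalently the average of the x-
   and y-coordinate variances of the plot), the total-variance relation is
   exact for any finite series rather than asymptotic in series length.

A ratio whose denominator is zero (constant series for C1d/C2d/CTd, or no
heart-rate-changing beats for Nd) is undefined and carried as NaN with
explicit validity flags; 0/0 is never coerced to 0.5 or 0.  Recordings with
undefined ratios are excluded from cohort prevalence denominators.

Phenotypes use strict inequalities: HRA1 ⇔ C1d > 0.5, HRA2 ⇔ C2d < 0.5,
HRAT ⇔ CTd < 0.5, HRAN ⇔ Nd < 0.5, HRAcomp ⇔ HRA1 ∧ HRA2.  Each recording
is analysed whole (one plot per 24-h recording); no windowing or averaging.

## Recording QC

Eligibility requires: duration ≥ 18 h (computed from summed RR, since the
text export carries no wall-clock timestamps), sinus fraction ≥ 0.90
(artifacts count in the denominator — all recorded beats), fewer than 100
supraventricular + ventricular beats within any one hour, and no ectopic
pairs (≥ 2 consecutive) or runs (≥ 3).  The ectopic-density window is a
sliding 1-h window anchored at beat times, evaluated at every ectopic
beat — stricter and better-defined than clock-hour bins.  Pairing for the
Poincaré plot is chain-breaking: a pair is emitted only for two adjacent
sinus beats, so no pair spans a removed beat (standard NN-interval
practice).

## Cohort statistics

- Median and IQR with linear-interpolation ("type 7") quantiles.
- Girls-vs-boys comparisons: two-sided Mann–Whitney U, normal approximation
  with tie and continuity corrections (an exact-enumeration mode exists for
  small samples); two identical constant samples give p = 1 by convention.
- Prevalence vs a 50 % null: exact two-sided binomial test (sum of outcome
  probabilities not exceeding that of the observed count).
- Sex differences in prevalence: Fisher's exact test; the probability-mass
  two-sided p is the default report and the smaller directional one-sided p
  is also carried, because published tables sometimes print the one-sided
  value.
- Age associations: Spearman rho on average ranks (tie-aware), with
  SE = √((1 − rho²)/(n − 2)) and a two-sided p from
  t = rho·√((n − 2)/(1 − rho²)) on n − 2 degrees of freedom.
- Percentages are rounded half away from zero to one decimal; α = 0.05
  two-sided; no multiple-testing correction (none is standard for this
  descriptive design).

The scipy implementations stand behind the Mann–Whitney, binomial, Fisher
and rank computations; the SE formula, conventions, and table assembly are
this package's.  Tests cross-check the scipy-backed operations against
independent enumeration oracles.

## Synthetic cohort generator

No public pediatric 24-h RR dataset accompanies this problem, so the
package ships a generator whose **defaults are calibrated once and frozen**
to reproduce the reference cohort statistics of healthy children
(asymmetry medians C1d ≈ 0.56, C2d ≈ 0.48, CTd ≈ 0.48, Nd ≈ 0.42;
phenotype prevalences ≳ 88 %; Spearman rho(age, SD2d) ≈ 0.3–0.5) at
realistic dispersion magnitudes (SD1 ≈ 38 ms, SD2 ≈ 200 ms).  The
mechanism is phenomenological — chosen as the simplest superposition that
produces all four asymmetry signs simultaneously — not an autonomic model.

Per recording (defaults in parentheses):

- **Circadian baseline**: cosine with amplitude 120 ms peaking at 02:00,
  plus 6 random-phase ultradian sinusoids (periods 0.4–4 h, combined
  amplitude budget 140 ms).  Label-neutral long-term variance.
- **Asymmetric respiratory sawtooth**: 6-beat cycles that rise for 2 beats
  and fall for 4, total rise 110 ms, per-cycle lognormal amplitude jitter
  (σ = 0.3).  Rises are half as frequent but twice as large as falls, so
  decelerations are rarer (Nd < 0.5) yet carry more squared step size
  (C1d > 0.5).
- **Orientation mixing**: each cycle is mirrored (4 small rises, 2 large
  falls) with probability clip(0.07 + 0.24·(e − 1)), where e is the
  standardised squared deviation of the slow baseline at the cycle start.
  Mirrored (deceleration-majority) cycles therefore concentrate where
  |ℓ − ℓ̄| is large, lifting C2d above the raw deceleration count fraction
  without materially changing overall counts.  This knob exists because a
  pure sawtooth-plus-noise construction pins C1d ≈ 1 − Nd, whereas the
  reference values require C2d (0.48) well above Nd (0.42).
- **Jitter with bursts**: white Gaussian beat noise (σ = 12 ms) that with
  probability 0.035 per beat is replaced by a heavy component
  (σ = 110 ms; sighs, movement).  Bursts add label-symmetric short-term
  variance, pulling C1d toward 0.5 while leaving counts almost unchanged —
  the second decoupling knob, letting C1d sit below 1 − Nd.
- **Activity transients** (4/h): linear RR drop of 120 ms over ~20 beats,
  exponential recovery over ~200 beats; spans are specified in beats of a
  650-ms heart and rescaled so an event occupies the same clock time at any
  mean RR.
- **Ectopics and artifacts** (cohort defaults 1/h and 2·10⁻⁵): beat
  replacements placed on a sparse grid so they never form pairs or runs; an
  ectopic shortens its RR (×0.55) and lengthens the next (×1.30).
- The series mean is pinned to `mean_rr_ms` over the nominal 24-h span, so
  a 24-h recording at the 650 ms default has ≈ 133 000 beats and the
  asymmetry ratios are scale-free.  The RR floor is relative (0.25× the
  subject's mean RR): a fixed absolute floor would truncate the RR
  distribution more for fast-heart-rate subjects and leak a spurious
  mean-RR dependence into SD2.

**Cohort structure** (96 subjects, 50 girls, master seed 42): ages from a
Beta(2.23, 1) shape over 3–18 y (median ≈ 14, adolescent-skewed); slow
amplitudes scale with age by +3.5 %/y around age 12 (inducing the positive
age correlation of SD2d/SD2a/SDNNd/SDNNa, rho ≈ 0.3–0.5, with no built-in
age trend in the short-term descriptors); boys' respiratory amplitude is
boosted ×1.08, expressing short-term asymmetry slightly more strongly in
boys; per-subject lognormal variation on slow amplitude (σ = 0.22),
RSA-and-jitter scale (σ = 0.25), asymmetry ratio (σ = 0.08), burst rate
(σ = 1.0), plus Gaussian spread of the mirror probability (σ = 0.02) and of
mean RR (σ = 30 ms around 650).  Mean RR is deliberately **independent of
age** so that the documented age coefficient is the only built-in age
channel; the real pediatric decline of heart rate with age is therefore
not emulated (see limitations).  Per-subject seeds derive from the master
seed; identical configurations are byte-identical.

Calibration was performed once over these defaults by matching the cohort
medians and prevalences, then frozen; `calibration_report` recomputes the
comparison at run time.  With the shipped defaults, cohort medians land
within ±0.01 of the reference C1d/C2d/CTd and within ±0.01 of Nd's 0.42
reference, stable to ≈ ±0.003 across master seeds.

### What the generator does and does not show

Passing tests on this cohort demonstrate that the pipeline recovers known
population statistics from raw beat series under realistic volumes
(~10⁵ beats/subject), QC contamination, and inter-subject spread.  They do
not validate the generator as physiology: it contains no respiration or
baroreflex dynamics, its ties/quantisation differ from 1000-Hz Holter
exports (RR values are continuous), its girls/boys difference is injected
rather than emergent, per-subject phenotype prevalences run a few percent
above the reference values (spreads are mildly narrower than clinical
IQRs), and C2d acquires a weak negative age trend through the interaction
of age-scaled amplitudes with the RR floor.

## Numerical notes

- Descriptor computation is a single vectorized pass; equality with a naive
  per-point loop is tested to 1e−12 relative.
- Undefined-ratio propagation, strict-inequality phenotype boundaries, and
  the label-swap antisymmetry ((x,y) → (y,x) maps C1d → 1 − C1d and swaps
  nd ↔ na) are covered by property tests.
- The three report tables are pure functions of the per-subject record set,
  so regenerating them from the saved descriptor CSV reproduces the direct
  pipeline output (ratios are stored at 4 decimals; agreement to that
  precision).
- Problem sizes in the shipped tests: 1000 random series of length
  10–5000 for the identity suite, 1000 series of length 10–200 for the
  loop-oracle comparison, and the full 96 × ~1.3·10⁵-beat cohort analysed
  once per session; the whole suite runs in well under a minute.

## Known limitations

- The generator's mechanisms are statistical stand-ins; parameter values
  are calibration artifacts, not physiological estimates.
- Mean RR does not fall with age in the synthetic cohort (see above).
- Fisher's test sidedness conventions differ across published software;
  both values are reported.
- Frequency-domain HRV, entropy, DFA, heart-rate turbulence, windowed HRA,
  and ECG-level beat detection are out of scope; analysis starts from
  annotated RR text files.
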