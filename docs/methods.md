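# Methods

## Assay timeline model

The VAMR assay is modeled as a fixed sequence of half-open windows in
whole seconds, 0-based from assay start; a stimulus "response" is the
activity in the single second beginning at stimulus onset.  The default
geometry: 1260 s dark acclimation (BSL1–4 occupy seconds 0–1200; the
trailing minute, 1200–1260, is a declared unassigned buffer so BSL1
stays anchored at the transfer-related activity peak near assay start),
600 s light (VSR1 = second 1260, VMR1 = 1261–1860), 1200 s dark
(VSR2 = second 1860, VMR2 = 1861–2160, VMR3–5 = three 300-s intervals),
then three acoustic-stimulus blocks of five 1-s stimuli at a 60-s
onset-to-onset period (ASR1 low-volume, ASR2/ASR3 high-volume; the four
59-s gaps inside each block pool into ISI1–3), separated by
inter-endpoint intervals of 60, 60 and 180 s, with five 60-s habituation
bouts between IEI2 and IEI3 (30 high-volume stimuli per bout at a 2-s
period — 1-s stimulus, 1-s gap — with four 60-s inter-bout intervals).
Total length 4623 s.  Two phrasings of the bout structure circulate
("stimuli at 1-s intervals" vs "1-s stimulus with a 1-s gap"); the
package adopts the explicit second reading, giving the 2-s period.

Windows are laid out cursor-wise, so overlap is impossible by
construction; the tiling identity (windows + buffers cover every second
exactly once) is still verified and violations raise an error naming
the first conflicting window.  Masked activity bins must be explicit
(NaN); they are excluded from window means with counts reported, and an
all-masked window yields a missing value, never zero.  Silent gaps in
input files are an error.

## Endpoint metrics

Interval endpoints are mean activity per second over their windows;
ASR1–3 average the five stimulus-second responses of their block.  The
three ratio metrics share a "late / (early + late)" convention, so each
is 0.5 under exact symmetry, 0 under complete habituation, and lives in
[0, 1]:

* **ASH1** — within-bout habituation of the first bout: sum of the last
  10 stimulus responses over the combined sum of the first and last 10.
  This normalizes away individual baseline startle amplitude.  An
  alternative convention (mean of the last 10 over the mean of the
  combined set, exactly twice the fraction) is exposed as a switch for
  sensitivity analysis.
* **ASH1/5** — potentiation of habituation: whole-window activity total
  of bout 5 over the summed totals of bouts 1 and 5.  Note the
  deliberate distinction: ASH1 uses stimulus seconds only, ASH1/5 uses
  whole bout windows.
* **ASR2/3** — memory retention: ASR3 mean over the sum of ASR2 and
  ASR3 means.  The alternative reading (ASR3 over the arithmetic mean
  of the two) differs only by a factor of 2 and was not adopted.

ASHsum is total activity over all five bout windows (stimulus and gap
seconds); IBI is mean activity per second over the four inter-bout
gaps.  A 0/0 ratio is recorded as missing and excluded from statistics
with an audit count — never coerced to 0 or 0.5.

## Bootstrap testing

The pooled two-sample bootstrap treats each group as a multiset
(inputs are canonically sorted, so within-group ordering can never
affect a seeded result).  `T_obs = |median(A) − median(B)|`; each of
`B` resamples draws `n_A + n_B` values with replacement from the pooled
data and splits them by the original group sizes; `p = #{T* ≥ T_obs}/B`
floored at `1/B`, so reported p-values are strictly positive and the
smallest reportable value is `1/B` (a `(count+1)/(B+1)` variant is
available behind a flag).  Medians of even-sized samples are the mean
of the two central order statistics.  An alternative location-shift
bootstrap (per-group resampling, statistic centered at the observed
difference) is selectable; the pooled form is the default.  All
endpoint × comparison tests of a run form a single BH family — the most
conservative plate-level reading — and per-test generators derive
deterministically from the master seed and the (endpoint, comparison)
labels, so serial and parallel execution agree.

**Known property — conservatism.**  Bootstrap sampling distributions of
sample quantiles converge slowly (order n^(−1/4)), so the resampled
null of a median difference is wider than the true sampling
distribution at n ≈ 45 per group.  Measured on iid normal groups, the
pooled test rejects at ≈0.03 at a nominal α = 0.05 (the location-shift
variant at ≈0.037); under the full synthetic global null the battery
rejects at ≈0.02–0.04.  The test is therefore valid but conservative:
its type-I error stays below the nominal level, and its power against a
fixed standardized shift is correspondingly below that of a mean-based
test (asymptotic efficiency 2/π at the normal).  Consumers comparing a
1-pooled-SD effect against a BH family of 125 tests should expect
adjusted-detection rates around 20–30 %, not the ≈90 % a mean test
would give; raw-p detection at α = 0.05 is ≈90 %.

Percentile CIs for medians use a separate resample count (default
1,000) and the 2.5th/97.5th percentiles of resample medians; per-1-s-bin
median bands resample wells jointly across bins so the band is coherent
along the trace.

## Metaproteomic statistics

Community shares divide each species' summed protein intensity by the
per-sample total over species-assigned proteins; "unassigned" rows are
excluded from the denominator with their mass fraction logged.  Phase
comparisons first average samples to one mean per (bioreactor, phase) —
the experimental unit — then apply the tie-corrected Kruskal–Wallis
test across phases and Dunn's post-hoc z tests
(`z = (R̄_i − R̄_j)/√[(N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/n_i + 1/n_j)]`,
two-sided normal p), BH-adjusted within each species' family of phase
pairs.  Dunn's test is implemented in-package (standard tie-corrected
formula) and pinned by a hand-computed no-ties fixture.

Pathway aggregation sums the intensities of all protein groups whose KO
belongs to a pathway; a KO in several pathways counts fully toward each
(no splitting; configurable upstream by editing the map).  Coverage is
|detected KOs ∩ pathway KOs| / |pathway KOs| — the KO-count denominator
was chosen over a protein-count denominator, as coverage of the
functional repertoire is what the filter is meant to guarantee.
Pathways need ≥15 % coverage and ≥5 distinct proteins; both filters are
monotone (relaxing them never drops a retained pathway) and exclusions
are reported with the failing filter.  Fold changes compare mean
*relative* pathway intensity (pathway / total KO-assigned intensity per
sample) between phases: `Log2FC = log2(mean_B/mean_A)`, retained iff
|Log2FC| ≥ 0.2 and KW p < 0.05; a zero phase mean yields a flagged
missing fold change, never ±∞.  Relative (not absolute) intensities
were chosen because the ordination operates on pathway relative
abundances.

PERMANOVA uses the one-way decomposition on squared Bray–Curtis
dissimilarities, `SS_total = Σ_{i<j} d²_ij/N`,
`SS_within = Σ_g Σ_{i<j∈g} d²_ij/n_g`, with label-permutation p-values
`(count+1)/(n_perm+1)`; pairwise comparisons are Hochberg-adjusted
(step-up family-wise control), matching the convention that BH is used
everywhere else.  PCA is column-centered SVD with a deterministic sign
convention (largest-magnitude loading positive per component).
Linear mixed-effects time-course comparisons are deliberately not
re-implemented; the pipeline exposes tidy per-phase tables for any
standard mixed-model library.

## Dose arithmetic

`daily mass = ADI × fraction × body weight`, spread over one daily
medium-exchange volume: 0.2 mg/kg/day × 0.10 × 70 kg / 250 ml =
0.0056 mg/ml.  Since mg/ml ≡ g/l, molarity is `0.0056 / 403.4 × 10⁶` =
13.88 µM, truncated to one decimal (13.8 µM) for reporting, matching
the design convention.  The design enumerators encode 2 colonization
statuses × 3 exposure groups × 10 flasks = 60 flasks and 8 strains ×
10⁹ cells = 8×10⁹ inoculum cells.

## Synthetic data

The behavior generator emulates the stereotyped larval phenotypes on
top of the schedule: dark baseline 10 activity units/s, light baseline
5 (larvae are less active under light), a dark-transition surge of
amplitude 40 decaying exponentially with τ = 150 s (so VMR2 captures
the surge and VMR3–5 the return to baseline), visual startle amplitude
60, acoustic startle amplitudes 30 (low volume) and 60 (high volume),
and within-bout responses `60 × 0.93^(a·(i−1))` for stimulus i — the
geometric decay reaches ≈12 % of the initial response by stimulus 30,
and the group-level habituation-acceleration factor `a` multiplies the
decay *exponent* (a pure amplitude factor would not accelerate
habituation).  Group-level hyperactivity multiplies the dark-surge
amplitude.  Per-bin noise is Gaussian (sd 5) truncated at zero, since
activity is non-negative — a documented deviation from a pure Gaussian
that slightly biases means upward in low-activity windows.  Each well
carries a lognormal activity multiplier (σ = 0.3), reflecting the large
between-individual variability of larval locomotion; without it the
endpoint-level dispersion would be implausibly tight.  Defaults are 45
wells per group across the six colonization × exposure groups, assigned
cyclically to 10 flasks per group.

The proteome generator draws per-species protein weights from a
Dirichlet, then sets each intensity to `total × species share ×
protein weight × phase-species effect × pathway-phase fold ×
bioreactor-species effect × lognormal noise` (σ = 0.25 measurement
noise, σ = 0.1 bioreactor effects), over 4 bioreactors sampled daily
through a 3-day stabilization, 7-day exposure and 4-day recovery.  The
synthetic KO/pathway map assigns KOs round-robin across species and
pads each pathway with undetected KOs to a configurable coverage
fraction.  Ground truth (expected shares after renormalization,
injected folds) is emitted as a separate record; tests never
reverse-engineer it from the data.

What the generators do *not* emulate: burst/bout swim kinematics,
circadian drift, plate-edge effects, mass-spectrometry missingness and
dynamic-range compression, or shared peptides between species
(species assignment is assumed pre-resolved; ambiguous mass goes to an
"unassigned" label).  Passing tests therefore demonstrate correctness
of the segmentation, metrics and statistics under controlled inputs,
not robustness to those real-data artifacts.

## Numerical and scale choices

Simulation-based checks run at the study's scale (45 wells/group, six
groups; 4 or 7 bioreactor samples per phase) with resample counts
scaled to the check: B = 500 for null-calibration sweeps, B = 5,000 for
adjusted-detection runs (with a 125-test BH family the 1/B raw-p floor
must satisfy 125/B < 0.05, so B ≥ 2,500 is structurally required),
B = 10,000 where a single test is compared against an exhaustive
oracle.  Community shares sum to 1 within 1e-9; zero-noise round trips
are exact to 1e-12.  Degenerate inputs are defined, not special-cased:
constant data give degenerate CIs, a constant matrix ordinates to zero
scores and zero explained variance, identical groups give H = 0 and
p = 1.

## Known limitations

* The bootstrap median test's conservatism (above) is inherent to the
  resampling scheme, not configurable away; if nominal type-I error is
  required, a permutation test on medians would be the replacement.
* The exact BH family of the original analysis workflow is not
  recoverable from its description; the plate-level family implemented
  here is the most conservative reading and is configurable.
* PERMANOVA assumes exchangeability of samples under the null; daily
  samples from the same bioreactor are pseudo-replicated in the global
  test, which is why the phase statistics for species shares operate on
  per-bioreactor means instead.
* The dose arithmetic takes the daily medium-exchange volume as the
  dilution volume; dosing regimes with other exchange rates need the
  volume argument adjusted accordingly.
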