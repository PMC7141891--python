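# Methods

## The estimator and its conventions

The inferred concentration of taxon *t* in a sample is

    IC_t = RA_t × TBL

with RA_t the taxon's relative abundance as a **fraction** and TBL the
total bacterial load from broad-range 16S qPCR in gene copies per swab.
Relative abundance is a fraction everywhere inside the package; percent
appears only at I/O boundaries (long-format readers accept a `percent`
column and divide by 100). This single internal convention is what makes
the conservation identity Σ_t IC_t = TBL hold exactly, and avoids silent
100× unit errors.

All error analyses run on a log10 scale, which requires finite mappings
for zeros:

| quantity | zero maps to | rationale |
|---|---|---|
| relative abundance | 1/depth | the smallest fraction one read could represent |
| inferred concentration | 1 copy/swab (log10 = 0) | a fixed floor below any plausible assay signal |
| targeted qPCR | floored at the detection threshold (93.8 copies/swab) | censored values are only known to be at/below it |

A mapped IC of 1 copy/swab is indistinguishable from a genuine
measurement of exactly 1 copy, so an explicit `ic_was_zero` flag travels
with every record; call classification and transition classes use the
flag (equivalently, the raw values), never the mapped ones. The
targeted-assay limits of quantification (2.5 copies/swab; 10 for the
broad-range assay) are carried as metadata only — every analysis uses the
single reporting threshold of 93.8 copies/swab, configurable.

Times are stored in hours; day-indexed inputs are converted on read
(rate windows are specified in hours).

## Error statistics

* **IC error** = log10(AC floored) − log10(IC mapped). Positive =
  underestimation by the inference.
* **Calls** from the raw values: false positive (IC > 0, AC ≤ threshold),
  false negative (IC = 0, AC > threshold), double negative (both
  negative), true positive otherwise. The four classes partition every
  record.
* **Large-error attribution**: among records with |IC error| > 0.5 log10,
  the share per relative-abundance bin. Bins are half-open — [0, 1%),
  [1%, 10%), [10%, 100%]. The absolute value is used for "large" (a
  symmetric criterion; overestimates count like underestimates). Both the
  including- and excluding-double-negative variants are always reported,
  because the two answer different questions (is the error driven by
  joint non-detection, or by genuine quantitative disagreement?).
* **Total-load underestimates**: a sample is flagged when TBL is
  *strictly* below the sum of the targeted-qPCR species concentrations.
  Both a per-sample and a per-record percentage are reported, since
  either denominator is defensible.
* **Rates**: between consecutive samples 18–36 h apart,
  rate = Δlog10 / (Δt/24) in log10 per day, computed on the mapped
  values for AC, IC and RA; rIC error = rate(AC) − rate(IC). When
  irregular sampling puts several future samples inside the window, the
  one nearest 24 h is paired and the walk continues from it — one pair
  per step, no overlapping pairs. Transition classes (double positive /
  single positive / double negative) come from the IC-zero flags of the
  two endpoints. The sign-error rate counts strictly opposite signs
  only; a zero rate is never "opposite" (quadrant membership excludes
  the axes). Variants with and without single-positive transitions are
  both emitted, since single positives are the dominant and qualitatively
  distinct failure mode.

## Noise decomposition

Each per-participant, per-assay log10 series is split by a discrete-
Fourier low-pass filter: with *n* grid points, the zero-frequency bin and
all bins with frequency index j ≤ floor(fraction × n/2) are kept as
signal (default fraction 0.25, i.e. a cutoff at a quarter of the Nyquist
frequency); the residual is noise. Retaining DC makes every regular
series' noise mean exactly zero, and Parseval's identity splits the
variance: Var(data) = Var(signal) + Var(noise).

The DFT needs regular sampling. Series whose steps deviate from the
median interval by more than 1% are linearly interpolated in log10 space
onto the median-step grid, and grid points further than a quarter step
from any real sample are masked out of all noise summaries, so
interpolation cannot manufacture zero-noise points. No detrending or
tapering is applied before the transform. Censored (at-threshold) values
enter the filter at the threshold, flagged; a toggle drops series that
are majority-censored.

Two variance summaries are reported. `noise_variance` is the plain
pooled variance of the residuals — the quantity a noise-floor summary
plot shows. For *parameter recovery* it is biased: an iid noise
component spreads its power uniformly over frequency bins, and the
residual band only contains the removed share of them (≈ 75–78% at the
25% setting), so the residual variance systematically underestimates the
full iid noise variance. `noise_variance_corrected` divides by the
removed-bin fraction and is the unbiased estimator of an iid noise
variance; the acceptance checks of noise recovery use it.

## Statistics

* Pearson r with two-sided p from the t distribution (n−2 df); undefined
  (raised) for zero-variance input. Pooled correlations run on the
  mapped log values, mapped zeros included — a flag supports excluding
  double negatives as a sensitivity analysis.
* **Hittner test** for two overlapping dependent correlations r(1,2) vs
  r(1,3): Dunn & Clark's z with the dependence term evaluated at the
  back-transformed average of the two Fisher transforms, two-sided normal
  p. This is the only dependent-correlation test exposed. When the
  triple is nearly collinear the asymptotic variance degenerates
  (2 − 2c ≤ 0); the statistic is then reported as NaN (or 0 when the two
  correlations are exactly equal) rather than a spurious number.
* **Breusch–Pagan**: OLS of y on X, then the squared residuals on the
  same design; LM = n·R² of the auxiliary regression (the studentized /
  Koenker form, the default because it does not assume Gaussian errors),
  p from χ² with k df. The original ESS/2 form on normalised squared
  residuals is available behind a flag. Under homoskedastic Gaussian
  simulation the studentized test is calibrated: rejection at α = 0.05
  lands within 2 points of nominal over 2,000 replicates (n = 150).
* t tests: paired, Welch, and one-sided Welch (or one-sample vs 0).
* Per-species regressions report intercept and slope of
  log10 IC ~ log10 AC.

## Clustering comparison

Samples are clustered by complete-linkage agglomeration on Euclidean
distances between their per-species log10 vectors (as mapped by the
inference conventions). Distance ties follow scipy's deterministic pair
ordering. Leaf order — which the merge tree alone does not fix — uses a
fixed seriation rule: at every merge the subtree containing the
lexicographically smallest label is drawn on the left.

The entanglement coefficient between two trees over the same samples:
rank each shared label by its position in each tree's leaf order, take
the Euclidean distance between the two rank vectors, and divide by the
distance obtained when one order exactly reverses the other. No
untangling/rotation optimisation is applied by default (a greedy
single-pass rotation search exists behind a flag for sensitivity).
The number of clusters is chosen by maximising the mean silhouette width
over tree cuts k = 2…8 — deliberately a single-index selector, labelled
as such in reports, not a multi-index majority vote.

## Synthetic cohort generator

The generator produces the study conditions the validation assumes, with
full ground truth:

* **Design**: 20 participants, 60 days of daily samples with ±2 h jitter,
  7 focal species with targeted assays (the vaginal panel: *L. crispatus*,
  *L. iners*, *L. jensenii*, *G. vaginalis*, *A. vaginae*, BVAB2,
  *Megasphaera*) plus 13 background taxa seen only by sequencing.
* **Latent dynamics**: per-(participant, taxon) log10 trajectories follow
  a mean-reverting random walk (baseline uniform on 1–7.5 log10,
  reversion 0.08/day, innovation sd 0.25 log10/√day) with Poisson
  bloom/decay ramp events (0.015/taxon/day, 3–6.5 log10 over 3–10 days).
  These rates were set once so that single species traverse many log10
  within a participant and total load several log10, the dynamic range a
  fluctuating low/high-diversity niche exhibits. A quarter of
  participants undergo an antibiotic window (days 0–7) forcing ≥ 0.8
  log10/day decline of the BV-associated taxa. Latent total load is the
  exact taxon sum, so conservation and perfect-recovery identities can be
  checked against truth.
* **Sequencing observation**: depth lognormal (median 23,304 reads,
  ln-sd 0.5), counts multinomial with probabilities = latent fractions.
  An `exact_fractions` switch records the latent fractions directly —
  the infinite-depth limit.
* **qPCR observation**: measured log10 = latent log10 + N(0, σ_q),
  independently per assay and for total load (σ_q = 0.3 log10 by
  default), so measured TBL can legitimately fall below the measured
  species sum. Values at/below the 93.8 copies/swab threshold are stored
  at the threshold and flagged; `censor=False` disables this.
* **Determinism**: truth, sequencing and qPCR observations draw from
  three separate seed-derived streams, so identical config + seed gives
  bit-identical tables, and changing only an observation parameter leaves
  the latent truth unchanged (useful for controlled degradation grids).

What the generator does **not** emulate: species interactions (no
Lotka–Volterra coupling), behavioural/menstrual covariates, PCR
amplification bias, chimeras or classification error in sequencing, and
day-to-day autocorrelation of measurement error. Passing tests therefore
demonstrate the correctness and calibration of the analysis machinery
under the stated statistical assumptions — not that real assays satisfy
those assumptions. In particular the generator's random-walk latent makes
day-scale rate analyses noisier than a smoother biological reality would
be, so its rate-correlation summaries are conservative.

## Numerical choices and degenerate inputs

* Conservation (Σ IC = TBL) is exact in the algebraic sense; tests assert
  it to a relative 1e−12, the honest meaning of "exact" after float
  summation.
* The perfect-recovery limit (σ_q = 0, exact fractions, censoring off)
  sets the analysis detection threshold effectively to zero as well: with
  no censoring in the data, keeping the default threshold would
  re-introduce flooring artifacts the limit is meant to exclude.
* Joins require a unique partner within the tolerance (default ±1 h);
  two candidates raise rather than guess. Unmatched rows are reported
  and logged, never dropped silently.
* Empty attribution (no error above the cutoff) returns an empty result
  with a warning; empty noise summaries and zero-variance correlations
  raise.
* p-values below 2.2e−16 are stored as floats but printed as bounds in
  human-readable reports.

## Problem sizes

The default synthetic cohort (20 × 60 samples, 7 assayed species →
8,400 species-sample records) runs the full pipeline in a few seconds.
The clustering stage thins to at most 400 samples by deterministic
striding — complete linkage is O(n²) in memory and the comparison is
about leaf order, which thinning preserves in distribution. Calibration
checks use 2,000 replicates (Breusch–Pagan) and 20 × 60-point series
(noise recovery); degradation grids use 10 participants × 40 days per
cell. All sizes are package defaults chosen to make the checks sharp at
interactive runtimes.
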