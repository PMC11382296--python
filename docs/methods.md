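# Methods

## Minute-level pipeline

Heart rate arrives as 5-second samples, steps as per-minute counts.
Samples are assigned to calendar minutes by floor-truncation of the
timestamp and averaged arithmetically; a minute must hold at least
`min_hr_samples` samples (default 6, half the nominal twelve) to be
kept — the completeness rule is a package choice, configurable, since
devices drop samples during poor skin contact. HR and SR minutes are
joined on the timestamp (inner join: a minute must carry both signals;
treating step-less HR minutes as SR = 0 is the documented alternative
and would only add minutes the activity filter removes). Timestamps are
local wall clock throughout; the analysis uses only time-of-day and
inter-observation gaps, so no timezone handling is needed or attempted.

The activity filter keeps minutes with `sr >= 60` steps/min. The
boundary is closed on the kept side ("below 60 excluded"); the filter
threshold, both deviation bands, the intensity cuts, the bout gap, the
grouping cut and the histogram grid are all fields of `AnalysisConfig`.

**Deviation arithmetic.** The coupling deviation is computed as
`|SR − HR| / HR`, which is algebraically `|R − 1|` but avoids the float
cancellation of `sr/hr - 1`: 99 vs 100 beats/min yields a deviation of
exactly `0.01` and classifies as coupled, as the band definition
intends. Band comparisons are inclusive on the upper edge
(`<= 0.01`, `<= 0.10`).

## Exact random-pairing null

The chance level of coupling is defined per subject by pairing every
recorded HR value with every recorded SR value (N² combinations).
Rather than Monte Carlo sampling, the default implementation computes
this distribution exactly: with SR sorted once, the mass of histogram
bin `[a, b)` is `Σ_h #{sr : a·h <= sr < b·h} / N²` by binary search per
(HR value, bin edge) — O(B·N log N) for B bins — and band probabilities
use the same inclusive deviation bands as classification
(`(1 ± t)·h` cut points, closed on both sides). Quantiles invert the
exact weighted CDF by bisection (equivalent to the inverted-CDF quantile
of the enumerated multiset); skewness uses the separability of raw
moments, `E[R^k] = E[SR^k]·E[HR^−k]`, assembled into the adjusted
Fisher-Pearson estimator (the estimator choice is a package convention;
nothing downstream is sensitive to it). A seeded Monte Carlo variant
(`null_sampled`) exists for cross-checking and for workflows that want
literal draws; tests verify it converges to the exact result.

The observed-vs-null comparison uses a one-sample Kolmogorov-Smirnov
test of the observed ratios against the exact null CDF (with a sampled
null, a two-sample test against the draws). Histograms share a fixed 1%
grid on R ∈ [0.3, 3.0] with two overflow bins; edges are constructed as
exact rational multiples so round ratios sit on bin boundaries.

The null deliberately destroys *all* temporal association, including the
ordinary physiological correlation between effort and heart rate — so
in correlated data the observed distribution differs from the null even
without any entrainment. Surrogate methods that preserve
autocorrelation are out of scope; conclusions about entrainment from
this null alone inherit that caveat.

## Bouts, grouping and cohort aggregation

An activity bout is a maximal run of kept minutes with consecutive
gaps < 60 min; duration is the inclusive span (end − start + 1), so an
isolated minute is a 1-minute bout. A bout is labelled with the
strongest coupling class present in at least 20% of its minutes, falling
back to the modal class with ties resolved toward the stronger class —
no standard convention exists for labelling a bout, so the share
threshold is configurable. Cohort quantities are medians (IQR) of
per-subject values; paired contrasts (occurrence between intensities,
observed vs null band probability/IQR/skewness, bout durations by class)
use Wilcoxon signed-rank over subjects with `r = |Z|/√N` from the
continuity-corrected normal-approximation Z. The Kruskal-Wallis effect
size implements the printed formula `η² = H/(N−1)`; the variant `H/N`
is available behind a flag. The age split (default 40 years) applies
Kruskal-Wallis to per-subject median ratios. No multiple-testing
correction is applied; all p-values are raw. Resting HR is summarised
from the below-threshold minutes the activity filter discards.

## Synthetic cohort generator

The generator is a **validation scaffold with ground truth**, not a
statistical replica of any real cohort. Each subject (RNG seed
`seed + subject_index`) gets daytime activity bouts (Poisson-scheduled
between 06:00 and 23:00 with enforced spacing, durations ~N(45, 25) min
clipped to [5, 180]), a per-bout base cadence uniform in
`cadence_range`, per-minute cadence wiggle, sleep with zero steps, and
overnight charging gaps in the HR stream. Sensor error follows the
published accuracy envelope of wrist devices: steps are undercounted by
3% with small jitter and rounded to integers; HR samples carry
multiplicative zero-mean Gaussian error with σ = MAPE·√(π/2) so the
realized mean absolute percentage error equals the 11% target (verified
by a calibration test).

Entrainment is injected at the minute level: a Bernoulli
(`couple_fraction`) subset of active minutes has its underlying SR set
equal to the minute-mean HR before sensor noise. Minute-level injection
matches the pipeline's resolution; within-cardiac-cycle phase is out of
scope.

Two design choices depart from the obvious physiological model, both
forced by the requirement that the injected fraction be *recoverable*:

* **Proportional HR tracking.** During bouts the HR target is
  `cadence / R_s` (capped at 185 bpm), where `R_s ~ N(0.92, 0.012)`
  clipped to [0.89, 0.945] is a subject-level base ratio. An affine
  response `resting + k·(cadence − 60)` makes the ratio profile cross
  R = 1 inside the cadence range for low-resting-HR subjects, producing
  chance coupling that is indistinguishable from injected entrainment;
  proportional tracking keeps non-entrained minutes uniformly clear of
  the ±1% band, so with noise off the measured CLC occurrence equals
  `couple_fraction` to within a fraction of a percentage point.
* **No onset transient.** Bouts start at the cadence-determined HR
  target; the first-order response (τ ≈ 2 min) acts only within the
  bout. A warm-up ramp from resting HR would sweep the ratio through 1
  at every bout start and register as spurious coupling.

Consequences worth knowing: the generator's minute-level HR-SR coupling
is much tighter than real physiology (Pearson r ≈ 0.95 on active
minutes, versus roughly 0.3–0.8 in real wrist data), its observed ratio
IQR is correspondingly small, and its weak-band probability under
default noise (~0.5 vs null ~0.22) overstates the concentration seen in
real recordings. Passing recovery and calibration tests on this
scaffold therefore validates the *pipeline arithmetic*, not the
generator's realism; distribution-shape claims about real data must come
from real data.

A second configuration, `independent_pairing_config`, removes the
minute-level HR-SR dependence entirely (active HR = resting + boost +
noise, independent of concurrent cadence). This is the configuration
under which the random-pairing null must be exactly calibrated, and it
is what the calibration experiment uses. Its marginals are placed so
the weak∪CLC band probability is ~5% and each subject accumulates
~4,000 active minutes over two weeks: large enough that per-subject band
counts are approximately symmetric (sparser counts are right-skewed and
a signed-rank test across subjects flags the skew as a false
miscalibration), small enough that the binomial sampling error of the
band probability stays well below the 0.01 comparison tolerance.

## Validation experiments and problem sizes

`clckit.experiments` (driven by `scripts/acceptance.py` and the heavier
tests) uses 16-subject × 14-day cohorts throughout — enough minutes
(~2,000–4,000 active per subject) for band probabilities to have
sub-percent sampling error while a full 20-seed calibration sweep runs
in about three minutes on one CPU:

* **Oracle equivalence** — the exact null against literal N²
  enumeration on random instances (agreement to 1e-12).
* **Calibration** — 20 independence cohorts: per-subject
  |observed − null| band probability, cohort signed-rank tests, KS
  false-positive rate.
* **Recovery** — injected entrainment at 2/5/10% under default sensor
  noise, all fractions sharing one seed (common random numbers) so the
  dose-response is measured on identical data.
* **Test levels** — empirical type-I error of the Wilcoxon,
  Kruskal-Wallis and Friedman wrappers over 1,000 seeded null
  replicates, and signed-rank power under a one-difference-SD shift.

**Known limitation: noisy recovery attenuates.** With the default 11%
sample-level HR MAPE, the minute-mean multiplicative HR error has
σ ≥ 0.11·√(π/2)/√12 ≈ 0.04 even under the most favourable (white) noise
structure, so an entrained minute survives inside the ±1% CLC band with
probability ≈ 0.2 at best; the −3% step undercount shifts the deviation
a further 3 points, bringing measured survival to ≈ 0.14. Measured CLC
occurrence under default noise is therefore ≈ `0.14·couple_fraction +
chance` (about 1.7%/2.1%/2.9% for injected 2%/5%/10%) — monotone in the
injected fraction and overwhelmingly detected by the KS test, but a
substantial underestimate of the injected fraction itself. This is an
intrinsic property of a ±1% detection band under ~4% minute-level
measurement noise, not something a different generator or pipeline
setting can remove; any occurrence estimated from wrist-grade sensors
carries the same attenuation.

## Degenerate inputs and numerical conventions

Empty streams parse to empty frames with warnings; malformed rows are
counted and logged, never silently dropped; duplicate step minutes keep
the first record; non-integer step values are rejected rather than
rounded. A subject with no post-filter minutes yields a flagged empty
report and is excluded from cohort medians with a warning. All-zero
paired differences flag the Wilcoxon result (Z undefined); an empty
coupling class is absent from duration tables rather than zero;
(near-)constant ratio samples report zero skewness. Exact-null
quantile bisection runs to 1e-12 relative tolerance. File outputs use
stable orderings and fixed timestamp formats so identical inputs
reproduce byte-identical outputs.
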