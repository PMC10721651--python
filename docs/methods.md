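# Methods

This note documents the models, estimators and numerical choices behind
`pfcpop`, and what the synthetic-data validation does and does not show.

## Session model

A session is one recording day of one task (`strategy`, `novelmap`,
`fammap`). Trials carry a 1.0 s fixation epoch, an instruction-stimulus
(IS) period whose duration is drawn from {1, 1.5, 2} s, and a go signal at
IS offset. Spike times are stored on a single canonical clock per trial
(seconds from fixation onset); alignment to the IS onset or go signal is
computed when binning. Binning is half-open — bin b covers
[t0 + b·step, t0 + b·step + width), a spike on the right edge belongs to
the next bin — and bins that extend past a trial's recorded span (e.g. a
1.5 s analysis window on a 1 s-IS trial) are flagged invalid rather than
zero-filled. Bin timestamps are bin centers; reported latencies therefore
refer to centers (the alternative left-edge convention would shift all
latencies by half a bin width, 75 ms for the ω² geometry).

Condition-based analyses use correct, non-correction trials only.
Correction trials re-present a failed trial's conditions, so counting them
would bias condition counts toward failed associations.

## Learning-point estimation

The correctness sequence n_i ∈ {0,1} is smoothed with centered windows of
2w+1 trials (w = 2 by default; edge windows are undefined rather than
padded). The learning trial k is the center of the earliest window whose
success count m satisfies P(Binomial(2w+1, p_null) ≥ m) < α, with
p_null = 0.45 and α = 0.05 — which forces m = 5, an all-correct window. A
sentinel is returned when no window qualifies, or when α < p_null^(2w+1)
makes the criterion unattainable. By construction the estimate lags a true
step change by 0–4 trials (the window must fill with correct trials);
the validation asserts exactly that band, not lag zero.

Sessions are estimated at session level by default (one k per session, on
the concatenated correctness in session order); a per-association mode
returns one k per association. Learning/post-learning blocks split at k,
with trial k in the learning block. Performance curves across sessions use
Wilson 95% intervals, which behave sanely at proportions near 0 and 1.

## Waveform classification

Mean waveforms (25 µs sampling) are cleaned by removing any spike whose
voltage exceeds 3 SD of the initial average at any sample, then QC'd:
traces whose main trough is smaller than the following peak, or whose
preceding peak exceeds 1.2× the trough, are excluded as putative axonal
signals. Surviving traces are cubic-spline interpolated tenfold (to
2.5 µs), normalized to a −1 trough, and the trough-to-peak duration is the
trough-to-argmax distance. A maximum at the trace end is flagged.

Bimodality of the pooled duration distribution is tested with the Hartigan
dip statistic, implemented in `pfcpop._dip` via the iterative greatest-
convex-minorant / least-concave-majorant algorithm. The implementation is
validated against an exact linear-programming oracle (minimal sup-norm
band admitting a monotone convex-then-concave fit, allowing the jump at
the mode that a unimodal distribution function may have) at small n, and
against analytic anchors (equally spaced points give exactly 1/(2n)).
P-values are Monte-Carlo (add-one convention): the *original* test draws
uniform samples of the same size; the *calibrated* variant draws from the
best-fitting single Gaussian (MLE mean/SD), a sharper reference when the
null of interest is a bell-shaped unimodal density rather than a flat one.
The uniform-reference test is the default everywhere.

Gaussian mixtures with 1 and 2 components are fitted by EM
(scikit-learn, 5 restarts, tol 1e−6) and compared by both AIC and BIC.
The narrow component is the smaller-mean component by definition. Cutoffs
are searched on a 1 µs grid over the data range: the low cutoff is the
largest duration with narrow:broad posterior odds ≥ 10, the high cutoff
the smallest with broad:narrow odds ≥ 10; durations between them stay
unclassified (NC). Labels are invariant to affine amplitude rescaling and
to common shifts of durations and cutoffs. The manual curation of real
datasets is modeled as an input boolean per unit, not re-implemented.

Baseline firing metrics use the fixation epoch (0–1 s) over completed
trials (≥ 30 by default): rate = total spikes / total time; Fano factor
from across-trial counts with sample variance (ddof = 1); CV from ISIs
pooled within trials only — trials are non-contiguous recordings, so
across-trial intervals are meaningless. Both are ≈ 1 for Poisson firing;
the generator's gamma-renewal option (shape k gives CV ≈ 1/√k) makes the
regular-firing case testable.

## Omega-squared selectivity

For a 3-level variable, ω² = (SS_between − df·MSE)/(SS_total + MSE) with
df = G − 1. The within-group mean square MSE is the within-group sum of
squares divided by (N − G); a `strict_printed` mode exposes the raw
within-group sum of squares in its place for comparison, but that variant
is not a variance fraction and is not used in any analysis. Raw values can
be negative and are kept in averages (clipping would bias population means
upward); degenerate all-equal data return 0.

Unequal condition counts bias ω², so every condition is subsampled without
replacement to the smallest count; the estimate is the mean over 50
subsample draws (one index set per draw, reused across time bins). Time
courses use 150 ms bins stepped by 15 ms. The label-shuffle null permutes
condition labels independently within each unit, once per iteration,
shared across bins — preserving each unit's temporal autocorrelation.
Population onset latency is the first bin center at/after IS onset whose
population-mean ω² beats the pointwise 99.9th null percentile; per-cell
latencies use each cell's own shuffle null, and latency distributions are
compared by Kruskal–Wallis.

Epoch analyses carry two slightly different boundary conventions, kept
verbatim as named configs: selective-cell histograms use early 50–450 ms /
late 500–900 ms; the task-related filter uses early 50–400 ms / late
400–900 ms (Kruskal–Wallis of per-trial baseline vs epoch rates, keep if
either p < 0.05). Rate matching removes the highest-rate unit until the
population mean reaches 2.5 ± 0.2 sp/s; the ≤ 0.5 Hz exclusion is a
separate flag.

## Cross-temporal decoding

Spike counts in 50 ms bins over the IS period (20 bins for 1 s) feed a
maximum-correlation classifier. Per cross-validation fold, each unit is
z-scored with the mean/SD of the training pseudotrials (all conditions
pooled, computed at the *training* bin and applied to both training and
test vectors — no test-set leakage); condition templates are the mean
z-scored training vectors; the prediction is the template with the highest
Pearson correlation across units. Zero-SD units are dropped from the fold;
a test vector that z-scores to a constant has no defined correlation and
receives a seeded uniform prediction; exact score ties are broken by
seeded jitter (±1e−9, far below any meaningful score difference).

Ten trials per condition per unit are drawn independently per unit
(pseudo-population construction, since units come from different
sessions), split 9/1 over ten leave-one-out folds; the whole procedure is
repeated over runs that resample trials and units, and accuracies are
averaged over folds then runs. Chance is 1/G = 1/3. The null stack
repeats the identical pipeline with condition labels permuted within each
unit, one permutation per iteration. Min–max normalization of the matrix
is display-only; statistics always use raw accuracies.

The accuracy estimator's sampling noise is binomial: each (train, test)
bin pair pools runs × folds × conditions predictions, so e.g. 10 runs give
SD ≈ 0.027 per pair at chance. Calibration checks on maxima over all 400
bin pairs must account for this floor; the validation suite asserts
unbiasedness and that the spread sits at the floor.

## Static bins and the stability index

An off-diagonal pair (tp1, tp2) is static when (i) both accuracy drops
d = CTD(diag) − CTD(tp1,tp2) stay below the 99.9th percentile of the same
differences in the null stack, (ii) CTD(tp1,tp2) exceeds its own 99.9th
null percentile, and (iii) both on-diagonal bins are significant at
α = 0.05/B (Bonferroni over B diagonal bins; 0.0025 for 20). The raw
schematic inequality (off-diagonal < diagonal) is deliberately replaced by
this statistical form — under sampling noise a raw inequality marks
almost nothing static. The permutation p floor is 1/(iterations+1), so
the diagonal gate needs ≥ 400 null iterations to be decidable at 0.0025;
analyses here use 400–1000.

The stability index of diagonal bin k is the mean of static flags over row
k and column k (diagonal excluded); smoothing pools rows/columns k−1..k+1,
truncated at the edges (no padding). Smoothing is applied first, masking
second: bins whose diagonal is not significant are masked — an index there
would describe a representation that is not demonstrably present. Two-
population comparisons use bins significant for both populations; where a
single summary over all bins is needed (e.g. the validation's late-IS
means), masked bins contribute 0, reading "no significant coding" as "no
static coding". Bootstrap variability resamples units with replacement and
repeats the full decode + null + classification, reporting the per-bin SD
of the smoothed index.

## Cluster-based permutation statistics

Candidate clusters are maximal runs of bins whose observed statistic
exceeds the per-bin 99.9th percentile of the null; cluster mass is the sum
of the observed statistic over the run; the null max-mass distribution
clusters every null series against the same thresholds; cluster
p = (null max-masses ≥ mass)/iterations, significant at p < 0.001 by
default. With singleton clusters the procedure reduces to a pointwise
percentile test, and p-values are invariant under monotone affine
rescaling applied to observed and null alike.

Null constructions: (1) condition-label shuffles within unit, for
chance-level tests; (2) random reassignment of units to two
pseudo-populations of the original sizes, for between-cell-type ω²
differences; (3) for the stability index, whose recomputation is
expensive, units are pooled and split into size-matched pseudo-populations
n_mix times, the index difference computed per mix, and all
C(n_mix, 2) pairwise differences between mixes form the null (46 mixes →
1035 differences at full scale; the validation uses 10 → 45, where the
p-value resolution is 1/45 and cluster significance is read at α = 0.05).
Directional two-population claims are tested one-sided in each direction.
The 2×2 proportion comparison is the Pearson χ² without continuity
correction, cross-checked against `scipy.stats.chi2_contingency`.

## Synthetic sessions: what they emulate, and what not

The generator reproduces the structure the analyses rely on: task timeline
and condition labels under the three task rules (strategy sessions follow
the repeat-stay/change-shift logic, so no fixed stimulus→response mapping
exists by design); Bernoulli step learners with correction trials after
errors; two waveform classes realized as difference-of-Gaussians voltage
traces whose extrema distances equal the drawn trough-to-peak durations to
within one raw sample (bump widths shrink with the duration so narrow
spikes keep both extrema; a contamination fraction produces QC-failing
axon-like traces); and renewal-process spiking (Poisson by default, gamma
shape for regular firing) with multiplicative rate modulation of a
preferred condition — across the whole IS period (`static`), within a
sub-window (`transient`, default 0–0.5 s), or with the preference
reassigned at a switch time (`switching`, default 0.5 s). Across-unit
baseline rates follow a gamma distribution around the class mean (shape 4
by default — a free parameter, since only the class-mean rates are pinned
down by the recordings being emulated). All randomness derives from one
master seed split into named streams (waveforms, spikes, behavior,
session), so stages are independently reproducible.

Deliberately absent: biophysical membrane dynamics, spike sorting and its
failure modes, eye movements, reward-magnitude effects, cross-trial
nonstationarities (drift, adaptation) and correlated noise across units.
Passing validations therefore show that the estimators recover the truth
of this generative model — unbiased chance levels, correct cell-type
recovery, correct static/dynamic discrimination — not that real recordings
satisfy the model's independence assumptions.

## Validation scales

The validation suite and `scripts/acceptance.py` run the pipeline at desk
scale, chosen once: 1300 waveforms for classification (mixture means
0.18/0.42 ms, SDs 0.04/0.07); 200 units for the ω² null calibration with
1000-iteration nulls; 100 units / 10 runs / 100 shuffles for decoding
chance calibration; 100-unit populations at 6 sp/s baseline and effect
size 3.5 for stability recovery, with 400–500 shuffle nulls and 5-run
decodes (the diagonal significance gate requires ≥ 400 iterations, and
1-run decodes make per-mix stability indices flip under the gate's
beat-all-nulls requirement); 10 mixes / 45 differences for the mixed-
population null; 200 seeds for learning-point recovery; 1000 signal-free
series for cluster-test calibration.
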