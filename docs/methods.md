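# Methods

This note records the models, conventions and numerical choices behind
hrvkit, what the synthetic data do and do not emulate, and the known
limitations.

## Editing model

Beats are labeled N (sinus), V (ventricular ectopic), S (supraventricular
ectopic) or U (unknown). An interval between consecutive beats is retained
iff **both** endpoints are N; this single predicate implements "remove the
interval ending at an abnormal beat and the interval succeeding an ectopic"
because the interval that succeeds an ectopic starts at it. U beats are
treated like ectopics for interval validity and count as non-sinus for the
quality gate. Removals are represented as gaps via per-interval contiguity
flags; no interpolation is ever applied. The gate "> 95 % pure sinus beats"
is a strict inequality: a recording at exactly 0.95 fails (the conservative
reading of "more than").

The moving-window filter makes a **single left-to-right pass**: for every
window of five mutually contiguous intervals, the central interval is
compared with the mean of the other four, all taken from the original
(pre-pass) series, and replaced by that mean when it lies strictly outside
±20 % of it. A deviation of exactly 20 % is not an outlier (closed
acceptance interval). Windows never span a gap; runs shorter than five
intervals pass through unfiltered, as do the first/last two intervals of
each run (no full window exists for them). Single-pass comparison against
originals means a replacement can never cascade into its neighbours'
verdicts.

## Time-domain panel

All SDs are population SDs (ddof = 0); descriptive trial summaries use
sample SDs (ddof = 1), the table convention. Successive-difference
statistics (RMSSD, NNx, pNNx, Poincaré pairs) use only pairs of temporally
adjacent intervals, skipping gaps. SDANN/SDNN-index segments are 5 min,
aligned to the recording start, assigning each interval to the segment
containing its end time; a trailing partial segment participates only if it
spans ≥ 60 s. With fewer than two segments SDANN is reported missing
(never zero). The NNx threshold defaults to the standard 50 ms and is
configurable. The NN histogram for the geometric measures uses
1/128 s ≈ 7.8125 ms bins aligned to multiples of the bin width; the
triangular index is N/(modal bin count); TINN is the baseline M − N of the
least-squares triangle with apex fixed at the modal bin, found by
exhaustive search of the baseline endpoints over bin centers (one padding
bin each side lets the triangle touch zero just outside the data). A
single-occupied-bin histogram degenerates to index 1 and TINN = one bin
width.

One caution for users comparing against published tables of this kind: an
SDNN-index several times larger than SDNN is arithmetically impossible
(each segment SD is bounded by the overall spread); a table row of that
shape is almost certainly a mislabeled mean-interval (IBI) row. hrvkit
implements the definition — the mean of per-segment SDs.

## Frequency-domain panel

The unevenly sampled (end-time, interval) pairs are resampled by cubic
spline onto a uniform 4 Hz grid spanning first to last interval end; gaps
are bridged by the spline (editing already removed the abnormal data, and
the sinus gate keeps gaps rare). Recordings shorter than 120 s are
rejected — too short for 0.04 Hz resolution. The Welch estimate uses 256 s
Hann-windowed segments at 50 % overlap with per-segment linear detrending
and one-sided density scaling, so the integral of the PSD recovers the
time-domain variance (window power compensated); a pure modulation of
amplitude A carries A²/2 of band power, which the tests assert within
Welch leakage tolerance (10 %). Band powers integrate the density with a
rectangle rule on the Welch grid over VLF [0.0033, 0.04), LF [0.04, 0.15),
HF [0.15, 0.40] (HF closed above): half-open edges mean no bin is double
counted, the three bands partition total power exactly, and
nLF + nHF = 1 by construction. TP is defined as VLF + LF + HF. When HF
power is exactly zero the LF/HF ratio is reported missing, not infinite.
Resampling rate, segment length, overlap and bands are all configurable;
the defaults are the conventional short-recording choices.

## Non-linear panel

Poincaré SD1/SD2 are the population SDs of (x_{i+1} − x_i)/√2 and
(x_{i+1} + x_i)/√2 over adjacent pairs. SD1 equals RMSSD/√2 exactly when
the mean successive difference is zero (the identity the tests assert on
series constructed with equal endpoints); on arbitrary data the two differ
by the mean-difference term.

Sample entropy uses m = 2, r = 0.2 × SD and the Chebyshev template
distance, with self-matches excluded and the same template count N − m at
both lengths. A/B = 0 yields a missing value, never ±∞. The
implementation is vectorised but exactly equals the O(n²) double-loop
count, which the tests verify.

DFA integrates the mean-centered series, splits the profile into
non-overlapping boxes (tail discarded at each box size), removes a
least-squares line per box and takes F(n) as the RMS residual; α1 fits
log F over boxes of 4–11 beats, α2 over 12–64. α1 requires ≥ 100 beats,
α2 ≥ 300. A caveat worth stating plainly: over 4–11-beat boxes the
estimator has the well-known positive small-scale bias for uncorrelated
noise — the expected squared fluctuation is σ²(n² − 4)/(15n), whose local
log–log slope over that range is ≈ 0.63, not the asymptotic 0.5. White
noise therefore *measures* ≈ 0.63 by construction of the conventional
estimator (our implementation matches both a brute-force oracle and this
closed form); integrated noise measures ≈ 1.5, where no comparable bias
exists. Comparisons between recordings analysed with the same box range
are unaffected.

Sample entropy and DFA run on the concatenated interval list even across
gaps (only Poincaré/RMSSD do pair-level exclusion); after the 95 % gate,
gaps are rare enough that the effect is negligible, but this is a
documented approximation.

## Synthetic data

The generator emulates what the pipeline consumes — intervals, not ECG
waveforms. Interval i is
mean_rr + lf_amp·sin(2π·0.1·t) + hf_amp·sin(2π·0.25·t) + ε, ε ~ N(0, σ²),
with t the cumulative time of the preceding beat; cumulative times are
quantized to 1 ms (quantization applied to cumulative sums so errors do not
accumulate). Intervals below 1 ms abort generation: besides nonphysical
parameters this also traps the asymptotic stall where the interval
approaches zero without crossing it. Defaults
(mean_rr = 940 ms, lf_amp = 32 ms, hf_amp = 15 ms, σ = 25 ms, 1200 s) were
chosen once to land the metric panels in the range of an older resting
cardiac cohort — SDNN ≈ 35 ms, mean HR ≈ 64 bpm, LF/HF ≈ 1.7,
SampEn ≈ 2, α1 ≈ 1.1.

Ectopy injection relabels round(fraction × n) beats, drawn uniformly
without replacement excluding the first and last two beats (so editing
windows remain well defined), and advances each V beat by
prematurity × local RR; with a full compensatory pause (default) the next
beat stays on schedule, otherwise it advances by the same shift. Beat
count and ordering are preserved or the injection raises.

Cohorts default to 30/29/30 subjects (land/water/control) with per-arm ages
(62.4 ± 7.6, 56.7 ± 8.4, 60.6 ± 8.3 years — the water arm younger, so the
age covariate matters), subject-level log-normal heterogeneity
(σ = 0.2 on modulation amplitudes, σ = 0.05 on mean RR, shared between a
subject's pre and post recordings), and arm-level post multipliers; the
water arm defaults to lf_amp × 1.3, hf_amp × 0.8, mean_rr × 0.94 — raising
LF/HF, α1 and heart rate — with null land/control arms. All randomness
derives from a single seed via spawned per-subject streams.

What the generator does **not** emulate: 1/f broadband structure, slow
non-stationary trends, respiration variability (the HF modulation is a
fixed sinusoid), ectopy clustering, or measurement artifacts other than
isolated spikes. Passing tests therefore demonstrate correctness of the
estimators and the direction-of-effect machinery under controlled spectral
structure, not performance on messy clinical data. Long-scale α2 in
particular is low (≈ 0.3) on synthetic recordings because beyond the LF
period the modulations average out; real RR series carry 1/f structure
there.

## Trial statistics

Normality gates are Shapiro–Wilk at α = 0.05 (configurable). Within-group
changes: paired t on normal differences, Wilcoxon signed-rank otherwise;
all-zero differences give p = 1 by convention. The between-group
comparison is an OLS ANCOVA `post ~ C(arm) + age + baseline` (the same
metric's pre value as baseline), omnibus arm p from the type-II F test;
pairwise arm contrasts are Wald t-tests on the fitted model, Sidak-adjusted
with k = 3. Collinear covariates raise with a diagnostic. Missing metric
values are dropped listwise per metric with a logged count. With no
covariates the same routine is exactly a one-way ANOVA (asserted against
`scipy.stats.f_oneway`).

Operating characteristics are measured by simulation through the real
ANCOVA code path: Gaussian outcomes with a baseline correlation of 0.5,
age as an independent null covariate, and one arm shifted by a stated
number of within-group SDs. Under the null both the within-group test and
the omnibus reject at ≈ 5 %. At the classic short-trial design point
(1 SD shift, 26/arm, two-sided α = 0.05) the measured omnibus power is
≈ 0.99 — consistent with noncentral-F theory (λ ≈ 17–23 for this pattern),
and far above the 80 % such sample-size statements usually quote; a
two-sample t at d = 1 needs only ~17/group for 80 % power. Published
designs quoting 26/group at 80 % are therefore conservative (or assume a
smaller detectable pattern than "one arm shifted by 1 SD"); the simulation
reports what the procedure actually delivers.

## Problem sizes and determinism

Monte-Carlo sizes were fixed at 50 seeds for DFA limits and cohort
direction checks, 2000 replicates for power and 1000 for type-I error —
enough for ±1–2 % precision on the reported rates while keeping the whole
suite and the acceptance script within a few minutes on one core. All
stochastic tests are seeded; identical seeds give bit-identical series,
cohorts and manifests.
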