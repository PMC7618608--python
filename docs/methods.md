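# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of the `rhythm_ioi` package.

## Data model

An *element* is a half-open interval `[onset, offset)` in seconds with a
class label, an individual and a recording identifier. Elements are grouped
into *bouts*: maximal runs whose inter-element silences (next onset minus
current offset) are strictly below a silence threshold — 250 ms for
budgerigar material, 500 ms for human material, configurable. A gap exactly
equal to the threshold splits; the tie rule is a package convention, as is
the offset-to-onset gap definition (an onset-to-onset mode exists for
cross-checks). Inter-onset intervals (IOIs) and their ratios are defined
only within bouts; a bout of *n* elements yields `max(0, n−1)` IOIs and
`max(0, n−2)` ratios.

The revised IOI-ratio `r_k = IOI_k / (IOI_k + IOI_{k−1})` describes each
interval relative to its predecessor; the legacy descriptor of earlier
studies is its mirror `1 − r_k` and is exposed both as `mirror_ratio` and
as `convention="legacy"`, so distributions remain comparable across the two
conventions.

## Permutation null

The null hypothesis is that the *order* of IOIs is random within
exchangeability strata. The default stratum key is
`(individual, initiating class, terminating class)`: this is the only
labeling under which permuted ratios are always formed between IOIs
flanked by the same element classes and individuals as in the original
sequence, and it is the labeling the pair-level analyses require.
Coarser modes — `(individual, initiating class)` and individual-only (for
unlabeled material such as speech) — are configuration options.

A permutation shuffles IOI *values* uniformly among positions of the same
stratum, across bouts; positions keep their bout membership and labels, so
each stratum's value multiset is conserved exactly (asserted in tests as
exact equality, not tolerance). Shuffling across bouts is a package choice
(a within-bout mode was considered and rejected as the default: most strata
contain few IOIs per bout, so within-bout shuffling leaves the null nearly
degenerate).

Randomness comes from one master seed driving a single PCG64 stream;
permutations are generated in deterministic blocks (block size depends only
on the dataset's IOI count), so identical seed + configuration + input
reproduce bit-identical results.

## Density, deviation, decision

Each ratio sample is summarized by a Gaussian KDE with fixed bandwidth
0.01 (ratio units) evaluated on a fixed 512-point grid spanning [0, 1] —
a *common* grid is required for pointwise moments across permutations, and
[0, 1] is the ratio's full support. No boundary reflection is applied, so
mass within a few bandwidths of 0 or 1 leaks off the grid and densities of
edge-heavy samples integrate to slightly less than one. Implementation:
the kernel is evaluated exactly on the band of grid points within 8σ of
each sample (relative truncation error < 1e−13) and accumulated with
`bincount`; a dense quadratic-cost oracle in the test suite confirms
agreement to 1e−10.

The normalized deviation at each grid point is
`(density − mean) / SD`, with moments taken over the permutation densities
only (sample SD, ddof 1). Including the observed curve in the moment pool
is a documented option; at the default 10,000 permutations the two
readings are numerically indistinguishable, and excluding the observed
curve from its own null moments is the cleaner choice. Where the
permutation SD collapses (below 1e−12 of the largest mean density —
typically the extreme ends of the ratio axis, where normalization would
inflate tiny density fluctuations into huge deviations) the deviation is
set to 0 and the point is flagged in `sd_floor_mask`; no profile ever
contains NaN or infinity.

Quantiles (test statistic and bands) are the empirical
`ceil(q·N)`-th order statistic — conservative, unambiguous, and exact
under enumeration. The test statistic is the `(1−α)` quantile of the
permutations' maximal absolute deviations (α = 0.01, N = 10,000 by
default; the configuration rejects `N < 1/α`). Significance requires the
observed maximum to *exceed* the statistic strictly. The confidence
envelope is pointwise — at each grid point the (0.5%, 99.5%) quantiles of
the permutation deviations; a constant max-envelope band is available via
`global_band`. Peaks are strict local extrema of the observed deviation
(plateau ties resolve to the leftmost grid point; no minimum prominence or
separation by default, both configurable) that lie outside the envelope.

Pair-level analysis restricts the density estimation to ratios whose
*both* constituent IOIs carry the requested ordered pair label, while the
permutation still shuffles the full IOI vector within strata. Omission
analysis instead removes all IOIs of the given pairs before ratio
formation; ratios then only connect surviving IOIs that were adjacent in
the original sequence, and the whole test is re-run on the reduced
dataset.

## Synthetic data

The generator emulates the statistical shape of natural warble material:

* bout sizes `1 + NegBinom(r = 0.6, mean = 7.9)` — mean ≈ 8.9 elements per
  bout with a long tail reaching hundreds;
* lognormal IOIs (median 120 ms, σ = 0.6) — heavy-tailed and strictly
  positive, qualitatively matching natural inter-element gap
  distributions; gamma and uniform families are pluggable for contrast
  experiments;
* element classes drawn i.i.d. from configurable weights, including a
  budgerigar-like 7-class preset with realistic stratum sparsity;
* element durations clipped so intra-bout gaps stay below 200 ms —
  guaranteeing that re-grouping at the 250 ms threshold reconstructs the
  generated bouts — and 500 ms inter-bout silences.

Null sequences draw IOIs i.i.d., which makes the order exchangeable within
any stratum labeling by construction. Patterned sequences repeat a
relative-IOI grammar (`[1]` isochrony, `[1, 2]` a 1:2 alternation) scaled
by a per-bout lognormal base interval (median 100 ms, σ = 0.5) and
multiplied by unit-mean lognormal jitter of a given CV. The per-bout base
interval is essential: under this null, rhythm is an ordering property,
and a planted pattern is detectable precisely because permutation mixes
IOIs of different bout tempi (spreading the permuted ratio distribution)
while the observed ratios stay on the grammar. Zero-jitter patterns give
closed-form ratio multisets used as oracles in the tests.

What the generator does *not* emulate: serial correlation of IOIs beyond
the planted grammar, class-dependent IOI distributions (available but not
default), drift in tempo within a bout, or any spectral realism in the
audio fixtures — synthetic audio is tone bursts with 1 ms ramps over white
Gaussian noise, intended solely for boundary-detection testing. Passing
tests therefore demonstrate correctness of the machinery under controlled
conditions, not that real recordings contain (or lack) rhythm.

## Segmentation front-end

Preprocessing is a zero-phase (forward–backward) 5th-order Butterworth
bandpass — 400 Hz–15 kHz budgerigar, 75 Hz–5 kHz human — followed by a
stationary spectral gate: the per-frequency noise floor is the mean plus
`noise_k` SD (⅓ budgerigar, 1 human) of the STFT magnitude over the whole
recording, and magnitudes are reduced by 1.5× the floor, clipped at zero.
The over-subtraction factor is calibrated analytically: for
Rayleigh-distributed noise magnitudes, plain mean+1 SD subtraction retains
≈16% RMS, while 1.5× retains ≈4% (−28 dB), comfortably meeting a ≥20 dB
reduction on noise-only input. The STFT window equals the RMS window
(5 ms, hop ¼ window), bounding burst-boundary smearing by one envelope
window. Zero-phase filtering and the short gate window are both chosen so
that the quantity consumed downstream — the onset — is not biased.

The RMS envelope uses a 5 ms window and 1 ms hop (`sqrt(mean(x²))` per
window, cumulative-sum implementation). Elements are maximal envelope
regions at or above `threshold_fraction` (default 1/6) of the recording's
*global linear RMS*; whether the original criterion was linear or dB is
not documented, so linear is the default and the fraction is configurable.
Sub-threshold dips shorter than 5 ms (measured as the envelope-frame run
extent) do not split an element; the alternative reading — requiring
supra-threshold runs to last at least 5 ms — is available as
`short_gap_mode="seed"`. Element onset is reported at the *end* of the
first supra-threshold window and offset at the *start* of the last one;
for a high-SNR burst both land within about one envelope step (1 ms) of
the truth, where a center convention would bias onsets by half a window.
Cleaning drops elements shorter than 10 ms (budgerigar) / 20 ms (human)
and relabels "noisy" elements longer than 70 ms as "unknown"; it never
alters boundaries.

## Problem sizes in the test suite

The statistical properties are verified at sizes chosen to give tight
Monte-Carlo envelopes while remaining desk-scale: type-I calibration uses
200 replicate null datasets (1 individual, 3 classes, 200 bouts) at 500
permutations, α = 0.01, with the pass band the 99% binomial envelope of
the nominal rate (≤ 6/200); power uses 50 replicates of planted isochrony
and of a 1:2 grammar (jitter CV 3%, >500 ratios each) requiring ≥95%
rejection and excess peaks within 0.02 (two bandwidths) of every planted
ratio; the enumeration oracle uses 6 IOIs (720 orderings) against 10,000
Monte-Carlo permutations. Because the max-deviation law on 6 IOIs is
heavily atomic, the enumeration comparison fixes a common normalization
(the enumeration's exact moments) so the Kolmogorov distance measures
sampling error alone; the package's self-normalized moments and test
statistic are compared to enumeration separately.

## Known limitations

* The ratio describes only adjacent-interval (local) structure; longer-
  range periodicity is invisible to it.
* Near-boundary ratios (≈0 or ≈1) sit where the permutation SD is small;
  the SD floor suppresses spurious infinite deviations but peaks very
  close to the edges should be interpreted with caution.
* Sensitivity grows with sample size both through the observed density and
  through the permutation maxima: small datasets face a larger test
  statistic, so non-significance on few ratios is weak evidence of
  non-rhythmicity.
* The segmentation front-end is an amplitude-threshold detector; it will
  merge overlapping vocalizations and is not a substitute for manual
  annotation in noisy field recordings.
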