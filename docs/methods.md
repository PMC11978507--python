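# Methods

## Signal model and assumptions

The toolkit assumes the standard nanopore observation model: while the
k-mer `s[r-c : r-c+k]` (c = central-base offset) occupies the pore, the
measured current is approximately constant at a k-mer-specific level, with
per-sample Gaussian noise; traversal speed is stochastic, so one k-mer
dwells for a variable number of raw samples ("stays" when segmentation
produces several events for one position) and occasionally advances within
a single event ("skips"). Each read's current is related to model units by
an unknown per-read affine transform (amplifier gain/offset drift). Direct
RNA traverses the sequence 3'→5' (the `reverse_signal` model flag);
reverse-strand DNA alignments are computed against the reverse-complement
expected signal and stored in forward coordinates.

## Event segmentation

Rolling Welch t-statistics between two adjacent windows are computed at
two window lengths; a boundary is an above-threshold local maximum, and an
accepted peak suppresses further boundaries within one window span for
that window length. Defaults follow the predecessor convention: DNA
windows (3, 6) with thresholds (1.4, 9.0); RNA (7, 14) with (2.5, 9.0),
the longer RNA windows compensating for slower traversal. Variances from
the cumulative-sum formulation are clamped to zero below a relative
1e-12 floor so noiseless constant stretches cannot yield spurious infinite
statistics. Over-segmentation is harmless (stays absorb it);
under-segmentation is not, which drives two identifiability notes below.

## Normalization

Iteration 1 (method of moments) maps event means E so that scale·E+shift
has exactly the mean and population sd of the covered reference k-mer
levels K; each covered position contributes once. Iteration 2 regresses
model means on per-position observed means (all raw samples aligned to a
position averaged first, so dwell does not weight the fit). The fit is
ordinary least squares with one robustness addition: residuals beyond 2.5
robust standard deviations (MAD·1.4826) of an initial fit are dropped and
the fit repeated, twice. Without it, the few percent of positions that the
first alignment pass misassigns attenuate the slope by 10–17%, an order of
magnitude outside the 2% recovery the second iteration should deliver;
with it, a planted affine distortion is recovered to <1% at 500+ positions
and noise sd 0.1. The estimator remains least squares (the rank-based
Theil–Sen alternative was deliberately not used). After the second DTW
pass the regression is refit on the realigned observations, and that
refined transform is recorded in the `un` tag.

During training only iteration 1 is applied: early-iteration models are
error-prone, and regression against a wrong model is worse than moments.

## bcDTW

Band placement: per reference position, the band is centered on the event
containing the midpoint of that position's ref-moves interval, half-width
⌈width/2⌉ (default width 25 events), clipped, forced monotone, and
repaired for connectivity (adjacent columns must overlap even where long
dwells or merged events make the ref-move centers jump by more than the
bandwidth). The first and last columns are clamped to admit the complete
path.

The recurrence is implemented exactly as stated, including the
multiplicative skip penalty: within a column the dependence
`D[i] = c_i + min(a_i, D[i-1])` is solved as a vectorized cumulative
minimum (`D = S + cummin(a − S_prev)` with S the cost prefix sum), which
is algebraically identical to the loop; a brute-force full-matrix oracle
in the test suite confirms exact agreement. Traceback ties break
diagonal > stay > skip. The multiplicative penalty scales the accumulated
cost, so a forced late skip is drastically more expensive than an early
one; consequences for fixtures are discussed under "Generator".

Indels longer than `del_max` (10) are spliced: insertion samples are
masked out of the alignable signal, deleted reference stretches are
excised, and positions whose k-mer window straddles an excision junction
are masked in the output (the spliced k-mer is still used to align
through; `--unmask-splice` keeps the values). A position's samples are one
contiguous run by construction of the encoding; where DTW assigns events
on both sides of a masked gap to one position, the longer run is kept and
the remainder masked.

## Layers and encoding

Per reference position: length (aligned sample count, 0 = skip), current
mean and population sd computed from the raw normalized samples between
the assigned event boundaries (not from event summaries), optional event
counts (fractional 1/g across a skip group of g positions). Skip groups
share the carrier's values unless masked; `keep_best` retains the member
whose model level is nearest the observed mean (used in training), `all`
masks the group.

The `us`/`ur`/`uc`/`ud`/`un` tag semantics are described in the README.
Two deliberate deviations from a pure 16-bit layout: `us` must mix
negative masked runs with the 65535 overflow sentinel and `ur` holds
genomic coordinates, so both are stored as 32-bit BAM arrays while keeping
the 16-bit sentinel codec for `us` magnitudes; and a small `ub` tag stores
the consumed-signal span so the Σ|us| conservation check needs no external
file. The null quantum is 65535 (the only self-consistent choice given
the unsigned 16-bit [−5, 5] fixed-point range), and the
reference-conservation invariant counts non-negative `us` entries (zeros
are reference positions with no signal, so they occupy coordinates).
Quantization error is at most half a quantum, 10/65534/2 ≈ 7.6e-5
normalized units.

## Training

Each iteration streams reads in a seeded random order until every k-mer
reaches `min_kmer_count` (production default 500; desk-scale fixtures use
50), aligning with skip cost 4, keep-best skip masking and one
normalization iteration, keeping positions with `mvcmp.dist ≤ 1` (distance
to the move projection), pooling per-position current means by k-mer, and
recording median and sd; under-covered k-mers inherit the previous model
so iteration is total, and the result is renormalized to mean 0 / sd 1.
De novo initialization treats the ref-moves as a crude alignment, pools at
a short k (1-mer) to average out their one-to-two-base errors, and the
k-mer length then grows by 2 every `iters_per_k` iterations
(1 → 3 → 5), each expansion giving every longer k-mer its contained
k-mer's value with central positions aligned (expand-then-reduce is the
identity).

Convergence behaviour, measured on synthetic data: pooling with the true
alignment reproduces the truth model to r ≈ 0.9999, and one iteration
started *at* the truth stays there (noiseless: exact to float precision;
noisy: r ≈ 0.9995). Started de novo, the iteration can lock into
self-consistent local off-by-one modes seeded by expansion error when a
k-mer occurs in only one sequence context — the aligner then finds exactly
the (wrong) levels the model predicts, and the median confirms them.
Context diversity breaks these modes: the training fixture therefore uses
eight 2 kb contigs whose De Bruijn(4,5) cores are alphabet-permuted and
rotated, so every 5-mer occurs in several distinct local contexts (the
property genome-scale training data has), and runs 16 iterations. Under
those conditions recovery reaches r ≈ 0.99 against the truth model.

## Synthetic data generator

`simulate_read` draws, per reference position: dwell from a shifted
geometric distribution (mean 8 samples by default, minimum `dwell_min`),
zeroed with the skip probability (2%); samples from
Normal(model mean, noise_sd · model sd) (noise_sd 0.3 default; synthetic
truth models carry unit per-k-mer sds so noise_sd is in normalized units);
a per-read affine distortion (scale ~ N(1, 0.02), shift ~ N(0, 0.05));
pA calibration and DAC quantization; and a move table at stride 5 with
±1 block jitter. Synthetic truth models combine additive per-position base
effects with k-mer-specific deviations; the central-base effect is a fixed
well-separated quartet (seeded base assignment, 4× the flanking
magnitude), because real pores have dominant central-base structure — a
model whose central marginal is degenerate defeats the 1-mer de novo
training bootstrap by construction, which is a property of the pore, not
of the method. Per-position randomness is keyed by (seed, reference
coordinate), so read pairs differing only by an indel are identical
elsewhere — the property the splice-invariance check measures. Optional
features: indel specs, dwell boosts tied to a base at a fixed offset (for
the dwell-variability statistic), and modified-track models via
`inject_modification` (IUPAC motif + in-k-mer offset + level shift).

What the generator does **not** emulate, and hence what passing tests do
not show about real data: adapter/stall/open-pore segments, time-varying
gain, basecaller miscalls (the read sequence is the reference except for
requested indels), realistic dwell autocorrelation, and multi-read-group
calibration differences.

Two identifiability constraints are built into the fixtures deliberately:

* homopolymer runs are capped at k where k-mer completeness is requested —
  adjacent identical k-mers produce no current step, cannot be segmented
  by any level-based detector, and force skips that the multiplicative
  penalty prices pathologically in near-noiseless data;
* the noiseless-exactness checks use `dwell_min` ≥ the long t-test window,
  since shorter dwells are invisible to the stated windows even without
  noise. Noisy-regime tests keep the defaults.

The modification-detection fixture additionally screens planted motif
sites so the shifted level contrasts with the flanking levels (gates
0.9/0.4 normalized units), and selects the planted 2-base motif per model
as the one yielding the most identifiable sites: a site whose modified
level coincides with a neighbor's is indistinguishable to any mean-cost
aligner (the same class of limit as a homopolymer boundary), and which
modifications are detectable depends on the pore's level landscape, as in
reality.

## Numerical and interface choices

0-based half-open coordinates internally, BAM's convention only at I/O
boundaries. Population (n-denominator) standard deviations throughout.
Substitution profiles use absolute differences and include
self-substitutions (they add zeros, scaling columns uniformly). Jaccard
distance is the standard 1 − |A∩B|/|A∪B|. KS statistics use
`scipy.stats.ks_2samp`; z-scores use unbiased variances. Multiple-testing
correction is not applied by default (a Benjamini–Hochberg helper is
provided). Ties in `central_base` break toward the smaller index. U is
silently mapped to T. `eventalign`'s `event_length` column is in raw
samples, since alignments do not store a sampling rate.

## Known limitations

* Adaptive band repositioning, HMM transition models and GPU execution
  are out of scope; the band is fixed before alignment.
* POD5/FAST5/BLOW5 readers are declared adapter interfaces only; SLOW5
  ASCII is the implemented raw-signal format.
* The multiplicative skip penalty makes forced skips position-dependent in
  cost; references rich in repeated adjacent k-mers (long homopolymers)
  degrade alignment quality near those runs.
* Desk-scale training (hundreds of reads, kilobase contigs) needs the
  context-diversity conditions above; single-context corpora can converge
  to locally shifted models.
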