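# Methods

## Overview

`brainhmm` models the structural complexity of the cortical gray-matter
(GM) boundary as a *sequence* of per-slice complexity summaries and asks
whether that sequence is better explained by a "demented" or a "control"
generative model. The chain is:

1. **Distance series.** Each axial slice of a tissue-labeled volume is
   reduced to the ordered Euclidean distances from consecutive points on
   the outer GM boundary to the slice's GM center of mass. One slice, one
   series; a subject is the top-to-bottom stack of 130–140 such series.
2. **Complexity features.** Each series yields (a) a regularity-dimension
   profile — local slopes of sample entropy against log(1/r) over a
   shrinking tolerance grid — and (b) an experimental semivariogram over
   integer index lags.
3. **Vector quantization.** Pooled training vectors from both groups are
   quantized with LBG codebooks: regularity profiles into J = 2 indices
   (used as hidden states), semivariogram profiles into J = 32 indices
   (used as observable symbols).
4. **HMMs.** Per group, a discrete HMM λ = (A, B, π) is estimated by
   supervised counting from the paired (state, symbol) index sequences; π
   is fixed uniform. Baum-Welch refinement is available but off by
   default (see "Supervised vs re-estimated" below).
5. **Decision rules.** A held-out subject is assigned to the group whose
   model gives its symbol sequence the higher scaled-forward
   log-likelihood, or (second rule) to the group whose model has the
   smaller symmetrized Monte-Carlo Kullback-Leibler dissimilarity
   d = 1 − exp(D_s) to the subject's own supervised HMM.

## Sample entropy and the regularity dimension

SampEn(m, r, N) = −ln(A/B), where B counts ordered pairs (i ≠ j) of
length-m templates whose Chebyshev distance is ≤ r, and A the same for
length m+1; both counts run over the N − m templates starting at indices
1..N−m. The series is standardized to zero mean and unit sd first, so r
is in sd units — otherwise a fixed tolerance grid would mean different
things on slices of different size. If either count is zero the value is
undefined (`nan`), never ±inf.

Defaults: m = 2 (standard practice for series of a few hundred points;
exposed as a parameter), r grid descending 1.00, 0.95, …, 0.05 (20
values).

The regularity dimension is the rate at which SampEn grows with
log(1/r). Since the underlying limit r → 0 cannot be evaluated on data
(match counts die out), the per-slice feature is the 3-point sliding
least-squares slope of the SampEn profile against log(1/r), giving 18
interior values per slice. Undefined SampEn entries (usually at the
smallest tolerances) are filled by carrying the last finite value so
every slice yields a fixed-length vector for quantization; slopes whose
window contains carried values are flagged as imputed. Slices with fewer
than 3 finite SampEn values raise a feature error and are dropped.

A caution borne out by simulation: the slope at the very edge of the
defined region uses the highest-variance SampEn estimate (the (m+1)-match
count is nearly zero there). On white noise the *average* slope over the
small-r half of the defined region is nonnegative essentially always,
while the single edge slope is negative in roughly 1 run in 12. Tests and
interpretation therefore use the averaged reading.

## Semivariogram

γ(h) = (1/2N(h)) Σᵢ (xᵢ − xᵢ₊ₕ)², with N(h) = L − h non-circular pairs at
index lag h along the boundary traversal (an arc-length proxy; Euclidean
binning was rejected because it produces variable-length, non-deterministic
feature vectors). Distances are used in raw pixel units, so γ carries the
absolute scale of boundary fluctuation; the per-dimension z-scoring inside
the VQ stage (below) removes gross scale differences across lags before
clustering. Default maximum lag K = 100, so any boundary of ≥ 101 points
yields an equal-length vector; shorter boundaries are flagged and the
slice dropped.

## Vector quantization

LBG with binary splitting: start from the global centroid, split every
code vector c into c(1 ± ε) with ε = 0.01, then Lloyd-iterate
(nearest-neighbor assignment, centroid update) until the relative
distortion improvement falls below 10⁻⁶ or 100 iterations. Distortion is
D = (1/TK) Σ ‖y − Q(y)‖², reported per codebook. Empty cells are reseeded
from a random member of the most populous cell (the only use of the
seeded RNG). This rule also rescues the degenerate first split on
z-scored data, where the global centroid is the zero vector and a
multiplicative perturbation cannot separate it.

Training vectors are pooled from both groups (a shared quantizer keeps
index sequences comparable across subjects) and z-scored per dimension;
the scaler is stored in the codebook and re-applied at encoding time.
Ties in nearest-neighbor assignment break to the lowest index. State
codebook size 2 and symbol codebook size 32 are the defaults; a sweep
utility (`classifier.symbol_size_sweep`) covers 4–256.

## Discrete HMMs

Supervised estimation is add-pseudocount counting of transitions and
emissions (default pseudocount 10⁻³ — without it a held-out subject can
emit a symbol a group never produced in training, sending both group
likelihoods to −inf). π is fixed uniform everywhere and is never
re-estimated: with two coarse regularity states the starting slice of a
stack carries no group information. Forward likelihood uses per-step
normalization with log accumulation (raw products underflow at T ≈ 135).
Baum-Welch sums expectations over sequences, updates A and B only, and is
monotone in total log-likelihood up to rounding.

**Supervised vs re-estimated.** The default classification workflow uses
the supervised estimates; Baum-Welch refinement is available behind a
flag (`refine=True`). Refining every group model toward higher P(O|λ) on
its own training data also tends to raise the probability of the *other*
group's sequences, and with small training sets it can flip
marginally-separated subjects; the supervised estimates are the
better-behaved default here.

**KLD.** D(λ₁, λ₂) = (1/T₂) log[P(O_λ₂|λ₁)/P(O_λ₂|λ₂)] with O_λ₂ a single
sequence of length T₂ = 2000 sampled from λ₂; symmetrized as the mean of
the two directions and mapped to d = 1 − exp(D_s). Both draws use the
same seed (common random numbers), which makes d exactly 0 for identical
models, exactly symmetric in its arguments when T₁ = T₂, and lower in
Monte-Carlo variance. A −inf likelihood flags the result and saturates d
at 1.

## Classification and validation

Positive class is the "demented"-style group; sensitivity = TP/(TP+FN),
specificity = TN/(TN+FP). Ties — including both likelihoods at −inf —
classify as control (conservative toward "no disease") and are logged.
The KLD rule estimates the held-out subject's own HMM from its index
sequences with the same pseudocount and falls back to the likelihood rule
if both divergences are non-finite.

Leave-one-out retrains **both codebooks and both group models** in every
round; codebooks are training artifacts, and folding them in prevents the
optimistic bias of quantizing with prototypes that saw the test subject.
The n-fold scheme uses stratified random splits (equal training fraction
per group) repeated with a seeded generator; rates are reported as mean ±
sd over repeats.

A subtlety worth recording: if the two groups' training data are
*bitwise identical*, LOO accuracy is deterministically 0 rather than 0.5
— the held-out subject's group has one fewer training sequence, so
pseudocount smoothing leaves the opposite group's model marginally
sharper on the shared empirical sequence. Chance behaviour is obtained
(and tested) with statistically identical, not bitwise-identical, groups.

## Synthetic cohorts

A subject is a stack of annular GM masks whose outer boundary follows

    ρ(θ) = R(z) + e(z) · Σₖ aₖ sin(kθ + φₖ) + ε(θ)

with R(z) = R₀√(1 − τ(2z−1)²) an ellipsoidal taper along the stack
(τ = 0.8 by default; 0 disables it), e(z) = 0.75 + 0.25 cos(2πz + φₑ) a
smooth per-subject envelope that gives slice-ordered sequences genuine
sequential structure, φₖ per-subject harmonic phases, and ε i.i.d.
Gaussian radial jitter drawn per slice on a dense 720-point angular grid
and interpolated to pixel angles. Pixels are included when their center
lies within half a pixel of the band [ρ − thickness, ρ], so a noiseless
circle of radius R yields boundary distances in [R − 0.5, R + 0.8]
(half-pixel plus diagonal discretization). Seeds: per-subject seeds are
derived from (master seed, CRC32(group), index) via `SeedSequence`, so
every output is a pure function of the spec.

**Default study conditions** (`study_spec`): two groups of 30 subjects,
135 slices (inside the typical 130–140 whole-brain range), 176-pixel
grid, base radius 55 px, ring thickness 6 px. Controls: harmonics
(4, 2.5), (6, 1.5) px, jitter sd 0.1 px. Demented: the same plus
(9, 1.2), (13, 1.0), (17, 0.8), (23, 0.6) px and jitter sd 1.2 px. The
demented boundary is thereby genuinely less predictable — higher sample
entropy (≈1.24 vs ≈0.81 at m=2, r=0.2 on probe runs) and a raised
semivariogram nugget — not merely larger in amplitude. That direction
matters: a single *large* clean high-frequency harmonic would instead
*lower* sd-relative SampEn, because it adds regular structure that
dominates the variance after standardization. A `gap` parameter scales
the extra harmonics and jitter for monotonicity experiments.

What the generator does **not** emulate: realistic cortical folding
topology (gyri/sulci are not annuli), WM/CSF compartments, partial-volume
and segmentation errors, intensity inhomogeneity, inter-subject
registration error. Passing tests therefore demonstrate that the chain
recovers controlled boundary-irregularity differences from rasterized
shapes end to end — not clinical performance on real MRI.

## Problem sizes

Chosen to keep the default suite and the acceptance script comfortably
reproducible on one CPU: the end-to-end study runs at the full 30
subjects/group × 135 slices; the gap-monotonicity property test uses 12
subjects/group × 20 slices; the SampEn group-separation check uses 10
subjects/group × 4 slices; the acceptance script's n-fold stage uses 10
repeats per training fraction (LOO under both rules dominates its
runtime), while the library default remains 100 repeats.

## Known limitations

- The annulus model is radially star-shaped by construction; boundaries
  of real cortical sections are not, and the distance series of a
  non-star-shaped contour is not a function of angle.
- The regularity-dimension reading (sliding-window slope of SampEn vs
  log(1/r)) is one of several defensible realizations of a limit that
  cannot be evaluated on data; the pointwise ratio I_r/log(1/r) is
  singular at r = 1 and was rejected.
- The empirical KLD uses a single Monte-Carlo draw per direction;
  margins smaller than its seed-to-seed sd can flip labels (the
  likelihood rule has no such noise and is the default).
- With 2 hidden states and π uniform, label switching makes A nearly
  exchangeable; comparisons of estimated models to generators align
  states by the best permutation.
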