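# Methods

This note documents the model, the numerical choices and the synthetic
study conditions behind spikeface, and what the test suite does and does
not establish.

## Model and assumptions

The system is a purely feedforward hierarchy; each stage consumes only
the previous stage's output and there is no recurrence, no continuous
time, and no leak in the integrate-and-fire units.  Each afferent spikes
at most once per stimulus; all information is carried by the firing
*order*, never by rates or precise latencies.

**Retina.**  ON/OFF ganglion cells are modelled by a single
center–surround kernel, `K(x,y) = g·(x²+y²−σ²)/σ⁴·e^{−(x²+y²)/2σ²}`,
evaluated on the integer grid `[−r, r]²` with `r = ceil(3σ)`.  The
analytic kernel integrates to zero; after truncation a constant is
subtracted so the discrete entries sum to zero exactly, preserving the
defining property that uniform illumination evokes no response.  The
linear response is rectified into an ON map (positive part) and an OFF
map (negative part); the stage is linear before rectification, so both
maps scale with image contrast.  Default scales σ ∈ {1, 2} pixels; their
rectified outputs are averaged into the V1 input.

**V1.**  Complex Gabor kernels with 8 orientations `ψ_μ = πμ/8`
(μ = 0..7, spanning 180°) per frequency scale `k_ν = k_max/f^ν`.
Defaults: σ = 2π, k_max = π/2 rad/pixel, f = √2, 3 scales — conventional
Gabor-wavelet settings.  The `e^{−σ²/2}` term removes the DC component
analytically only on the continuous infinite plane; after sampling and
truncation (radius 3σ/k_ν, three envelope standard deviations) a small
envelope-weighted correction removes the residual, so the measured DC
response is at numerical noise level rather than merely "small".  The
modulus of the complex response is the stage output (complex-cell-like
phase invariance); the real and imaginary parts (simple-cell-like
quadrature pair) remain accessible via `gabor_response_complex`.

**Topographic ICA.**  The feature stage assumes whitened inputs are a
rotation of sparse sources whose *energies* are dependent inside a fixed
neighborhood `h(i,j)` (binary, symmetric, self-inclusive; line, ring or
Chebyshev-grid index distance).  The per-sample log-likelihood is
`Σ_j P(G_j) + log|det W|` with `G_j = Σ_i h(i,j)(w_iᵀz)²`.  For the
sparsity nonlinearity we use `P(y) = −α·sqrt(y + ε) + β` with ε = 1e-3,
α = 1, β = 0, whose derivative `p(y) = −α/(2·sqrt(y+ε))` is smooth at
zero energy.  An affine P would have a constant derivative and the
topographic coupling would cancel out of the gradient, so a curved P is
a structural requirement of the model, not a tuning choice.  The
gradient update is `Δw_i ∝ E[z(w_iᵀz)r_i]`, `r_i = Σ_k h(i,k)p(G_k)` —
the neighborhood sum sits *inside* p through G and outside it through r,
the form consistent with the likelihood above.

Optimization: W starts from a seeded random Gaussian matrix made
orthogonal by `W ← (WWᵀ)^{−1/2}W`; the same symmetric orthogonalization
follows every gradient step, so `WWᵀ = I` holds to 1e-8 throughout.  The
step size backtracks (halving, up to 40 times) whenever a step would
lower the likelihood by more than 1e-9, which makes the recorded
likelihood trace non-decreasing; the step relaxes back (×1.2, capped at
the configured rate) after accepted steps.  Stopping: relative
likelihood change below `tol` (1e-6 by default) or `n_iter` iterations.
Matrix inverse square roots use eigendecomposition with an eigenvalue
floor of 1e-12; whitening keeps the top `n_keep` eigenpairs of the
sample covariance and refuses eigenvalues below 1e-10 of the largest.
Mixing recovery uses the pseudo-inverse `A = (WV)⁺`, which equals the
inverse in the square case and a subspace inverse under dimension
reduction.

A caveat observed on the synthetic benchmark: the gradient ascent
recovers the *sources* essentially perfectly (Amari index ~0.01) but the
topographic *arrangement* of the learned components can settle in a
permutation-local maximum of the likelihood, and the final likelihood
value does not reliably rank arrangement quality across initializations.
The neighbor-vs-non-neighbor energy-correlation gap therefore comes out
positive but modest, and no restart heuristic is applied (one seeded
initialization per fit).

**Spiking readout.**  Feature vectors (the concatenated TICA
neighborhood energies of a fixed grid of patches, see below) are encoded
by rank: the top `ceil(keep_frac·n)` activations spike in descending
order, ties broken by ascending index, zeros never spike.  A neuron
accumulates `P = Σ_j mod^{order(j)} w_j` and fires iff `P ≥ P_th`.  Maps
share one weight vector per class, set to the batch average
`w_j = (1/N) Σ mod^{order(a_j)}` — each map responds to the average rank
pattern of its category, and batch training equals the mean of
single-wave trainings by linearity.  Thresholds are calibrated per map
as `margin × min(own-class training PSP)` (margin 0.9 by default;
margin ≤ 1 guarantees every training sample fires its own map).  The
paper-level alternative of a fixed hand-set threshold is not supported:
nothing in the model fixes the PSP scale a priori.

Lateral inhibition is subtractive and winner-based: repeatedly take the
globally strongest not-yet-winning above-threshold unit and subtract
`amplitude·e^{−d²/2σ²}` from the other classes' maps around its
location, for at most one round per class.  With a flat (non-spatial)
feature vector every class map degenerates to a single neuron and the
zone acts at distance zero, i.e. winner-take-all suppression.  The
decision is the firing map with the highest post-inhibition potential;
if no map fires the sample is "rejected" (an all-black image, for
example, produces an empty spike wave and zero potentials).

## Pipeline interfaces

The stages are glued as follows: preprocess (elliptical face mask,
margin 0.05; illumination normalization) → retina ON+OFF (averaged over
scales) → Gabor modulus maps → 2×2 local-max pooling → per-map grids of
non-overlapping 8×8 patches → TICA energies per patch → one concatenated
feature vector per image.  TICA is fit on `n_patches` (3000) patches
sampled from the pooled maps of the *training* images only.  Local-max
pooling echoes complex-cell spatial invariance; patch-indexed energies
keep coarse spatial layout, which the classes need (a smile and a frown
have identical global orientation statistics and differ only in where
the diagonal energy sits).

**Illumination normalization default.**  Two global methods are
provided: histogram equalization and mean–variance standardization
(affine rescale to [0, 1]; constant images map to 0.5).  The default is
mean–variance.  On images with a large, nearly uniform region — the
synthetic faces, and tightly cropped real faces alike — equalization
stretches the narrow noise band of that region across the full intensity
range, flooding the contrast stages with amplified noise; on the
benchmark this costs tens of accuracy points.  The affine method cannot
amplify noise (and the later stages are already invariant to global
affine intensity changes, since the retina removes the offset and rank
order absorbs the gain; its practical role is to standardize inputs for
the masked-background edge).

## Synthetic study conditions

`make_face` renders an oval face (intensity 0.8 on 0.05 background), two
eye ellipses whose height is proportional to `eye_openness`, mirrored
brow segments rotated by `brow_angle`, and a quadratic mouth whose
signed `mouth_curvature` bends it up or down, on a 64×64 canvas.  The
five classes draw these three parameters from disjoint ranges (e.g.
happy: curvature 0.55–0.90; anger: brow −0.50..−0.28), so a threshold
rule on the generating parameters labels the data perfectly — any
end-to-end failure is a pipeline fault, not a data fault.  Illumination
is a multiplicative lateral ramp `1 + 0.5·sin(angle)·(x−c)/c` (0°
frontal, 90° fully lateral); noise is additive Gaussian (sd 0.01 in the
benchmark datasets); everything is bit-reproducible from the seed.

What the generator does *not* emulate: pose, identity variation,
occlusion, hair and background clutter, non-rigid texture, or the
within-class ambiguity of real expressions.  Passing the benchmark shows
the hierarchy transmits and classifies the geometric differences it was
given; it does not predict accuracy on photographic data.

The TICA benchmark draws either independent unit-variance Laplacian
sources, or Gaussian sources `s_i = σ_i g_i` whose variance field
`σ² = h·u` is shared within width-m index neighborhoods with
`u ~ lognormal(0, 2)`.  The heavy-tailed variance components put the
neighbor energy correlation of the true sources near 0.2 — strong enough
that the dependency the model is supposed to detect actually exists at
the benchmark sample size (with unit-exponential components it would be
2/27 ≈ 0.07, mostly below the estimation noise floor).  The mixing
matrix is seeded random with condition number below 20.

Benchmark sizes, chosen to exercise every stage at desk scale: 5 classes
× 20 images for the 70/30 evaluation; 6 sources × 10 000 samples for
blind-source recovery; 12 sources × 20 000 samples for the topographic
arrangement check; 20 train + 10 test images per class for the
illumination protocol (train frontal, test at 45°).

## Known limitations

- The output layer is effectively a nearest-class-template rule in the
  rank-transformed feature space; it has no discriminative training
  beyond the class averages and inherits their limitations.
- Lateral inhibition cannot change the winner when all class maps are
  single neurons (subtraction preserves the order of the others); it
  matters for score reporting and for spatial maps.
- The topographic arrangement caveat above: energy-correlation topology
  is recovered weakly, and only the sign of the neighbor/non-neighbor
  gap should be relied upon.
- Whitening is a hard rank reduction; inputs whose covariance is nearly
  singular in the retained subspace are rejected rather than regularized.
- The permutation control of the evaluation protocol has high variance
  by construction (whole test classes follow one permuted template), so
  it is reported as a mean over several permutation runs.
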