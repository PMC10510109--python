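# Methods

This note documents the models, estimators, parameter choices, and known
limitations behind `memnano`. It is the place to look when a default needs
justifying or a numerical choice needs auditing.

## Nanoclustering statistics (spatial)

### Estimator

Gold-particle coordinates on a rectangular plasma-membrane sheet are
summarized by the isotropically edge-corrected univariate K-function

    K̂(r) = A / (n(n−1)) · Σᵢ Σ_{j≠i} w_ij · 1(‖xᵢ−xⱼ‖ ≤ r)

with A the sheet area, n the particle count, and w_ij the inverse of the
fraction of the circle centered at xᵢ with radius ‖xᵢ−xⱼ‖ lying inside the
rectangle. The n(n−1) pair normalization is used (rather than n²) because it
makes the estimator exactly unbiased for πr² under complete spatial
randomness at fixed n; the two conventions differ by the factor (n−1)/n,
which cancels entirely in the envelope-normalized quantities below. The
variance-stabilized form L(r)−r = √(K/π) − r is zero in expectation under
CSR and positive under clustering.

The circumference fraction is computed analytically, not by sampling: each
of the four rectangle edges at distance d < r from the center removes a cap
of arc angle 2·arccos(d/r), and caps of adjacent edges overlap near a corner
by max(0, arccos(dᵢ/r) + arccos(dⱼ/r) − π/2), subtracted once per corner.
This is exact whenever r does not exceed half the shorter side; the radius
grid warns beyond that. Limiting values: weight 1 deep inside, 2 on an edge,
4 at a corner.

### Envelope normalization and L_max

The confidence envelope is pointwise: for each radius, the 99th percentile
of L(r)−r over `n_sims` (default 1000) CSR simulations with the same n and
region as the observed sheet. Dividing the observed curve by the envelope
puts the CSR 99% confidence level at 1 at every length scale, so values
above 1 indicate statistically meaningful clustering and the curve maximum
L_max summarizes its extent. A pointwise (per-radius) envelope is used, not
a simultaneous band, because the normalization is applied per length scale.
Radii where the envelope percentile is ≤ 0 are excluded from the curve and
the L_max search — dividing by a non-positive confidence bound is
meaningless; ties in locating the maximum go to the smallest radius.

Default radius grid: 1–240 nm in 1 nm steps on a 1 µm² sheet. 240 nm keeps
the edge weights well-defined (≤ half the shorter side with margin) and
covers the length scales at which protein nanoclusters (radius tens of nm)
express themselves in K.

### Group tests

Per-sheet L_max values are compared between conditions with a pooled-null
bootstrap: the statistic is the difference of group means; the null pools
both groups and resamples two groups of the original sizes with replacement
(default 1000 resamples); the two-sided p-value is
(1 + #{|boot| ≥ |obs|})/(n_boot + 1), so it can never be smaller than
1/(n_boot+1). The construction (statistic and null) is a documented package
choice — alternatives can be plugged in — since only the test family is
standard, not its details. Labeling densities (points/µm² per sheet) are
compared by one-way ANOVA; the F statistic is computed from the
between/within decomposition directly so the degenerate cases are
well-defined (all densities identical → F = 0, p = 1; distinct group means
with zero within-group variance → F = ∞, p = 0).

## Single-particle tracking

Detection emulates a GLRT matched-filter test against a flat background.
The frame is correlated with a zero-mean, unit-norm Gaussian template of
the PSF width (default 1.3 px); under the flat-background null the squared
z-score of the response is χ²₁, with the noise scale estimated robustly
(MAD of the response). The sensitivity parameter s (default 30) is mapped
to a per-frame false-alarm probability 10^(−s/10), Bonferroni-split across
pixels into a per-pixel threshold. The mapping is an emulation — the
commercial tracker it mirrors does not publish its internals — calibrated
so that pure-noise frames essentially never yield detections. Candidates
are merged by 8-connectivity, refined by least-squares fit of a symmetric
2-D Gaussian with free background, and discarded within one PSF sigma of
the frame border.

Linking is greedy, frame by frame: candidate (track end, localization)
pairs within the maximum jump (default 5 px) are accepted in order of
increasing distance, ties to the earlier track; a track may skip one frame
(blinking, default max_gap 1); tracks with fewer than 6 observations are
discarded. "At least 6" is one reading of an ambiguous persistence rule
("more than 6 frames" could mean ≥ 7); `min_length` is configurable. Greedy
assignment was chosen over globally optimal matching because at the sparse
labeling densities this pipeline targets, assignment conflicts are rare and
the greedy result is almost always identical.

MSD is pooled (time-and-ensemble): for each lag, squared displacements are
averaged over all valid frame pairs across all tracks; pairs spanning a
blink contribute at their true frame difference. D is slope/4 of an
ordinary least-squares line through the first `n_lags` (default 4) MSD
points; the intercept estimates the localization-noise floor 4σ_loc²
(0.0036 µm² at σ_loc = 30 nm). Negative fitted D is allowed but flagged.
Positions are handled in µm internally; pixel inputs convert at
0.16 µm/px by default (a 100 × 100 px, 16 × 16 µm field of view).

## NMR metrics

CSP (ppm) = √((ΔN²/25 + ΔH²)/2) per residue, combining the amide ¹H and
¹⁵N shift changes with the conventional 1/25 down-weighting of ¹⁵N inside
the root. PRE ratios are I_tagged/I_untagged, normalized by dividing all
raw ratios by the maximum so the least-attenuated residue reads exactly 1
(an optional flag normalizes instead by the mean over a user-named set of
unaffected residues). No dilution/receiver-gain correction between the
tagged and untagged samples is applied; if needed it should be folded into
the intensities upstream.

TRACT: the TROSY (α) and anti-TROSY (β) ¹⁵N decay series are each fit to
I(t) = I₀·e^(−Rt) by nonlinear least squares initialized from a log-linear
fit (an additive offset is optional by flag). The rate difference
ΔR = R_β − R_α equals twice the transverse ¹⁵N-CSA/N–H-dipole
cross-correlation rate; for an isotropic rigid rotor

    ΔR(τc) = 4·p·δ_N·P₂(cosθ)·[4J(0) + 3J(ω_N)],
    p = μ₀γ_Hγ_N h/(16π²√2 r³),  δ_N = γ_N B₀ Δσ/(3√2),
    J(ω) = (2/5)·τc/(1 + (ωτc)²)

with r_NH = 1.02 Å, Δσ = 160 ppm, θ = 17°. This conversion is external to
the nanoclustering analyses and standard in the relaxation-interference
literature; as an internal consistency check, the implemented expression
puts the field at which the interference is maximal relative to
auto-relaxation near 1.05–1.1 GHz (the known TROSY optimum), grows
linearly with τc in the slow-tumbling limit, and is strictly increasing in
τc, so the Brent-bracketed inversion (1 ps–1 µs) is well-posed. At
900 MHz, ΔR = 30 s⁻¹ corresponds to τc ≈ 9.5 ns and ΔR ≈ 62 s⁻¹ to 20 ns.

## Assay curves

DSF: the melt curve is normalized to its maximum; the first derivative is
taken with a Savitzky–Golay filter (window 15 points ≈ 7 °C on the default
0.5 °C grid, cubic, analytic derivative) when the grid is uniform, falling
back to central differences otherwise. The symmetric window suppresses
measurement noise without shifting a symmetric transition. Tm is the
derivative maximum refined by a parabola through the peak and its
neighbors (the raw grid would quantize Tm to 0.5 °C). All local derivative
maxima are reported as diagnostics; only the global maximum defines Tm. A
curve whose derivative is never positive raises "no melting transition".

DLS: scattering intensity versus log₁₀(concentration) is fit by a
continuous two-segment ("hinge") model y = a + bx + c·max(0, x−x_b), with
the breakpoint x_b searched exhaustively over interior grid positions
(≥ 2 points strictly on each side) and CAC = 10^(x_b). The segmented fit
must beat a single straight line by an F-test (2 extra parameters, default
α = 0.05) and must steepen (c > 0); otherwise "no aggregation onset
detected". The breakpoint is restricted to observed grid positions, so its
resolution is the grid spacing.

FLIM: single-component exponential tailfit I(t) = I₀e^(−t/τ) + offset,
restricted to t ≥ tail_start, by bounded nonlinear least squares. Flat
traces and fits whose τ exceeds the observation window by orders of
magnitude are rejected as non-convergent with the residual in the message.

## Synthetic-data generators

The generators produce data with exactly the statistical structure the
analyses assume, plus ground truth for recovery tests:

- **CSR patterns**: n points i.i.d. uniform on the region — the
  Monte-Carlo null of the envelope.
- **Clustered patterns**: a Thomas-style process; parent centers uniform,
  occupancy uniform on {4,…,6} per cluster (the nanocluster occupancy the
  spatial analysis targets), isotropic Gaussian dispersion. The dispersion
  default of 20 nm is artifact-chosen — no cluster radius is established
  for the system being emulated — and is the free parameter of the
  generator. Offspring landing outside the sheet are re-drawn rather than
  clipped or torus-wrapped, preserving the exact per-cluster count with
  edge-consistent density.
- **Brownian tracks**: per-frame displacement components N(0, 2DΔt);
  reflecting boundaries keep positions inside the field of view (tests of
  increment statistics use a region large enough that reflections never
  occur); independent Gaussian localization error on reported positions;
  blinking drops a frame's observation with fixed probability but never
  two in a row, so single-gap linking can in principle recover every
  track. Defaults: 10 ms frames, 16 × 16 µm region.
- **Rendered movies**: each localization becomes an integrated (pixel-
  averaged erf) symmetric 2-D Gaussian of given total photon count on a
  uniform background, with optional Poisson counting noise; 0.16 µm/px
  gives the default 100 × 100 px frame.
- **NMR tables**: reference shifts uniform in typical amide windows
  (¹H 7–9.5 ppm, ¹⁵N 105–130 ppm); perturbed residues receive fixed
  (ΔH, ΔN) offsets and a fractional tagged-intensity loss; multiplicative
  Gaussian noise.
- **Curves**: mono-exponential decays on the standard interleaved TRACT
  delay schedules (α: 0–240 ms in 14 steps; β: 0–70 ms in 14 steps),
  logistic melts on the 25–95 °C, 0.5 °C grid, two-segment log-
  concentration scattering series (default breakpoint 80 nM), and
  exponential-plus-offset lifetime decays; noise is Gaussian and
  proportional to signal.

Every generator consumes one integer seed feeding a single NumPy
`default_rng` stream; identical seeds give bit-identical outputs.

### What the generators do not emulate

Real immunogold patterns carry antibody-linker displacement (~10 nm),
variable labeling efficiency, and non-rectangular sheet boundaries; real
TIRF movies have bleaching, anomalous diffusion, and structured
background; real NMR intensities have peak-overlap and baseline artifacts.
Passing the recovery tests therefore demonstrates the correctness and
calibration of the estimators under their stated assumptions, not
robustness to every instrumental artifact of real data.

## Problem sizes and numerical tolerances

The statistical test-suite checks run at desk scale chosen for stable
pass/fail behavior: envelope calibration uses a 1000-simulation envelope
probed with 2000 fresh CSR patterns at n = 300 (binomial 3σ band on the 1%
exceedance rate); estimator unbiasedness uses 500 simulations against the
exact πr² expectation (3 MC SE per radius); clustering power uses 100
replicates of 50-cluster patterns with 100-simulation matched envelopes;
diffusion recovery uses 500 tracks of 200 frames; rate recovery uses 200
replicates at 1% noise. Floating-point equality against brute-force
oracles is asserted at rtol 1e-10 (summation order differs between
implementations). Bootstrap p-values carry the +1 correction, so exact
zeros never occur.

## Known limitations

- The edge-correction formula is exact only for radii up to half the
  shorter region side; larger radii trigger a warning, not an error.
- The GLRT sensitivity scale is a calibrated emulation, not a
  reimplementation of the proprietary tracker it stands in for; absolute
  sensitivity values are not interchangeable between the two.
- Greedy linking can mis-assign crossing particles at high density; the
  pipeline targets sparse labeling where this is negligible.
- The ΔR→τc inversion assumes isotropic rigid-body tumbling with fixed
  r_NH, Δσ, and θ; anisotropic or exchange-broadened systems will bias τc.
- The CAC breakpoint is quantized to the measured concentration grid.
- Rectangular observation windows only; masked or irregular sheets are out
  of scope.
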