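# memnano

Quantitative analysis of membrane-protein nanoclustering and lateral
mobility, with the companion biophysical assay metrics, in one tested
Python package. It is written for researchers who study how peripheral
membrane proteins (the motivating system is K-Ras on the inner plasma
membrane leaflet) organize into nanoscale clusters and how that
organization responds to perturbation — and who need the statistics behind
immunogold electron microscopy, single-particle TIRF tracking, NMR
titrations, and plate-based assays to be reproducible and testable.

## What it computes

**Nanoclustering from immunogold EM** (`memnano.spatial`). Gold-particle
coordinates (x, y in nm) inside a 1 µm² plasma-membrane sheet are
summarized by the isotropically edge-corrected univariate Ripley
K-function,

K̂(r) = A/(n(n−1)) · Σᵢ Σ_{j≠i} w_ij · **1**(‖xᵢ−xⱼ‖ ≤ r),

where w_ij is the inverse of the fraction of the circle about xᵢ with
radius ‖xᵢ−xⱼ‖ lying inside the sheet, computed analytically from arc
geometry. The variance-stabilized curve L(r)−r = √(K̂/π) − r is divided
pointwise by a Monte-Carlo 99th-percentile envelope of matched CSR
(complete spatial randomness) simulations, so the value 1 marks the 99%
confidence level and the curve maximum L_max summarizes the extent of
clustering. Conditions are compared by a pooled-null bootstrap on
per-sheet L_max and by one-way ANOVA on gold labeling density.

**Single-particle tracking** (`memnano.tracking`). GLRT-style matched-
filter spot detection (default sensitivity 30, PSF 1.3 px) with sub-pixel
2-D Gaussian refinement; greedy nearest-neighbor linking with a 5 px
maximum jump, single-frame blinking tolerance, and a 6-observation minimum
track length; pooled time-and-ensemble MSD; D = slope/4 of the first MSD
lags, whose intercept reports the 4σ² localization-noise floor.

**NMR metrics** (`memnano.nmr`). Chemical-shift perturbation
CSP (ppm) = √((ΔN²/25 + ΔH²)/2); paramagnetic relaxation enhancement
ratios I_tagged/I_untagged normalized to a maximum of 1; TRACT α/β decay
fitting with inversion of the ¹⁵N CSA/dipole cross-correlation rate
difference to the rotational correlation time τc.

**Assay curves** (`memnano.curves`). DSF melting temperature from the
maximum of the first derivative of the normalized melt curve; DLS critical
aggregation concentration from a continuous two-segment breakpoint fit in
log-concentration; FLIM lifetime from a single-exponential tailfit.

**Synthetic data** (`memnano.synthgen`). Seeded generators for every input
above — CSR and Thomas-clustered point patterns (4–6 points per cluster),
Brownian trajectories with localization noise and blinking, rendered TIRF
movies, paired NMR tables, and all four curve families — each returning
ground truth alongside the observables, so every stage of the pipeline is
testable without lab data.

## Worked example

Simulate three clustered PM sheets (50 clusters of 4–6 points, 20 nm
dispersion, 1 µm²), compute per-sheet K-functions, a 200-simulation CSR
envelope matched to each sheet's point count, and normalized L_max:

```
$ cat config.yaml
seed: 1
out_dir: demo_out
n_sheets: 3
n_clusters: 50
cluster_sd_nm: 20.0
n_sims: 200
r_step_nm: 2.0

$ memnano run --config config.yaml
sheet0: n=247, density=247.0/um^2, L_max=10.947 at r=54 nm
sheet1: n=252, density=252.0/um^2, L_max=9.144 at r=56 nm
sheet2: n=257, density=257.0/um^2, L_max=9.514 at r=60 nm
manifest: demo_out/manifest.json
```

Each sheet carries ~250 gold particles (~250/µm² labeling density). L_max
around 9–11 — far above 1, the normalized 99% CSR confidence level —
says the patterns are very strongly clustered, with the signal peaking at
length scales of 50–60 nm, consistent with the simulated 20 nm cluster
dispersion (the L-statistic peaks at a few times the cluster radius). A
CSR pattern run through the same pipeline gives L_max scattered near 1.
`demo_out/` holds the per-sheet curves, the summary table, and a manifest
recording config, seed, and version for reproducibility.

The other stages work the same way from the command line, e.g.:

```
$ memnano simulate curve --kind melt --out melt.csv -p tm=55 --noise-sd 0.01 --seed 3
$ memnano curves tm melt.csv
Tm = 55.35 degC

$ memnano simulate curve --kind tract --out a.csv -p R=18
$ memnano simulate curve --kind tract --out b.csv -p R=80
$ memnano nmr tract a.csv b.csv --field 900
R_alpha = 18.000 s^-1, R_beta = 80.000 s^-1, delta_R = 62.000 s^-1, tau_c = 20.04 ns
```

or from Python:

```python
from memnano import spatial, synthgen
from memnano.core import Region

region = Region(1000.0, 1000.0)  # nm
grid = spatial.default_radius_grid()  # 1-240 nm
pattern, _ = synthgen.gen_cluster_pattern(
    synthgen.ClusterModel(n_clusters=50, region=region), seed=1
)
envelope = spatial.csr_envelope(pattern.n, region, grid, n_sims=1000, seed=2)
curve = spatial.l_curve(spatial.ripley_k(pattern, grid))
result = spatial.normalize_and_lmax(curve, envelope)
print(result.l_max, result.r_at_max)
```

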