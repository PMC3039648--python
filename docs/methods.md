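# Methods

## Spectral synthesis of fractional Brownian fields

A fractional Brownian field in D dimensions with Hurst exponent H has power
spectral density S(f) ∝ |f|^−(2H+D). The generators draw, for every lattice
wavenumber **k**, a coefficient

    A(k) = g · r^−(2H+D)/2 · e^{iφ}

with g ~ N(0, 1), φ ~ U[0, 2π), and r the Euclidean norm of the frequency
vector, then inverse-FFT and keep the real part. The squared magnitude then
has expectation r^−(2H+D), satisfying the spectral condition. The
proportionality constant of the spectral density is taken as 1; the absolute
scale of the output is arbitrary (consumers rescale, e.g. with
`normalize01`).

Two generators differ in how the coefficient lattice is assembled:

- **`generate_independent` (benchmark).** Every coefficient is drawn
  independently and the radius is computed from the raw coordinate indices
  k_d ∈ {0..n−1}. Both choices are faithful to the classic recipe and both
  are defects: the lattice violates the conjugate-symmetry condition
  required for a real inverse transform, so discarding the imaginary part
  loses half the signal, and the power concentrates near the index origin
  rather than the frequency origin. Together they produce the well-known
  diagonal "smearing": the distribution of I(45°) − I(135°) at distance 1 is
  strongly shifted away from zero (median ≈ −0.21 at H = 0.1 in the
  comparison experiment below). The generator exists only as a comparison
  baseline.

- **`generate_symmetric` (corrected).** Radii are computed from *folded*
  signed frequencies (f_d = k_d if k_d ≤ n/2, else k_d − n; Nyquist folds to
  +n/2), so the two members of a conjugate pair share one spectral
  magnitude. The lattice is then made exactly conjugate-symmetric:
  A(k*) = conj(A(k)) with k*_d = 0 if k_d = 0 else n − k_d; self-paired
  coefficients (every component 0 or n/2) keep only their real part; the
  zero-frequency coefficient is zeroed, which pins the output mean to
  exactly 0. The inverse transform is then real up to floating rounding
  (imaginary RMS ≲ 1e−16 of the real RMS; the invariant asserted everywhere
  is ≤ 1e−9) and the field is isotropic.

**Randomness and reproducibility.** One `numpy.random.Generator` seeded from
the user's seed; draws are consumed in a fixed documented order — a full
row-major lattice of normal draws, then a full row-major lattice of phases.
Symmetrisation is deterministic: of each conjugate pair, the member with the
lower row-major rank keeps its own draw and the other receives the exact
conjugate, so equal seeds give bit-identical landscapes. The two generators
consume the same draws, so on a given seed the corrected output is exactly
the symmetrised counterpart of the benchmark output.

**Grids.** Side lengths are powers of two (exact FFT sizes) and equal in
every dimension — unequal extents would scale the spectrum differently per
axis and confound the per-dimension autocorrelation. Arbitrary extents are
obtained by generating the smallest covering power-of-two cube and cropping
(`compose.crop` / `generate_for_extent`); cropping keeps the low-index
window, never changes retained values, and clears the periodic flag.
Inverse transforms use the 1/N normalisation convention.

**Dimension-specific Hurst exponents.** The exponent applied to a
coefficient at folded frequency f is the weighted average
Σ_d |f_d| H_d / Σ_d |f_d|. The weighting function is a modelling choice:
|f_d| weights make a coefficient aligned with one axis feel that axis's
exponent alone and interpolate linearly in between, and they collapse to the
scalar H when all H_d are equal. The per-dimension exponents themselves are
constant across the lattice, so the field remains stationary. A 3-D field
with H = (0.9, 0.9, 0.1) read as (space, space, time) gives a time series
of smooth maps that decorrelate quickly between snapshots; raising the
temporal exponent to 0.9 makes consecutive snapshots strongly correlated
(asserted as a mean slice-to-slice correlation contrast over 10 seeds at
64³).

## Hurst estimation

`estimate_hurst` regresses log mean periodogram power on log frequency
radius: bins are rounded integer radii, bins with radius < 1 (DC) or > n/4
(aliasing-prone corners) are excluded, and H = −(slope + D)/2. The abscissa
of each bin is the log of the *mean radius within the bin*, not the bin
label: the power law is convex in r, so the label version biases the slope
flat (Ĥ low by ≈0.05 at n = 128). Recovery at n = 128 over 20 seeds is
0.085 / 0.490 / 0.896 for generating H = 0.1 / 0.5 / 0.9. Estimates outside
(0, 1) are returned with a warning — they indicate the input is outside the
fBm family (white noise has a flat spectrum, hence Ĥ ≈ −D/2).

## Binary neutral models

All selections are **exact counts** (round-half-to-even of p × pool size),
never Bernoulli trials, so realised habitat proportions are deterministic.

- `random_percolation`: round(h·N) cells chosen uniformly without
  replacement.
- `curdle`: hierarchical curdling. A plan is a strictly nested sequence of
  (tile side, proportion) stages ending at cell resolution; at each stage
  every selected parent tile selects an exact count of its children
  uniformly at random. The overall proportion is the product of stage
  proportions, and the final count is seed-independent: the reference
  three-stage design on 512² (64-cell tiles at 0.75, 8-cell tiles at 0.75,
  cells at 0.5) always yields 73 728 suitable cells (≈28%).
- `threshold_by_rank`: the k highest-valued cells of a continuous landscape
  become habitat; ties break by flattened row-major index (stable and
  deterministic; ties are measure-zero for continuous surfaces).

## Directional Moran's I on the torus

Spectral-synthesis landscapes are periodic, so autocorrelation is measured
on networks wrapped into a torus. For each direction θ ∈ {0°, 45°, 90°,
135°} (clockwise from the x-axis: vertical, SW–NE diagonal, horizontal,
SE–NW diagonal; rows are the y-axis), the step map partitions the n×n torus
into n disjoint cycles of length n. Distance is the **hop count along the
cycle** (minimum of the two wrap directions, classes 1..n/2 — beyond n/2
wrap distances repeat), so diagonal class d means d diagonal steps
(Euclidean d·√2); this compares like classes across directions, as distances
are measured along the links.

Moran's I uses identity weights w_ij(d) = 1 iff cells i, j are exactly d
hops apart on their shared cycle. On a cycle cover the double sum reduces to
Σ_i z_i z_{i+d} / Σ_i z_i² (deviations z from the global mean): for
d < n/2 each unordered pair is counted once against S₀ = 2N; at d = n/2
each pair twice against S₀ = N; the ratio is identical. The implementation
is verified to 1e−12 against a literal double-loop evaluation of the
formula, and satisfies the randomisation expectation E[I] = −1/(N−1),
exact rotation/translation symmetries on the torus, and I(1) = −1,
I(2) = +1 on a checkerboard.

**Significance.** The reference analysis marks correlogram points against a
random-landscape null; the construction here is a permutation test (default
M = 999 relabellings of the cell values): empirical p = (r+1)/(M+1) with r
the count of permuted statistics at least as extreme in the smaller tail,
and "high"/"low" flags at the α/2 empirical quantiles.

**Anisotropy statistics.** Δ_cardinal = I(0°) − I(90°) (positive: stronger
north–south than east–west autocorrelation) and Δ_diagonal = I(45°) −
I(135°), per distance class. An isotropic generator centres both on zero
over replicates.

## The comparison experiment

`run_experiment` reproduces the generator comparison at its study
conditions, which are the defaults: both generators × H ∈ {0.1, 0.5, 0.9} ×
100 replicates on 32×32 lattices (600 landscapes, 1024 cells each).
Replicate r of combination c uses seed `base + c·10⁶ + r`, so any single
landscape is reproducible in isolation. Per replicate the four correlograms
are computed for d = 1..16 and reduced to the two Δ statistics; per
combination the replicate distributions are summarised by median, type-7
quartiles, full range, and the McGill notch `median ± 1.58·IQR/√m` (a rough
95% CI for the median under asymptotic normality; 1.58 is the standard
Tukey boxplot constant). The full experiment runs in a few seconds; the
headline contrast (benchmark diagonally anisotropic at H ≤ 0.5 by sign
test at p < 0.01, corrected generator consistent with zero, cardinal
medians near zero for both with a wider benchmark IQR at H = 0.1) is
asserted property-based in the acceptance tests, since the reference
results are reported only as box plots.

## Serialisation and CLI

Grids are plain text: CSV matrices (rows = y, columns = x) and ESRI ASCII
rasters for 2-D, and a flat format (extent line, then one value per line,
row-major) for any dimensionality. Floats are written with 17 significant
digits, so CSV/flat round trips are bit-exact. Files read back are flagged
non-periodic, since periodicity cannot be inferred from a file. The CLI is a
thin layer over the library (`generate`, `classify`, `correlogram`,
`experiment`, `compose`); a YAML/JSON config may supply any option with
explicit flags taking precedence, and every run logs its parameters and
seed at INFO level.

## What the synthetic landscapes do and do not show

The generators emulate stationary, periodic, Gaussian self-similar fields
with power-law spectra — a null model, not a model of any real landscape.
Real landscapes are at best fractal-like over limited scale ranges,
non-Gaussian, non-stationary (gradients, anisotropic physical processes) and
non-periodic. Passing tests therefore certify the statistical properties of
the generator (symmetry, spectrum, isotropy, exact counts), not ecological
realism; gradient composition and cropping are the provided bridges toward
more realistic scenarios.

## Numerical choices and degenerate inputs

- Conjugate symmetry is exact (bitwise), not approximate; the imaginary
  residual bound 1e−9 is asserted on the inverse transform.
- Moran's I, Hurst estimation, and normalisation reject constant
  landscapes; `amplitude` and `composite_hurst` reject the zero-frequency
  vector, which generators special-case to 0.
- Rounding of selection counts is half-to-even throughout `classic`.
- Test problem sizes (n = 128 for recovery, 64³ for the spatio-temporal
  contrast, the full 600-landscape experiment) were chosen as the smallest
  sizes at which the corresponding statistical contrasts are stable.

## Known limitations

- Midpoint-displacement generation is deliberately out of scope (inferior
  approximation to fBm, unwieldy beyond 2-D).
- Non-power-of-two transforms are not performed; arbitrary extents always go
  through generate-and-crop.
- The permutation test is a generic null construction; no analytic
  variance-based z-test is exposed (the randomisation mean is available as
  a property check only).
- The diagonal distance convention (hops, not Euclidean units) makes
  diagonal and cardinal classes comparable by link count, not by metric
  distance.
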