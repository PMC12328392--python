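# Methods

This note documents the models implemented in `fpchem`, the choices made
where the design was genuinely open, and what the synthetic datasets do and
do not establish.

## Study design emulated by the generator

The synthetic module (`fpchem.synth`) emulates a two-species
fingerprinting study: 2 species × 20 methanolic extracts × duplicate
injections, detector traces at 254, 280 and 330 nm on a uniform
13.2–64.5 min window sampled every 0.4 s (2.5 Hz, 7696 points with
inclusive endpoints — the sampling rate is inferred from the window span
and point count, as only those two are documented for the instrument).

Each trace is

```
A(t) = g · Σ_k a_k(species) · f_{e,k} · λ_k(wavelength) · exp(−(t − r_k)² / 2σ_k²)
       + drift(t; wavelength) + ε(t)
```

- **Peak library** — 10 shared peaks (equal amplitude in both species,
  0.2–1.0 AU) and 5 species-specific peaks per species (0.7–1.3 AU, zero
  in the other species), widths σ = 0.08–0.25 min, retentions ≥ 0.8 min
  apart. Three peaks are flagged *active* and re-placed inside the
  20–35 min region: one shared (emulating the vitexin region at 330 nm)
  and two specific to the high-activity species (emulating tannic and
  chlorogenic acid at 280 nm). Species-specific amplitudes were set high
  enough that between-species structure dominates extract-to-extract
  variability, which is what the downstream clustering contracts
  (dendrogram purity, CCC ≥ 0.968, Hopkins ≤ 0.17) assume of the real
  system.
- **Extract factors** *f<sub>e,k</sub>* — lognormal, sd 0.2 on the log
  scale, independent per extract and peak: the smallest structure that
  makes duplicate injections nearly identical while extracts differ.
- **Injection factor** *g* — normal, sd 0.01: a global per-injection scale
  (injection-volume variation). Together with detector noise
  ε ~ N(0, 0.002 AU) i.i.d. per point, this calibrates the duplicate
  Pearson correlation far above the 0.93 reproducibility gate.
- **Drift** — a slow sine (period 35–55 min) plus linear and quadratic
  terms, amplitude 0.05 AU (≈5 % of the largest peaks), deterministic per
  wavelength so that blanks and samples share it, emulating mobile-phase
  composition change and stationary-phase bleed.
- **Ground truth** — the latent antioxidant level of an extract is the
  unit-weight sum of its active-peak amplitudes (simplest recoverable
  target for marker assignment). The four assay columns are affine maps of
  the latent level onto realistic mg GAE / mg TE per g dry weight scales,
  plus independent method noise with sd equal to 10 % of the latent sd.
  When a configuration plants no active peaks the latent level is
  degenerate; the assay noise then falls back to the same fraction of a
  unit latent scale so the panel remains a valid readout.

What the generator does **not** model: detector saturation and nonlinear
response, co-elution and peak-shape asymmetry, retention-time drift
between runs (high replicate correlations are what justify skipping
alignment, and the generator reproduces that regime rather than testing
it), spectral (wavelength-continuous) structure, and any real assay
chemistry. Passing tests therefore demonstrate correctness of the
*analysis* under the stated statistical structure, not robustness to
misaligned or saturated chromatograms.

## Preprocessing

Stages run in the order blank subtraction → reproducibility gate →
consolidation → baseline correction → window cropping. Ordering baseline
correction before cropping was chosen so the suppression windows can use
context beyond the analysis window when it exists; the two orders differ
only near the window edges, and the test suite asserts this as a
documented non-equivalence rather than an identity.

- **Reproducibility gate** — per extract, the minimum pairwise Pearson *r*
  over its (blank-subtracted, full-trace) replicates; extracts below the
  0.93 threshold are reported with a warning but the pipeline never
  aligns peaks (out of scope by design). Constant traces raise an error
  rather than propagating NaN.
- **Consolidation** — pointwise mean of the duplicate injections per
  extract (the per-extract traces feeding clustering and regression); a
  separate pointwise group-median operation provides the per-species
  median trace used for visualization-style summaries.
- **Baseline** — an iterative local-suppression estimator in the spirit
  of R's `baseline::fillPeaks`. Each pass replaces the working trace by
  `min(b_i, max(avg2_i, avg4_i))` where `avg2 = (b[i−m] + b[i+m])/2` and
  `avg4 = (4(b[i−m] + b[i+m]) − (b[i−2m] + b[i+2m]))/6`, over half-widths
  shrinking geometrically from 2.0 min to 0.2 min across 8 passes, with
  quadratic Savitzky–Golay smoothing (0.2 min window, edge-exact
  polynomial fitting) before and after. `avg4` is exact for cubic
  backgrounds, so curved drift is tracked without the O(κm²) undershoot a
  plain two-point average accumulates; `avg2` guards against the
  four-point stencil's negative lobe next to tall peaks. The defaults
  (2.0 min initial half-window, 8 passes, 0.2 min smoothing) leave a
  0.1-min-σ peak untouched while removing 35–55-min-scale drift; on a
  noiseless ramp-plus-Gaussian input the corrected peak area is exact and
  the operation is idempotent to machine precision. Corrected values are
  not clipped at zero, keeping correlation computations unbiased.

## Similarity and cluster validation

Distances are 1 − Pearson *r* between fingerprints. For the reported
dendrograms an elementwise square root compresses the distances (monotone,
so memberships at any cut are unchanged); Ward linkage follows the
ward.D2 convention (inputs treated as distances, objective on their
squares — `scipy.cluster.hierarchy` provides the agglomeration, with a
brute-force greedy Lance–Williams oracle in the test suite). The CCC is
computed against the matrix actually clustered, i.e. the transformed one.
A nuance worth recording: a dendrogram reproduces an ultrametric input
exactly under average-type linkages, but Ward's update inflates heights
for ultrametrics with three or more levels; the exact CCC = 1 property is
therefore asserted on two-level ultrametrics, where it holds for Ward too.

The Hopkins statistic follows the near-zero-is-clusterable orientation:
with w the nearest-real-neighbour distances of m sampled real points and u
those of m uniform points in the bounding box, H = Σw/(Σw + Σu), m =
max(5, ⌊0.1·n⌋). It is computed on 2-dimensional PCA scores — uniform
reference sampling in the raw 7696-dimensional bounding box is
meaningless — and fingerprint rows are standardized (per-trace centre and
scale) before the projection, giving the statistic the same invariance to
per-sample offset and overall intensity that the correlation distance has;
raw coordinate arrays are projected without row standardization.

## Antioxidant indices

Assay panels carry total polyphenols (mg GAE/g DW) and DPPH/ABTS/FRAP
(mg TE/g DW). Standard scores use the sample (n−1) standard deviation,
jointly over all samples. The RACI is the row mean of the z-matrix; the
PC1 variant takes the first right singular vector of the z-matrix
(unit-norm loadings oriented to a positive sum) and scores z·v. When the
four columns are equally intercorrelated the two indices coincide up to a
positive factor (R² = 1); on the default panels the agreement R² exceeds
0.999 and all four loadings fall in [0.4, 0.6]. Hypothesis testing for
the species contrast is out of scope; only the direction and magnitude of
the group means are reported.

## PLS, OPLS and marker assignment

PLS1 uses NIPALS with the deterministic start w ∝ X'y (stationary after
one inner pass for a scalar response; the loop still checks convergence
and would fail loudly at 500 iterations), deflating both X and y, with
coefficients B = W(P'W)⁻¹q reproducing the sequential predictions exactly.
X is mean-centred by default — standard for chromatographic profiles where
the absorbance scale is already common — with autoscaling available as an
option. OPLS extracts orthogonal components with weight
w_o ∝ p − (w'p)w; orthogonal scores are exactly uncorrelated with y by
construction, the predictive weight direction is unchanged by the
orthogonal deflations, and the sequential filtering is folded into a
single coefficient vector, so OPLS with k orthogonal components predicts
identically to (k+1)-component PLS (asserted to 1e-8 over random
instances). Default component counts are 2 latent variables for PLS and
1 predictive + 1 orthogonal for OPLS.

Leave-one-out cross-validation refits (and re-centres) inside every fold;
Q² = 1 − PRESS/TSS with TSS about the full-data mean. Both MSE and RMSE
are reported explicitly to avoid the recurring ambiguity between the two;
RPD is the sample sd of y over the relevant RMSE, with +inf as the
perfect-fit sentinel.

Markers are maximal runs where B exceeds 0.1 × max(B), at least 0.1 min
wide — only positive coefficients, since compounds tracking the
antioxidant index have positive coefficients; the thresholds are package
defaults chosen in the absence of a published numeric rule. Apexes are
matched to the standards table within 0.5 min at the matching wavelength.

## Problem sizes and numerical choices

Default analyses use the full 40-sample × 7696-point matrices at 280 and
330 nm. Seed-replicated checks (RACI agreement, marker recovery, CV
inequalities) use 20–50 generator seeds; Hopkins medians use 50 sampling
seeds. Grid uniformity is enforced to 1e-9 min; distance-matrix symmetry
to 1e-12; score orthogonality and the OPLS/PLS equivalence to 1e-8. Ties
in agglomeration are resolved by scipy's deterministic ordering, and every
random draw in the package flows from an explicit integer seed, so all
reported numbers are exactly reproducible.

## Known limitations

- The marker rule is interval-based; heavily overlapping peaks would merge
  into one interval and co-eluting inactive compounds cannot be separated.
  Retention-time matching suggests, but cannot establish, compound
  identity — structural confirmation needs mass spectrometry.
- With only ~5 probe points (m = 0.1·n at n = 40) the Hopkins statistic is
  noisy; medians over many sampling seeds are reported for that reason.
- The reproducibility gate warns rather than excludes; automatic exclusion
  would change downstream sample counts and is left to the caller.
- External data must arrive on a common uniform grid (a linear-interpolation
  resampler is provided); no retention-time warping is implemented.
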