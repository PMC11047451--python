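# Methods

`meegsi` implements a desk-scale electrophysiological source imaging (ESI)
chain: surface geometry, analytic forward models with a numerical
quality-control (QC) loop, Hermitian cross-spectral estimation, geometrical
priors, regularized cross-spectral inverse solvers, and a between-modality
comparison statistic. This note documents the models, the conventions and
defaults, and what the synthetic study does and does not emulate.

## Geometry

Surfaces are closed, outward-oriented triangular meshes in SI meters.

**Vertex normals** are area-weighted averages of incident face normals.
**Mean curvature** uses the cotangent Laplace–Beltrami operator with mixed
(Voronoi) vertex areas, falling back to barycentric thirds where the Voronoi
cell degenerates; the sign convention makes convex (gyral-crown-like) regions
positive with outward normals, so a sphere of radius R has H ≈ +1/R
(verified to better than 0.1 % on icosphere fixtures).

**Decimation** is iterative edge collapse driven by quadric error with a
link-condition guard, so closed genus-0 meshes stay closed and genus-0. The
collapsed vertex takes the quadric-optimal position, guarded against
ill-conditioned solves by a midpoint fallback.

**Geodesic distances** are shortest paths on a chord-length graph over the
1- and 2-ring vertex neighborhoods (Dijkstra). Including second-ring chords
reduces the metrication bias of pure edge-graph Dijkstra from several percent
to under 0.1 % on icospheres; path lengths always dominate the straight-line
distance, but may slightly undercut the exact polyhedral geodesic. This
trades a small, documented bias for determinism and simplicity — adequate
for interpolation weights, which only need a monotone distance ranking.

**Low-to-high interpolation** uses inverse-geodesic-distance weights to the
k = 3 nearest low-mesh vertices, normalized per row (a row-stochastic
operator: constants interpolate exactly); a coincident vertex takes weight 1.

**Graph Laplacian**: combinatorial L = D − A; the deformed variant is
L + εI, which is full-rank for ε > 0 and converges uniformly to L as ε → 0.
Its inverse (or Moore–Penrose pseudoinverse at ε = 0) is the standardization
factor of the smoothness prior.

**Outward warp** (the distance correction): vertices within a smoothing
radius (default 2 cm) of an offending source point are pushed along their
normals with a cosine taper, overshooting to 110 % of the minimum distance so
corrected points clear the strict below-threshold flag; vertices outside the
radius never move, and the warp stops short (flagging the case incorrigible)
if it would cross a supplied outer shell.

## Forward models

All EEG lead fields are dense real matrices, sensors in rows, in V/(A·m),
average-referenced by default (zero column mean).

* **Homogeneous (boundary-free)**: the infinite-medium dipole potential
  V(r) = q·(r−r₀)/(4πσ‖r−r₀‖³). Any positive σ gives the same QC
  correlations (Pearson r is scale-free); the default is the brain value
  0.33 S/m.
* **Three-shell concentric spheres**: per-degree Legendre series with the
  radial two-point boundary problem solved by a small linear system per
  harmonic. Radii are nondimensionalized by the outer radius so the powers
  rᵑ, r⁻⁽ⁿ⁺¹⁾ stay bounded — without this the solve is catastrophically
  ill-conditioned beyond n ≈ 60. The default truncation is 60 terms; the
  tail decays geometrically as (b·R₁/R₃)ⁿ, convergent to ~1e-6 relative at
  the fixture eccentricities and to 1e-8 by 80 terms at eccentricity 0.8.
  Oracles: equal conductivities reproduce the single-sphere series to
  machine precision, and a central dipole matches the closed form
  3q·cosθ/(4πσR²).
* **Spherical MEG magnetometer**: the closed-form spherical-conductor
  solution; independent of the conductivity profile, with purely radial
  dipoles silent to machine precision.
* Defaults: conductivities 0.33 / 0.0042 / 0.33 S/m (brain, skull, scalp)
  and shell radii 0.082 / 0.088 / 0.092 m with the cortex sphere at
  0.079 m — conventional textbook values, configurable in JSON.

Realistic boundary-element models are deliberately out of scope: the QC is
forward-model agnostic, and externally computed lead fields can be imported
through the HDF5 + JSON container.

## Lead-field quality control

The quality index correlates a tested lead field against the homogeneous
baseline in two modes: per sensor across all sources (row-wise) and per
source across all sensors (column-wise), both Pearson with mean removal.
Zero-variance rows or columns are reported undefined and flagged rather than
assigned r = 0. Flagging is strict-below: sensors < 0.7, sources < 0.33
(boundary values pass); a configurable `flag_mode` decides whether either
mode alone flags (default) or both must. Sources closer than 2 mm (default,
configurable) to the inner skull are flagged geometrically.

The automatic loop computes the tested lead field, evaluates correlations
and distances, warps the inner skull outward where distance flags exist,
recomputes, and stops at the first clean pass or after `max_iterations`
(default 3), labeling unresolved cases incorrigible rather than pausing for
manual input. A packaged spherical template model can substitute an
incorrigible individual model, with provenance recorded as `template`.

## Spectral estimation

Three transforms produce complex coefficients per channel, frequency and
sample:

* **FFT**: non-overlapping windowed segments; coefficients scaled so the
  one-sided squared moduli sum to the segment energy (interior bins carry
  √2). One coefficient per segment per bin.
* **GF-HT**: per target frequency, the analytic signal of the series
  filtered by a frequency-domain Gaussian centered there. "Bandwidth" means
  two standard deviations of that Gaussian (the convention is a package
  choice). One coefficient per time point; the per-frequency mean power
  converges to the FFT periodogram as the bandwidth shrinks.
* **BF-HT** (default): zero-phase order-4 Butterworth band-pass plus Hilbert
  transform per band; the default partition is delta 0.5–4, theta 4–8,
  alpha 8–13, beta 14–30 and gamma 30 Hz to 0.9 × Nyquist — five slices.

Cross-spectral slices are S_f = (1/m) Σ z z^H (coefficients are zero-mean by
construction; no mean subtraction), Hermitian PSD by construction, with the
sample count m recorded. The default analysis grid is 0–50 Hz at 0.5 Hz
excluding DC: 100 frequencies.

## Priors

Each prior is a standardization of the design matrix with a recorded inverse:

1. **Rotational invariance** ("field"): project the free-orientation lead
   field onto the normals, solve the scalar problem, lift the solution back
   to 3×3 blocks n_i S_ij n_jᵀ, take each source's principal spectral
   direction, and re-project. No explicit angular density is evaluated; the
   decreasing-with-sagittal-angle preference is implicit in the
   standardize/de-standardize route.
2. **Curvature depth compensation**: column weights
   w = intercept + slope·H with separate gyral (H ≥ 0) and sulcal (H < 0)
   branches; H = 0 takes the gyral branch. Defaults slope 0.5 / intercept
   1.0 on both branches — exposed in config; these are package defaults, not
   empirically optimized values.
3. **Graph-Laplacian smoothing**: L ← L·(Lap + εI)⁻¹, estimates mapped back
   through the same factor; default ε = 1e-3.
4. **Parcellation**: label groups share one scale hyperparameter in the
   sparse Bayesian solver; singleton labels reduce exactly to the ungrouped
   solver.

Composition order is curvature → Laplacian → rotational invariance (column
scalings, then smoothing, then orientation reduction); the order is a design
choice and is recorded in the standardization object.

## Inverse solvers

**Type one — structured sparse Bayesian learning.** Per frequency slice,
the model is v ~ CN(0, L Γ Lᴴ + σ²I) with Γ = diag(γ). γ is iterated with
the MacKay fixed point (posterior mean power over the learning fraction
λ = diag(TL)), with the elastic-net penalty α₁Σ√γ + α₂Σγ folded into each
coordinate's scalar problem and solved by a safeguarded Newton iteration.
The plain EM update (γ ← posterior second moment) also converges here but
needs several times more iterations; MacKay is the default for its pruning
speed. On convergence the solver returns the quasilinear operator
T = Γ Lᴴ (L Γ Lᴴ + σ²I)⁻¹, the posterior source cross-spectrum
T S_vv Tᴴ + (Γ − T L Γ), the scales, and a support mask.

σ² defaults to the mean of the smallest ⌈N/4⌉ eigenvalues of the data slice.
The support statistic is the posterior concentration λ_i = diag(TL)_i ∈
[0, 1] (the fraction of the prior scale pinned by the data), thresholded at
0.95 by default — a convention, not a calibrated probability. Because the
log-likelihood keeps every γ interior (never exactly zero), thresholded
support sizes are not guaranteed monotone in α₁; the guaranteed monotone
consequence of the penalty is shrinkage of the total scale mass Σγ, which is
what the suite asserts.

**Type two — Hermitian graphical models.**

* HGRidge: the unique PD stationary point of −logdet Θ + tr(SΘ) +
  (α/2)‖Θ‖²_F shares eigenvectors with S and has eigenvalues
  (−d + √(d² + 4α))/(2α) — closed form, cross-checked in the suite against a
  gradient-based optimizer on the real parameterization.
* HGLASSO: −logdet Θ + tr(SΘ) + α Σ_{i≠j}|Θ_ij| with the ℓ1 on complex
  moduli (phase-rotation invariant) and an unpenalized diagonal, solved by
  ADMM (Θ-step by eigendecomposition, Z-step by modulus soft-thresholding),
  to a primal/dual residual tolerance of 1e-8. α = 0 short-circuits to the
  inverse; α above the largest off-diagonal modulus provably yields the
  exact diagonal solution.

**Two-step / one-step.** Two-step applies HGLASSO/HGRidge to the
(support-restricted) source cross-spectrum of a type-one solve; off-support
entries are zero. One-step runs EM on the sensor cross-spectrum:
E-step posterior source cross-spectrum under v ~ CN(0, L Θ⁻¹ Lᴴ + σ²I),
M-step graphical solve on it; the penalized marginal objective is tracked and
five consecutive increases raise an error. Restricted spectra are jittered by
1e-10 of their largest eigenvalue before inversion.

**Baselines.** eLORETA iterates w_i = √(l_iᵀ K⁺ l_i) with
K = L W⁻¹ Lᵀ + reg·(tr/N)·I — the regularization is relative to the
covariance scale, which keeps the fixed point resolvable in double precision
(with an absolute tiny reg the iteration hits a ~1e-7 noise floor set by the
condition number). At the default reg = 1e-8 it attains exact localization
for all noiseless point sources on the 500-source fixture. LCMV rows are
l_iᴴC⁻¹/(l_iᴴC⁻¹l_i) (unit gain). Argmax ties break to the lowest index.

## Synthetic study

The generators are pure functions of their arguments and a seed.

* **Geometry**: nested icospheres (cortex 0.079, inner skull 0.082, outer
  skull 0.088, scalp 0.092 m); the 19-electrode 10–20 layout from the
  standard angular coordinates projected to the scalp; a 500-source cortex
  as the upper cap (top 500 of a ~1000-vertex decimation, re-projected to
  the cortex radius). The cap choice reflects anatomy — cortical sources lie
  under the electrode cap; full-sphere "cortices" put sources antipodal to
  every electrode, where tested-vs-homogeneous correlations genuinely
  collapse and no QC threshold is meaningful.
* **Oscillatory networks**: spectral synthesis — complex Gaussian Fourier
  coefficients drawn per bin with the prescribed cross-spectral density
  (Gaussian band profile × Hermitian coherency target + white floor),
  Hermitian-symmetrized and inverse transformed. The theoretical
  cross-spectral tensor is therefore exact, not asymptotic; the FFT
  estimator is unbiased for it up to resolution smoothing, so tensor
  comparisons in the suite aggregate over a band. Defaults: alpha center
  10 Hz, bandwidth 2 Hz, unit amplitude, noise floor 0.05, 200 Hz sampling.
* **Sensor projection**: v = Lj + white noise scaled to a requested
  broadband SNR (default 10 dB).
* **Artifacts**: inner-skull dents (vertices pulled to 0.5 mm of target
  cortex points), tangential sensor jitter (electrodes slide along the
  scalp; radial jitter is physically impossible for attached electrodes),
  noise-replaced lead-field columns, and mesh blur. The "tested" lead field
  of the QC fixture is the three-shell model with deterministic pseudo-noise
  added to columns of sources closer than the critical distance to the inner
  skull — emulating the numerical instability of boundary integration near
  touching surfaces, which is exactly the failure mode the distance
  criterion exists for.
* **Paired spectra tensors**: EEG log-normal, MEG = e^{a_f}·EEG^{b_f}·e^ε
  with defaults a = 1.5, b = 0.8, ε of SD 0.1 — the generative reading of
  the scaling-regression model.

What passing these tests shows: the estimators and solvers are correct on
linear, stationary, Gaussian data with spherical geometry and exactly known
ground truth. What they do not show: robustness to real anatomy (folded
cortices, BEM numerics), nonstationary or nonlinear dynamics, real sensor
noise spectra, or preprocessing artifacts.

## Comparison statistics

Log spectra are regressed per frequency (MEG on EEG, pooling sources and
cases); the intercept a_f is the acquisition-dependent power scale and the
slope b_f the spatial-decay contraction. The permutation test then compares
MEG residuals against slope-scaled, case-centered EEG residuals: the
statistic per (source, frequency) cell is the two-sample mean difference over
its pooled standard error; whole cases are the permutation unit (modality
labels shuffled across the pooled 2C cases); family-wise control comes from
the (1 − α) quantile of the permutation null of the maximum absolute
statistic over every cell. Testing residuals (rather than rescaled spectra)
is the package's reading; the alternative is one switch away. Per-band maps
OR the significant cells across in-band frequencies. Calibration: on null
fixtures at reduced scale (100 × 5 × 15, 500 permutations, 200 replications)
the empirical family-wise error at α = 0.01 lands near 0.015 — within
binomial tolerance.

## Numerical conventions

* Hermitian inputs are validated to 1e-8 relative and symmetrized before
  eigendecompositions; PSD slices tolerate eigenvalues down to −1e-10
  relative.
* Millimeter sensor layouts are auto-detected (any coordinate above 1.5)
  and converted with a logged warning.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; every CLI command takes `--seed` and its
  numeric outputs are byte-reproducible.
* Fixture problem sizes (500 sources, 19 sensors, m = 200 spectral samples,
  10-node graphs with m = 2000, 200-replication calibration) are the
  package's standard desk-scale study; they were chosen so every recovery
  target is met with margin under the default conditions.

## Known limitations

* The deformed Laplacian is realized as the convergent shift L + εI; other
  deformations with the same ε → 0 limit exist.
* The three-shell model is a sanity-scale stand-in for realistic conductor
  models, not a replacement.
* SSSBL support is a thresholded concentration statistic, not a posterior
  probability with frequentist calibration.
* The one-step graphical EM has no global convergence guarantee; it
  monitors its objective and raises on sustained increase.
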