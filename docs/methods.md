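# Methods

This note documents the models and procedures implemented in `ramanld`,
the parameter choices that matter, and what the synthetic data do and do
not establish about real measurements.

## Spectrum model and preprocessing

A lipid-droplet (LD) Raman spectrum is a strictly increasing wavenumber
grid with finite intensities and sample metadata (cell line, methionine
level, insulin level, cell id, droplet id). Preprocessing follows the
measured-background convention of confocal Raman microspectroscopy: a
background trace acquired per droplet at the droplet's focal plane is
subtracted pointwise (no baseline is fitted), after which spectra are
normalized.

Three normalizations are provided and freely chainable, with the chain
recorded in metadata:

* **vector** — unit Euclidean norm; standard chemometric scaling.
* **simplex** — closure to sum one. If negative intensities are present
  (possible after background subtraction) the minimum is first shifted
  to zero; the shift is recorded and warned about. We read "simplex" as
  sum-to-one closure — the usual meaning for compositional spectra — and
  flag this as an interpretive choice.
* **peak@ν** — division by the intensity at the grid point nearest ν
  (typically the 2940 cm⁻¹ protein band), used for ratiometric work.

Order of operations is a configuration, not a hard-coded rule; the
drivers use background → vector → simplex for clustering/entropy inputs
and peak@2940 alone for ratio panels. Negative residuals after
background subtraction are retained (except under simplex closure) so
that downstream Gaussian noise models see undistorted statistics.

Band intensities for ratios are the maximum within ±5 cm⁻¹ of the named
position, absorbing 1–2 cm⁻¹ calibration jitter. Peak *normalization*
anchors the nearest grid point itself so that the anchored point equals
exactly 1.

## Relative-entropy wavenumber ranking

At each wavenumber the per-class intensity distribution is modelled as a
Gaussian with the class sample mean and Bessel-corrected SD. Class SDs
are floored at 10⁻⁶ of the set's global intensity range; otherwise a
degenerate class (identical spectra) would yield infinite divergence.

For a pair of classes the two Gaussians are discretized on a shared
support spanning both means ± 6 max-SD (covering all but ~10⁻⁹ of the
mass, so the probability floor is immaterial), on `L` equal bins:
`p_i ∝ exp(−(c_i − μ)²/2σ²)`, floored at 10⁻³⁰⁰ and renormalized. The
score is the symmetric Kullback-Leibler divergence; for k ≥ 3 classes
(three insulin levels) it is the average pairwise divergence
`1/(k(k−1)) Σᵢ≠ⱼ D_KL(Pᵢ‖Pⱼ)`, which reduces exactly to the symmetric
form at k = 2. The 2 (methionine) × 3 (insulin) design is ranked one
factor at a time; no entropy score is defined for the interaction.

**Vector length.** The default is `L = 10⁵`; `L = 10⁷` is accepted for
full-scale runs. Against the closed-form Gaussian KL
(`ln(σ₂/σ₁) + (σ₁² + Δμ²)/(2σ₂²) − ½`) the discretized pipeline agrees
to ~10⁻⁷ relative error already at 10⁵ bins across SD ratios in
[0.5, 2] and mean gaps up to 3 SD, so the longer vectors change nothing
at reporting precision while costing 100× the memory and time.

**Profile evaluation.** The per-wavenumber profile is computed by the
same discretize → floor → renormalize → sum pipeline, evaluated in the
log domain in float32, chunked over wavenumbers. Cells whose probability
underflows float32 carry ≲10⁻³⁸ mass and contribute nothing at
reporting precision; a unit test pins the chunked profile to the
float64 modular pipeline at 10⁻⁴ relative tolerance.

**Small-sample bias.** The plug-in symmetric KL of two fitted Gaussians
is biased upward by roughly 2/n per class pair under the null (n spectra
per class). At the study's n = 25–50 this floor is ~0.04–0.08 nats with
per-grid maxima of a few tenths; genuine band effects of ≥ 2 noise-SD
score in whole nats. Rankings are therefore meaningful, but absolute
small scores near the 2/n floor are not evidence of an effect.

## Pseudo-Voigt unmixing

Overlapping bands are fitted as sums of Gaussian-Lorentzian blends
`h·[η/(1+4u²) + (1−η)·exp(−4 ln 2 · u²)]`, `u = (ν−ν₀)/FWHM`, with one
shared FWHM per component — the common "GL blend" parameterization with
unit height at the center for any mixing η. Fitting is bounded least
squares (centers inside the window, h ≥ 0, FWHM ∈ [step/2, span],
η ∈ [0, 1]); auto-initialization takes the n most prominent local maxima
of a lightly smoothed trace, with widths from width-at-half-prominence
and η = 0.5. Non-convergence is reported via a flag, not an exception.

Fit error % is defined as `100 · Σ|residual| / Σ|data|` over the window
(an RMS-based alternative is selectable, since published error
percentages often leave the convention unstated); R² is
`1 − SS_res/SS_tot`. Default windows bracket the Amide II′
(1380–1520 cm⁻¹) and Amide I / heme (1520–1700 cm⁻¹) regions. The number
of components is user-fixed; model selection is out of scope.

Peak prominence is the standard topographic definition on the 1-D trace
(baseline-invariant); width is measured at peak − prominence/2 with
linear interpolation.

## Ratio statistics

Ratios are computed per spectrum; non-positive denominators yield NaN
with an explicit `_defined` flag rather than dropped rows. Group
contrasts propagate SDs in quadrature (`√(SD_X² + SD_Y²)`).

The two-way ANOVA is the classical balanced decomposition via cell
means with sum-to-zero effect constraints — for a balanced design this
coincides with Types I/II/III, and a test pins it against a sum-to-zero
Type III OLS fit in statsmodels. Balance (equal n ≥ 2 per cell) is a
precondition, not a repaired condition; unbalanced inputs are rejected.
Each spectrum is a datum (observations pooled across trials); analysing
per-cell means instead is a caller-side aggregation. The all-equal
response is reported as 0/0 with a degeneracy flag. Simulation places
the interaction's type-I error at nominal level (0.03–0.07 band at
α = 0.05 over 2000 replicates of the 2×3, n = 5 null) and its power
above 0.8 for a one-error-SD interaction pattern at n = 25.

t-tests are two-tailed, Welch by default (variances across treatment
groups need not match), pooled on request. p-values are reported raw,
with optional Benjamini-Hochberg adjustment across a panel; marker
strings follow the 0.05/0.01/0.001/0.0001 convention.

## Classification and embedding

The classifier is scikit-learn's MLP with one rectified hidden layer of
100 units, softmax output, cross-entropy loss with L2 penalty
α = 2·10⁻⁴, Adam updates (step size `learning_rate_init`, default 10⁻³ —
the usual Adam default, since no published value constrains it), at most
200 iterations, on spectra min-max scaled to [0, 1] per spectrum.
Held-out accuracy uses a stratified, seeded 80/20 split. The embedding
is PCA (10 components) followed by t-SNE at perplexity 30 with early
exaggeration 1 (i.e. none) and PCA initialization; both stages are
deterministic given the seed. No accuracy target is attached to the
classifier — its checks are sanity bands (chance on null cohorts,
high accuracy on clearly separated ones).

## 3D morphometry and TPF quantification

**De-striping.** The scan artifact is additive and constant along the
fast-scan (x) axis, i.e. confined to the kx = 0 column of each slice's
2-D spectrum. Its per-row level is estimated with the median over x —
robust to bright sparse droplets, which would bias a mean — and the
deviation from the slice level is subtracted, removing all non-DC
row-constant frequencies. Gaussian smoothing (σ = 1 voxel default)
follows. On stripe-free phantoms the operation changes the stack by
< 2% relative RMS; on striped phantoms it removes > 90% of stripe-band
power.

**Segmentation.** Otsu (default) or fixed threshold, 26-connectivity
3-D labelling, minimum component size 27 voxels (suppresses noise
specks at the visible droplet scale). Volumes are reported in voxels
and µm³.

**Sphericity.** With rᵢ the Euclidean distances from a droplet's
centroid to its surface voxels (6-connectivity boundary), the score is
`max(0, 1 − SD(r)/mean(r))`: 1 for an ideal sphere, decreasing with
surface dispersion. The coefficient-of-variation form is our concrete
realization of "distance from a perfect sphere"; it is scale-invariant
up to voxelization (< 0.05 change on doubling a sphere's radius) and
strictly ordered against growing ellipsoid axis ratios. Single-voxel
droplets score 1 by convention and are flagged. The retention threshold
(default 0.6) is configuration; a voxelized sphere scores ≈ 0.97 and a
3:1 ellipsoid ≈ 0.65, so the default separates them cleanly.

**Background subtraction.** Rolling ball (default radius 50 px,
approximating cell size) via morphological background estimation;
sliding paraboloid as the same operation with a paraboloid-like
ellipsoid structuring surface (height = radius/2 by default). The
background never exceeds the image, so corrected intensities are
non-negative.

**Redox.** Optical redox ratio `F/(F+N)` per pixel, NaN where
`F + N ≤ 0` (undefined, never coerced to 0), with per-cell means over
supplied masks. Cell masks come from ground truth or the user — manual
segmentation is not reimplemented.

## Synthetic study conditions

The generator emulates the study's data layout rather than its physics:

* **Spectra** — sums of pseudo-Voigt bands at the canonical LD positions
  (1000, 1250, 1450, 1558, 1610, 1660, 2135, 2180, 2850, 2880, 2935,
  3010 cm⁻¹) on a 600–3200 cm⁻¹ grid at 1 cm⁻¹ (the acquisition grid is
  not published; ours is a configurable choice), heights parameterized
  at the peak (published values are peak intensities, not areas), plus
  additive homoscedastic Gaussian noise, default SD 0.02 = 2% of the
  dominant CH₂ band (consistent with tight SD bands around averaged LD
  spectra). Replication defaults to 5 spectra/cell × 5 cells/group.
  Group effects are per-band amplitude multipliers; the default design
  raises the C-D lipid band 1.5× under 20x methionine, grades CH₂ with
  insulin (0.9/1.0/1.1), and adds a 1.2× interaction on the C-D lipid
  band at high insulin.
* **Stacks** — spheres/ellipsoids at a constant level over constant
  background, a row-wise sinusoidal stripe (period 8 voxels, random
  phase per slice) standing in for scan noise, and iid Gaussian noise.
  No point-spread function, shot noise, or intensity texture.
* **TPF pairs** — flat per-cell disk intensities plus a smooth additive
  background and optional noise.

Consequently, passing tests establish that the *algorithms* recover
known truth under the stated noise model — oracle agreement, unbiased
ratio recovery, calibrated tests, exact phantom morphometry — not that
they are robust to optical artifacts absent from the phantoms
(spectral baselines beyond the measured background, PSF blur,
shot-noise scaling, droplet texture, cell-shape irregularity).
Deuterium kinetics over time are not simulated.

## Problem sizes and numerical conventions

The shipped simulations use: 20 (μ, σ) pairs at L = 10⁵ for the
divergence oracle; 20 seeds × 25 spectra/class for entropy
localization; 20 noise replicates of the 4-peak window; 2000 null and
500 powered ANOVA replicates; a 10-sphere SNR-10 phantom plus 12 + 12
phantom cells for morphometry; and 10 seeds each for the classifier
bands — sizes chosen so the whole chain re-runs from scratch in a few
minutes on one CPU while keeping Monte-Carlo error well inside the
asserted margins. All randomness flows from `numpy.random.default_rng`
seeds; fixed seeds give bit-identical cohorts, stacks and images. Ties
in auto-initialized peak picking resolve toward higher prominence;
degenerate inputs (all-zero spectra, empty stacks, flat regions,
singleton groups) are either rejected with a message or returned with
explicit flags, as documented per function.
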