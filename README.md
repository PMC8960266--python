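# ramanld

Chemometric and 3D image analysis of lipid-droplet (LD) metabolism in
breast-cancer cells, for studies that combine spontaneous Raman
spectroscopy of single droplets, heavy-water-probed stimulated Raman
scattering (DO-SRS) image stacks, and two-photon autofluorescence (TPF)
of flavins and NADH under nutrient manipulation (methionine x insulin).

The package is aimed at spectroscopists and image analysts who need the
full analysis chain as tested, reusable code:

* **Spectrum preprocessing** — paired per-droplet background subtraction,
  vector (unit `‖I‖₂`) and simplex (`ΣI = 1`) normalization, protein-peak
  (2940 cm⁻¹) normalization, group averages with SD bands.
* **Relative-entropy feature ranking** — at each wavenumber ν, class
  intensities are modelled as Gaussians, discretized into long
  probability vectors `p(v_i)`, and scored by the symmetric
  Kullback-Leibler divergence
  `D_sym = (D_KL(A‖B) + D_KL(B‖A)) / 2`, or for k ≥ 3 classes the average
  pairwise divergence `D(P₁…P_k) = 1/(k(k−1)) Σᵢ Σⱼ D_KL(Pᵢ‖Pⱼ)`.
  The resulting profile ranks Raman bands by their power to discriminate
  treatment groups.
* **Pseudo-Voigt peak unmixing** — bounded least-squares decomposition of
  spectral windows into Gaussian-Lorentzian blends
  `h·[η L(ν) + (1−η) G(ν)]`, with fit error %, R², and topographic peak
  prominence / width-at-half-prominence metrics.
* **Ratiometric statistics** — CH₂:CH₃ (2850/2935, lipid:protein),
  CD_L:CD_P (2135/2180, de novo lipid:protein), CD_L:CH₂ (2135/2850),
  lipid-arrangement 2850/2880 ratios; quadrature-propagated contrasts;
  balanced two-way ANOVA with sum-to-zero constraints; two-tailed
  t-tests (Welch or pooled).
* **Classification and embedding** — single-hidden-layer rectified MLP
  (100 units, L2 α = 2·10⁻⁴, Adam, ≤ 200 iterations) and PCA (top 10
  components) → t-SNE (perplexity 30, no exaggeration).
* **3D morphometry and TPF quantification** — scan-stripe removal,
  Otsu/fixed thresholding with 26-connectivity labelling, sphericity
  scoring `max(0, 1 − SD(r)/mean(r))` over centroid-to-surface distances,
  per-cell count/volume summaries, rolling-ball and sliding-paraboloid
  background subtraction, optical redox ratio `F/(F+N)`, line profiles,
  per-cell histograms with SEM, maximum-intensity projections.
* **Synthetic data** — `ramanld.synthetic_data` generates ground-truthed
  LD spectrum cohorts (pseudo-Voigt bands + Gaussian noise, factorial
  amplitude effects), 3D droplet phantoms with stripe artifacts, and
  flavin/NADH image pairs, so every stage is testable end to end.

## Worked example

```python
import numpy as np
from ramanld.synthetic_data import default_cohort_design, generate_spectrum_cohort
from ramanld.entropy_ranking import entropy_profile
from ramanld.ratiometrics_stats import compute_ratios, anova2_balanced

sset, truth = generate_spectrum_cohort(default_cohort_design(seed=1))
prof = entropy_profile(sset, "methionine_x")
print(prof.top_bands(3))

ratios = compute_ratios(sset)
table = anova2_balanced(
    ratios["cdl_ch2"], ratios["methionine_x"], ratios["insulin_x"],
    names=("methionine", "insulin"),
)
print(table.terms[["F", "p"]].round(4))
```

prints

```
   wavenumber      score  rank
0      2140.0  29.750347     1
1      2136.0  29.588268     2
2      2141.0  28.503462     3
                            F    p
term
methionine          2143.1007  0.0
insulin              100.3290  0.0
methionine:insulin    74.5254  0.0
error                     NaN  NaN
```

The entropy profile's top-ranked wavenumbers sit on the C-D lipid band
(2135 cm⁻¹), i.e. the methionine factor is detected where the generator
placed its de novo lipogenesis effect, and the balanced two-way ANOVA on
the CD_L:CH₂ ratio finds both main effects and the methionine x insulin
interaction that the design encodes.

The numbered drivers under `analysis/` run the full chain on the default
synthetic study (01 simulate → 02 preprocess/average → 03 entropy
ranking → 04 unmixing → 05 ratios/ANOVA → 06 morphometry → 07 TPF/redox
→ 08 classify/embed), printing what each stage found and writing compact
tables to `results/` (bulky raw spectra and full-grid tables go to
`scratch/`).

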