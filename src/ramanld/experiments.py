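"""Canned simulation experiments over the synthetic study conditions.

Each function here generates its inputs with :mod:`ramanld.synthetic_data`,
runs one stage of the analysis chain, and measures the result against the
known ground truth.  The analysis drivers under ``analysis/`` and the
reproduction script call these; they are ordinary library code, seeded
and deterministic.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from . import entropy_ranking as er
from . import ld_imaging as ldi
from . import peak_unmixing as pu
from . import ratiometrics_stats as rs
from . import synthetic_data as sd
from .chemometrics_ml import ClassifierConfig, train_spectrum_classifier
from .spectra_prep import SpectrumSet

__all__ = [
    "kl_discretization_sweep",
    "multiclass_reduction_check",
    "entropy_localization",
    "unmix_recovery",
    "anova_hand_example",
    "anova_null_type1",
    "anova_interaction_power",
    "droplet_phantom_check",
    "morphology_contrast",
    "redox_flatfield",
    "rolling_ball_gradient",
    "stripe_removal",
    "classifier_sanity",
]


# ---------------------------------------------------------------------------
# Entropy ranking
# ---------------------------------------------------------------------------

def kl_discretization_sweep(length: int = 100_000) -> pd.DataFrame:
    """Discretized vs closed-form symmetric Gaussian KL over 20 (mu, sigma) pairs.

    The pairs span SD ratios in [0.5, 2] and mean gaps |dmu|/sigma in
    [0, 3]; the closed form is the independent oracle for the whole
    discretize-and-sum pipeline.
    """
    ratios = (0.5, 0.75, 1.0, 1.5, 2.0)
    gaps = (0.0, 1.0, 2.0, 3.0)
    rows = []
    for r in ratios:
        for g in gaps:
            mu_a, s_a = 0.0, 1.0
            mu_b, s_b = g, r
            disc = er.gaussian_pair_divergence(mu_a, s_a, mu_b, s_b, length=length)
            closed = 0.5 * (
                er.gaussian_kl_closed_form(mu_a, s_a, mu_b, s_b)
                + er.gaussian_kl_closed_form(mu_b, s_b, mu_a, s_a)
            )
            rel = abs(disc - closed) / closed if closed > 0 else abs(disc - closed)
            rows.append(
                {
                    "sigma_ratio": r,
                    "mean_gap": g,
                    "discretized": disc,
                    "closed_form": closed,
                    "rel_err": rel,
                }
            )
    return pd.DataFrame(rows)


def multiclass_reduction_check(length: int = 100_000) -> dict:
    """k=2 reduction to the symmetric divergence, and a k=3 closed-form check."""
    params = [(0.0, 1.0), (1.0, 1.3), (2.5, 0.8)]
    mus = np.array([[p[0]] for p in params])
    sigmas = np.array([[p[1]] for p in params])
    lo = float(mus.min() - 6 * sigmas.max())
    hi = float(mus.max() + 6 * sigmas.max())
    vecs = [er.discretize_gaussian(m, s, (lo, hi), length) for m, s in params]

    k2_multi = er.multiclass_divergence(vecs[:2])
    k2_sym = er.symmetric_kl(vecs[0], vecs[1])

    k3_multi = er.multiclass_divergence(vecs)
    total = 0.0
    for i in range(3):
        for j in range(3):
            if i != j:
                total += er.gaussian_kl_closed_form(*params[i], *params[j])
    k3_closed = total / 6.0
    return {
        "k2_abs_diff": abs(k2_multi - k2_sym),
        "k3_discretized": k3_multi,
        "k3_closed_form": k3_closed,
        "k3_rel_err": abs(k3_multi - k3_closed) / k3_closed,
    }


def _two_class_cohort(
    band: float,
    shift_sds: float,
    n_per_class: int,
    noise_sd: float,
    seed: int,
    grid=None,
) -> SpectrumSet:
    """Two methionine classes identical except a mean shift at one band."""
    base_amp = {b.center: b.amplitude for b in sd.DEFAULT_BANDS}[band]
    mult = 1.0 + shift_sds * noise_sd / base_amp
    design = sd.CohortDesign(
        cell_lines=("MDA-MB-231",),
        methionine_levels=(1.0, 20.0),
        insulin_levels=(1.0,),
        multipliers={("MDA-MB-231", 20.0, 1.0): {band: mult}},
        cells_per_group=max(1, n_per_class // 5),
        spectra_per_cell=5 if n_per_class % 5 == 0 else n_per_class,
        noise_sd=noise_sd,
        grid=grid,
        seed=seed,
    )
    if design.cells_per_group * design.spectra_per_cell != n_per_class:
        design = replace(design, cells_per_group=1, spectra_per_cell=n_per_class)
    sset, _ = sd.generate_spectrum_cohort(design)
    return sset


def entropy_localization(
    n_seeds: int = 20,
    n_per_class: int = 25,
    shift_sds: float = 2.0,
    band: float = 3010.0,
    noise_sd: float = sd.DEFAULT_NOISE_SD,
    length: int = 100_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Does the entropy profile's argmax land on the one shifted band?

    Per seed, a two-class cohort differs only by a ``shift_sds``-noise-SD
    mean shift at *band*; a hit is an argmax within one band FWHM.
    """
    fwhm = {b.center: b.fwhm for b in sd.DEFAULT_BANDS}[band]
    rows = []
    for i in range(n_seeds):
        sset = _two_class_cohort(band, shift_sds, n_per_class, noise_sd, seed + i)
        prof = er.entropy_profile(sset, "methionine_x", length=length)
        peak = float(prof.wavenumbers[int(np.argmax(prof.scores))])
        rows.append(
            {
                "seed": seed + i,
                "argmax_wavenumber": peak,
                "hit": abs(peak - band) <= fwhm,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Peak unmixing
# ---------------------------------------------------------------------------

#: four well-separated blend components in the Amide I / heme window
UNMIX_SCENARIO = (
    pu.PeakComponent(1540.0, 0.8, 18.0, 0.3),
    pu.PeakComponent(1580.0, 0.5, 16.0, 0.5),
    pu.PeakComponent(1622.0, 0.9, 20.0, 0.2),
    pu.PeakComponent(1665.0, 1.2, 22.0, 0.4),
)
UNMIX_WINDOW = (1500.0, 1700.0)


def _unmix_signal(noise_frac: float, rng) -> "sd.RamanSpectrum":
    from .spectra_prep import RamanSpectrum

    grid = np.arange(1480.0, 1721.0, 1.0)
    y = np.zeros_like(grid)
    for c in UNMIX_SCENARIO:
        y += pu.pseudo_voigt(grid, c)
    if noise_frac > 0:
        y = y * (1.0 + noise_frac * rng.normal(size=grid.size))
    return RamanSpectrum(grid, y)


def unmix_recovery(n_reps: int = 20, noise_frac: float = 0.01, seed: int = 0) -> dict:
    """Noise-free and 1%-multiplicative-noise recovery of the 4-peak window."""
    rng = np.random.default_rng(seed)
    clean = _unmix_signal(0.0, rng)
    res0 = pu.unmix_peaks(clean, UNMIX_WINDOW, n_peaks=4)
    true_centers = np.array([c.center for c in UNMIX_SCENARIO])
    got_centers = np.array([c.center for c in res0.components])
    out = {
        "clean_max_center_err": float(np.max(np.abs(got_centers - true_centers))),
        "clean_r2": res0.r_squared,
        "clean_fit_error_pct": res0.fit_error_pct,
    }
    errs, r2s = [], []
    for _ in range(n_reps):
        noisy = _unmix_signal(noise_frac, rng)
        res = pu.unmix_peaks(noisy, UNMIX_WINDOW, n_peaks=4)
        errs.append(res.fit_error_pct)
        r2s.append(res.r_squared)
    out["noisy_fit_error_pct"] = np.asarray(errs)
    out["noisy_r2"] = np.asarray(r2s)
    return out


# ---------------------------------------------------------------------------
# ANOVA
# ---------------------------------------------------------------------------

def anova_hand_example() -> rs.AnovaTable:
    """The textbook 2x2, n=2 example with known sums of squares."""
    values = [1, 2, 3, 4, 5, 6, 7, 8]
    a = ["a1", "a1", "a1", "a1", "a2", "a2", "a2", "a2"]
    b = ["b1", "b1", "b2", "b2", "b1", "b1", "b2", "b2"]
    return rs.anova2_balanced(values, a, b)


def anova_null_type1(
    n_reps: int = 2000,
    levels: tuple = (2, 3),
    n: int = 5,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error rate of the interaction term under a pure-noise design."""
    rng = np.random.default_rng(seed)
    na, nb = levels
    a = np.repeat(np.arange(na), nb * n)
    b = np.tile(np.repeat(np.arange(nb), n), na)
    hits = 0
    for _ in range(n_reps):
        y = rng.normal(size=na * nb * n)
        table = rs.anova2_balanced(y, a, b)
        if table["A:B"]["p"] < alpha:
            hits += 1
    return hits / n_reps


def anova_interaction_power(
    n_reps: int = 500,
    n: int = 25,
    effect_sd: float = 1.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Power for a one-error-SD interaction on the C-D lipid ratio, 2x3 design.

    The injected interaction is a sum-to-zero pattern gamma = u x v with
    u = (1/2, -1/2), v = (1, 0, -1), scaled by *effect_sd*, so its total
    squared effect equals one error variance — the desk-scale analogue of
    the significant methionine x insulin interaction in the de novo lipid
    ratio.
    """
    rng = np.random.default_rng(seed)
    u = np.array([0.5, -0.5])
    v = np.array([1.0, 0.0, -1.0])
    gamma = effect_sd * np.outer(u, v)  # (2, 3)
    na, nb = gamma.shape
    a = np.repeat(np.arange(na), nb * n)
    b = np.tile(np.repeat(np.arange(nb), n), na)
    cell_effect = np.repeat(gamma.ravel(), n)
    hits = 0
    for _ in range(n_reps):
        y = cell_effect + rng.normal(size=na * nb * n)
        table = rs.anova2_balanced(y, a, b)
        if table["A:B"]["p"] < alpha:
            hits += 1
    return hits / n_reps


# ---------------------------------------------------------------------------
# Morphometry
# ---------------------------------------------------------------------------

def droplet_phantom_check(
    n_spheres: int = 10,
    shape: tuple = (64, 128, 128),
    radius_range: tuple = (6.0, 10.0),
    snr: float = 10.0,
    seed: int = 0,
) -> dict:
    """Segment a known sphere phantom and compare with analytic truth.

    SNR is droplet contrast over noise SD.  Segmented droplets are
    matched to truth by nearest centroid.  Also scores a radius-8 sphere
    against a 3:1 ellipsoid of equal volume.
    """
    rng = np.random.default_rng(seed)
    contrast = 1.0
    truth = sd.random_sphere_truth(
        n_spheres, shape, radius_range, rng=rng, background=10.0, contrast=contrast
    )
    stack, truth = sd.generate_droplet_stack(
        truth, shape, noise_sd=contrast / snr, stripe_amp=0.05, seed=rng
    )
    clean = ldi.destripe_and_smooth(stack, smoothing_sigma=1.0)
    droplets = ldi.segment_droplets(clean)
    vol_errs = []
    for c, v_true in zip(truth.centers, truth.volumes):
        if not droplets:
            break
        d = min(droplets, key=lambda d: np.linalg.norm(d.centroid - c))
        vol_errs.append(abs(d.volume_voxels - v_true) / v_true)

    # shape scoring: radius-8 sphere vs an equal-volume 3:1 ellipsoid
    sphere_truth = sd.PhantomTruth(
        centers=[[24.0, 24.0, 24.0]], semi_axes=[[8.0, 8.0, 8.0]]
    )
    s_stack, _ = sd.generate_droplet_stack(sphere_truth, (48, 48, 48))
    s_drop = ldi.segment_droplets(s_stack, threshold=10.5)[0]
    c = (512.0 / 3.0) ** (1.0 / 3.0)  # 3c * c * c = 8^3
    ell_truth = sd.PhantomTruth(
        centers=[[24.0, 24.0, 24.0]], semi_axes=[[3 * c, c, c]]
    )
    e_stack, _ = sd.generate_droplet_stack(ell_truth, (48, 48, 48))
    e_drop = ldi.segment_droplets(e_stack, threshold=10.5)[0]
    return {
        "n_true": n_spheres,
        "n_segmented": len(droplets),
        "volume_rel_errs": np.asarray(vol_errs),
        "sphere_sphericity": s_drop.sphericity,
        "ellipsoid_sphericity": e_drop.sphericity,
    }


def morphology_contrast(
    n_cells: int = 12,
    shape: tuple = (48, 96, 96),
    seed: int = 0,
) -> dict:
    """Fewer-but-larger droplet contrast between methionine groups.

    Control cells carry ~10 droplets of radius ~4.5; excess-methionine
    cells ~5 droplets of radius ~6.5 (the qualitative morphology effect
    of excess methionine).  Per-cell counts and mean volumes are compared
    by two-tailed t-tests.
    """
    rng = np.random.default_rng(seed)

    def run_group(mean_count, radius_lo, radius_hi):
        counts, volumes = [], []
        for _ in range(n_cells):
            k = max(1, int(rng.poisson(mean_count)))
            truth = sd.random_sphere_truth(
                k, shape, (radius_lo, radius_hi), rng=rng, margin=1.5
            )
            stack, _ = sd.generate_droplet_stack(
                truth, shape, noise_sd=0.1, stripe_amp=0.05, seed=rng
            )
            pre = ldi.destripe_and_smooth(stack, smoothing_sigma=1.0)
            droplets = ldi.segment_droplets(pre)
            summary = ldi.filter_and_summarize(droplets, sphericity_threshold=0.6)[0]
            counts.append(summary.count)
            volumes.append(summary.mean_volume_voxels)
        return np.asarray(counts, float), np.asarray(volumes, float)

    ctrl_count, ctrl_vol = run_group(10, 3.5, 5.5)
    met_count, met_vol = run_group(5, 5.5, 7.5)
    return {
        "control_counts": ctrl_count,
        "methionine_counts": met_count,
        "control_volumes": ctrl_vol,
        "methionine_volumes": met_vol,
        "count_p": rs.t_test_two_tailed(ctrl_count, met_count).p,
        "volume_p": rs.t_test_two_tailed(ctrl_vol, met_vol).p,
    }


# ---------------------------------------------------------------------------
# TPF quantification
# ---------------------------------------------------------------------------

def redox_flatfield(shape: tuple = (128, 128), n_cells: int = 4, seed: int = 0) -> dict:
    """Equal flavin and NADH, no background: redox must be exactly 1/2 in cells."""
    rng = np.random.default_rng(seed)
    masks = sd.make_cell_masks(shape, n_cells, radius=14.0, rng=rng)
    flavin, nadh, masks = sd.generate_fluorescence_pair(masks, 5.0, 5.0)
    ratio, per_cell = ldi.redox_map(flavin, nadh, masks)
    in_cells = ratio[masks > 0]
    return {
        "max_abs_dev": float(np.max(np.abs(in_cells - 0.5))),
        "per_cell": per_cell,
    }


def rolling_ball_gradient(
    shape: tuple = (256, 256),
    gradient_amp: float = 80.0,
    cell_level: float = 20.0,
    radius: float = 50.0,
    seed: int = 0,
) -> dict:
    """Rolling-ball subtraction of a smooth background under bright cells.

    Background RMS is the SD of outside-cell pixels; the reduction
    percentage compares before and after subtraction.
    """
    rng = np.random.default_rng(seed)
    masks = sd.make_cell_masks(shape, 4, radius=20.0, rng=rng)
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    gradient = gradient_amp * (
        0.6 * xx / shape[1] + 0.4 * np.sin(np.pi * yy / shape[0])
    )
    flavin, _, masks = sd.generate_fluorescence_pair(
        masks, cell_level, cell_level, background_gradient=gradient, noise_sd=0.5,
        seed=rng,
    )
    corrected = ldi.subtract_image_background(flavin, "rolling_ball", radius=radius)
    outside = masks == 0
    rms_before = float(flavin[outside].std())
    rms_after = float(corrected[outside].std())
    return {
        "rms_before": rms_before,
        "rms_after": rms_after,
        "reduction_pct": 100.0 * (1.0 - rms_after / rms_before),
    }


def stripe_removal(shape: tuple = (32, 96, 96), seed: int = 0) -> dict:
    """Stripe-band spectral power before/after de-striping, plus clean no-op."""
    rng = np.random.default_rng(seed)
    truth = sd.random_sphere_truth(4, shape, (5.0, 8.0), rng=rng)

    def stripe_band_power(stack):
        # power off the DC bin of the row-constant (kx = 0) spectrum
        rowmean = stack.data.mean(axis=2)
        spec = np.fft.rfft(rowmean - rowmean.mean(axis=1, keepdims=True), axis=1)
        return float(np.sum(np.abs(spec[:, 1:]) ** 2))

    striped, _ = sd.generate_droplet_stack(
        truth, shape, noise_sd=0.05, stripe_amp=0.5, seed=1234
    )
    cleaned = ldi.destripe_and_smooth(striped, smoothing_sigma=1.0)
    clean, _ = sd.generate_droplet_stack(truth, shape, noise_sd=0.0, stripe_amp=0.0)
    noop = ldi.destripe_and_smooth(clean, smoothing_sigma=1.0)
    rel_change = float(
        np.linalg.norm(noop.data - clean.data) / np.linalg.norm(clean.data)
    )
    p_before = stripe_band_power(striped)
    p_after = stripe_band_power(cleaned)
    return {
        "stripe_power_before": p_before,
        "stripe_power_after": p_after,
        "power_reduction_pct": 100.0 * (1.0 - p_after / p_before),
        "clean_rel_rms_change": rel_change,
    }


# ---------------------------------------------------------------------------
# Classification sanity
# ---------------------------------------------------------------------------

def _classifier_cohort(shift_sds: float, n_per_class: int, seed: int) -> SpectrumSet:
    """Two classes shifted by ``shift_sds`` noise-SDs at 10 bands (0 = null)."""
    noise_sd = sd.DEFAULT_NOISE_SD
    bands = [b.center for b in sd.DEFAULT_BANDS][:10]
    base = {b.center: b.amplitude for b in sd.DEFAULT_BANDS}
    mult = {c: 1.0 + shift_sds * noise_sd / base[c] for c in bands}
    design = sd.CohortDesign(
        cell_lines=("MDA-MB-231",),
        methionine_levels=(1.0, 20.0),
        insulin_levels=(1.0,),
        multipliers={("MDA-MB-231", 20.0, 1.0): mult if shift_sds else {}},
        cells_per_group=n_per_class // 5,
        spectra_per_cell=5,
        noise_sd=noise_sd,
        seed=seed,
    )
    sset, _ = sd.generate_spectrum_cohort(design)
    return sset


def classifier_sanity(n_seeds: int = 10, n_per_class: int = 50, seed: int = 0) -> dict:
    """Held-out accuracy on null vs 3-sigma-separated two-class cohorts."""
    null_acc, sep_acc = [], []
    for i in range(n_seeds):
        cfg = ClassifierConfig(seed=seed + i)
        null = _classifier_cohort(0.0, n_per_class, seed + i)
        null_acc.append(
            train_spectrum_classifier(null, "methionine_x", cfg).accuracy
        )
        sep = _classifier_cohort(3.0, n_per_class, 10_000 + seed + i)
        sep_acc.append(train_spectrum_classifier(sep, "methionine_x", cfg).accuracy)
    return {
        "null_accuracies": np.asarray(null_acc),
        "separated_accuracies": np.asarray(sep_acc),
    }
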