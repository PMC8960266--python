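"""Synthetic Raman spectra cohorts and image phantoms with known truth.

The study data this package analyses — lipid-droplet (LD) Raman spectra
under a 2 (methionine) x 3 (insulin) design, 3D SRS stacks of droplets,
and flavin/NADH autofluorescence pairs — are emulated here so every
downstream stage can be exercised against ground truth.

Spectra are sums of pseudo-Voigt bands at the canonical LD positions
(phenylalanine 1000, amide III 1200-1300, amide II'/CH2 1450, heme 1558,
aromatic side chains 1610, amide I 1660, C-D lipid 2135, C-D protein
2180, CH2 2850/2880, CH3 2935, =C-H 3010 cm-1) plus additive homoscedastic
Gaussian noise.  Group structure enters through per-group band-amplitude
multipliers.  Image phantoms contain spherical or ellipsoidal droplets on
a constant background with an optional row-wise sinusoidal stripe
artifact standing in for laser fast-scan noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .ld_imaging import ImageStack
from .peak_unmixing import PeakComponent, pseudo_voigt
from .spectra_prep import RamanSpectrum, SpectrumSet

__all__ = [
    "BandSpec",
    "CohortDesign",
    "PhantomTruth",
    "DEFAULT_BANDS",
    "default_grid",
    "default_cohort_design",
    "generate_ld_spectrum",
    "generate_spectrum_cohort",
    "generate_droplet_stack",
    "random_sphere_truth",
    "generate_fluorescence_pair",
    "make_cell_masks",
]


@dataclass(frozen=True)
class BandSpec:
    """One Raman band: center (cm-1), FWHM (cm-1), peak height, Lorentzian share."""

    center: float
    fwhm: float
    amplitude: float
    mixing: float = 0.0

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError("fwhm must be > 0")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must lie in [0, 1]")


#: Canonical LD band set.  Heights are relative peak intensities chosen to
#: resemble averaged LD spectra: the C-H stretching region dominates, the
#: C-D bands sit in the otherwise silent region, and fingerprint protein
#: bands are minor.
DEFAULT_BANDS = (
    BandSpec(1000.0, 12.0, 0.10),   # phenylalanine
    BandSpec(1250.0, 60.0, 0.15),   # amide III envelope
    BandSpec(1450.0, 30.0, 0.35),   # CH2/CH3 deformation (amide II')
    BandSpec(1558.0, 22.0, 0.08),   # heme backbone (cytochrome c)
    BandSpec(1610.0, 20.0, 0.08),   # trp/tyr/phe side chains
    BandSpec(1660.0, 35.0, 0.30),   # amide I
    BandSpec(2135.0, 45.0, 0.30),   # C-D lipid (de novo lipids)
    BandSpec(2180.0, 45.0, 0.25),   # C-D protein (de novo proteins)
    BandSpec(2850.0, 35.0, 1.00),   # CH2 symmetric stretch (total lipid)
    BandSpec(2880.0, 35.0, 0.70),   # CH2 Fermi resonance (lattice order)
    BandSpec(2935.0, 40.0, 0.80),   # CH3 stretch (protein)
    BandSpec(3010.0, 30.0, 0.25),   # =C-H stretch (unsaturated lipid)
)

#: Default acquisition noise SD, in the same units as band heights
#: (2% of the dominant CH2 band), consistent with tight per-group SD
#: bands around averaged LD spectra.
DEFAULT_NOISE_SD = 0.02


def default_grid(start: float = 600.0, stop: float = 3200.0, step: float = 1.0):
    """Wavenumber grid spanning fingerprint, silent, and C-H regions."""
    return np.arange(start, stop + step / 2, step)


def generate_ld_spectrum(
    bands,
    grid=None,
    noise_sd: float = 0.0,
    seed=None,
    metadata=None,
) -> RamanSpectrum:
    """One LD spectrum: sum of pseudo-Voigt bands plus iid Gaussian noise."""
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    intensity = np.zeros_like(grid)
    for b in bands:
        intensity += pseudo_voigt(
            grid, PeakComponent(b.center, b.amplitude, b.fwhm, b.mixing)
        )
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        intensity = intensity + rng.normal(0.0, noise_sd, size=grid.size)
    return RamanSpectrum(grid, intensity, dict(metadata or {}))


# ---------------------------------------------------------------------------
# Cohorts
# ---------------------------------------------------------------------------

@dataclass
class CohortDesign:
    """A factorial spectrum-cohort design with known band effects.

    ``multipliers`` maps ``(cell_line, methionine_x, insulin_x)`` group
    keys to ``{band center: amplitude multiplier}``; unlisted bands keep
    multiplier 1.  Replication defaults to the study layout: 5 LD spectra
    per cell and 5 cells per experimental group.
    """

    cell_lines: tuple = ("MDA-MB-231",)
    methionine_levels: tuple = (1.0, 20.0)
    insulin_levels: tuple = (0.1, 1.0, 2.0)
    multipliers: dict = field(default_factory=dict)
    cells_per_group: int = 5
    spectra_per_cell: int = 5
    bands: tuple = DEFAULT_BANDS
    grid: np.ndarray | None = None
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cells_per_group < 1:
            raise ValueError("cells per group must be >= 1")
        if self.spectra_per_cell < 1:
            raise ValueError("spectra per cell must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")

    def groups(self):
        for cl in self.cell_lines:
            for met in self.methionine_levels:
                for ins in self.insulin_levels:
                    yield (cl, met, ins)

    def group_bands(self, key) -> list[BandSpec]:
        mult = self.multipliers.get(key, {})
        return [
            replace(b, amplitude=b.amplitude * float(mult.get(b.center, 1.0)))
            for b in self.bands
        ]


def default_cohort_design(seed: int = 0) -> CohortDesign:
    """The default study-condition cohort for the TNBC-like line.

    Effects encode the qualitative findings the analysis chain should
    recover: excess (20x) methionine raises the C-D lipid band (de novo
    lipogenesis) and modestly raises CH2; insulin grades CH2; and a
    positive methionine x insulin interaction acts on the C-D lipid band
    at high insulin.
    """
    mult: dict = {}
    for met in (1.0, 20.0):
        for ins in (0.1, 1.0, 2.0):
            m: dict = {}
            if met == 20.0:
                m[2135.0] = 1.5
                m[2850.0] = 1.2
            m[2850.0] = m.get(2850.0, 1.0) * {0.1: 0.9, 1.0: 1.0, 2.0: 1.1}[ins]
            if met == 20.0 and ins == 2.0:
                m[2135.0] = m[2135.0] * 1.2
            mult[("MDA-MB-231", met, ins)] = m
    return CohortDesign(multipliers=mult, seed=seed)


def generate_spectrum_cohort(design: CohortDesign):
    """Generate a labelled cohort and its ground-truth effect table.

    Returns ``(SpectrumSet, truth)`` where *truth* lists, per group and
    band, the noise-free expected peak amplitude.  Bit-identical for a
    fixed design seed.
    """
    rng = np.random.default_rng(design.seed)
    grid = default_grid() if design.grid is None else np.asarray(design.grid, float)
    spectra = []
    truth_rows = []
    for key in design.groups():
        cl, met, ins = key
        bands = design.group_bands(key)
        for b in bands:
            truth_rows.append(
                {
                    "cell_line": cl,
                    "methionine_x": met,
                    "insulin_x": ins,
                    "band": b.center,
                    "amplitude": b.amplitude,
                }
            )
        for cell in range(design.cells_per_group):
            for droplet in range(design.spectra_per_cell):
                spectra.append(
                    generate_ld_spectrum(
                        bands,
                        grid=grid,
                        noise_sd=design.noise_sd,
                        seed=rng,
                        metadata={
                            "cell_line": cl,
                            "methionine_x": met,
                            "insulin_x": ins,
                            "cell_id": cell,
                            "droplet_id": droplet,
                        },
                    )
                )
    return SpectrumSet.from_spectra(spectra), pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# 3D droplet phantoms
# ---------------------------------------------------------------------------

@dataclass
class PhantomTruth:
    """Ground truth for a droplet stack phantom.

    ``semi_axes`` rows are (z, y, x) semi-axis lengths in voxels (equal
    for spheres).  ``overlapping`` is set by the generator when any voxel is
    claimed by more than one droplet.
    """

    centers: np.ndarray  # (n, 3) voxel coords (z, y, x)
    semi_axes: np.ndarray  # (n, 3)
    background: float = 10.0
    droplet_level: float = 11.0
    stripe_amp: float = 0.0
    overlapping: bool = False

    def __post_init__(self) -> None:
        self.centers = np.atleast_2d(np.asarray(self.centers, float))
        self.semi_axes = np.atleast_2d(np.asarray(self.semi_axes, float))
        if np.any(self.semi_axes <= 0):
            raise ValueError("semi-axes must be > 0")

    @property
    def volumes(self) -> np.ndarray:
        """Analytic ellipsoid volumes, voxels."""
        return 4.0 / 3.0 * np.pi * np.prod(self.semi_axes, axis=1)


def random_sphere_truth(
    n: int,
    shape: tuple,
    radius_range: tuple = (6.0, 10.0),
    rng=None,
    background: float = 10.0,
    contrast: float = 1.0,
    margin: float = 2.0,
    max_tries: int = 10000,
) -> PhantomTruth:
    """Place *n* non-overlapping spheres fully inside *shape*."""
    rng = np.random.default_rng(rng)
    centers: list[np.ndarray] = []
    radii: list[float] = []
    for _ in range(max_tries):
        if len(centers) == n:
            break
        r = rng.uniform(*radius_range)
        lo = r + margin
        c = np.array([rng.uniform(lo, s - 1 - lo) for s in shape])
        if all(
            np.linalg.norm(c - c2) > r + r2 + margin for c2, r2 in zip(centers, radii)
        ):
            centers.append(c)
            radii.append(r)
    if len(centers) < n:
        raise ValueError(f"could not place {n} spheres in shape {shape}")
    radii = np.asarray(radii)
    return PhantomTruth(
        centers=np.asarray(centers),
        semi_axes=np.repeat(radii[:, None], 3, axis=1),
        background=background,
        droplet_level=background + contrast,
    )


def generate_droplet_stack(
    truth: PhantomTruth,
    shape: tuple,
    noise_sd: float = 0.0,
    stripe_amp: float = 0.0,
    stripe_period: float = 8.0,
    seed=None,
    voxel_size: tuple = (1.0, 1.0, 1.0),
) -> tuple[ImageStack, PhantomTruth]:
    """Voxelize the phantom into a stack with noise and stripe artifact.

    Voxels whose centers fall inside a droplet take ``droplet_level``,
    the rest ``background``; the stripe is an additive sinusoid along y
    (constant along the fast-scan x axis, random phase per slice) and
    iid Gaussian noise is added on top.  Droplets must lie fully inside
    the stack; overlapping droplets are permitted but flagged in the
    returned truth.
    """
    rng = np.random.default_rng(seed)
    shape = tuple(int(s) for s in shape)
    for c, ax in zip(truth.centers, truth.semi_axes):
        if np.any(c - ax < -0.5) or np.any(c + ax > np.asarray(shape) - 0.5):
            raise ValueError("droplet extends outside the stack")
    zz, yy, xx = np.meshgrid(*[np.arange(s, dtype=float) for s in shape], indexing="ij")
    coverage = np.zeros(shape, dtype=np.int16)
    for c, ax in zip(truth.centers, truth.semi_axes):
        inside = (
            ((zz - c[0]) / ax[0]) ** 2
            + ((yy - c[1]) / ax[1]) ** 2
            + ((xx - c[2]) / ax[2]) ** 2
        ) <= 1.0
        coverage += inside
    data = np.where(coverage > 0, truth.droplet_level, truth.background).astype(float)
    if stripe_amp > 0:
        phases = rng.uniform(0, 2 * np.pi, size=shape[0])
        y = np.arange(shape[1], dtype=float)
        stripe = stripe_amp * np.sin(
            2 * np.pi * y[None, :] / stripe_period + phases[:, None]
        )
        data += stripe[:, :, None]
    if noise_sd > 0:
        data += rng.normal(0.0, noise_sd, size=shape)
    out_truth = replace(
        truth, stripe_amp=stripe_amp, overlapping=bool((coverage > 1).any())
    )
    return ImageStack(data, voxel_size, channel="2850"), out_truth


# ---------------------------------------------------------------------------
# 2D autofluorescence phantoms
# ---------------------------------------------------------------------------

def make_cell_masks(
    shape: tuple, n_cells: int, radius: float = 20.0, rng=None, margin: float = 4.0
) -> np.ndarray:
    """Labelled disk masks for *n_cells* non-overlapping round cells."""
    rng = np.random.default_rng(rng)
    masks = np.zeros(shape, dtype=int)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > 10000:
            raise ValueError("could not place cells")
        c = np.array(
            [
                rng.uniform(radius + margin, s - 1 - radius - margin)
                for s in shape
            ]
        )
        if all(np.linalg.norm(c - c2) > 2 * radius + margin for c2 in centers):
            centers.append(c)
            masks[(yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius**2] = len(centers)
    return masks


def generate_fluorescence_pair(
    cell_masks: np.ndarray,
    flavin_level,
    nadh_level,
    background_gradient: np.ndarray | None = None,
    noise_sd: float = 0.0,
    seed=None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flavin and NADH image pair over labelled cell masks.

    Levels are scalars or per-cell mappings ``{cell_id: level}``; the
    optional smooth ``background_gradient`` (what a rolling-ball pass is
    meant to remove) is added to both channels.  Returns
    ``(flavin, nadh, masks)``.
    """
    cell_masks = np.asarray(cell_masks)
    rng = np.random.default_rng(seed)

    def build(level):
        img = np.zeros(cell_masks.shape, dtype=float)
        for cid in np.unique(cell_masks):
            if cid == 0:
                continue
            lv = float(level[cid]) if isinstance(level, dict) else float(level)
            if lv < 0:
                raise ValueError("fluorescence levels must be >= 0")
            img[cell_masks == cid] = lv
        if background_gradient is not None:
            bg = np.asarray(background_gradient, float)
            if bg.shape != img.shape:
                raise ValueError("background gradient shape mismatch")
            img = img + bg
        if noise_sd > 0:
            img = img + rng.normal(0.0, noise_sd, size=img.shape)
        return img

    return build(flavin_level), build(nadh_level), cell_masks
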