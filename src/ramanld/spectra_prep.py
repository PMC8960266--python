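"""Spectrum containers, I/O and preprocessing.

Spontaneous Raman spectra of lipid droplets (LDs) arrive as two-column
wavenumber/intensity tables, one file per droplet, with sample metadata
(cell line, methionine level, insulin level, cell id, droplet id) in a
companion table.  Preprocessing follows the usual chemometric chain for
this kind of data: subtraction of a paired background spectrum taken at
the same focal plane as the droplet, then vector (unit Euclidean norm)
and simplex (sum-to-one closure) normalization for clustering inputs,
or normalization to the 2940 cm-1 protein peak for ratiometric work.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "SpectrumSet",
    "GroupStats",
    "read_spectrum_table",
    "write_spectrum_table",
    "read_spectrum_set",
    "write_spectrum_set",
    "subtract_background",
    "normalize_spectrum",
    "normalize_set",
    "peak_intensity",
    "group_average",
]

#: metadata columns every cohort carries
FACTOR_COLUMNS = ("cell_line", "methionine_x", "insulin_x", "cell_id", "droplet_id")


@dataclass
class RamanSpectrum:
    """One wavenumber/intensity trace with sample metadata.

    Wavenumbers are in cm-1 and must be strictly increasing; intensities
    are in arbitrary units and must be finite.
    """

    wavenumbers: np.ndarray
    intensities: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.wavenumbers.ndim != 1 or self.intensities.ndim != 1:
            raise ValueError("wavenumbers and intensities must be 1-D")
        if self.wavenumbers.size != self.intensities.size:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.intensities.size} intensities"
            )
        if self.wavenumbers.size and np.any(np.diff(self.wavenumbers) <= 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")

    def __len__(self) -> int:
        return self.wavenumbers.size

    def copy_with(self, intensities: np.ndarray, **meta) -> "RamanSpectrum":
        """New spectrum on the same grid; metadata is copied then updated."""
        md = dict(self.metadata)
        md.update(meta)
        return RamanSpectrum(self.wavenumbers.copy(), np.asarray(intensities, float), md)


@dataclass
class SpectrumSet:
    """A labelled collection of spectra sharing one wavenumber grid."""

    wavenumbers: np.ndarray
    intensities: np.ndarray  # (n_spectra, n_wavenumbers)
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be 2-D (spectra x wavenumbers)")
        if self.intensities.shape[1] != self.wavenumbers.size:
            raise ValueError("intensity columns must match the wavenumber grid")
        if len(self.metadata) != self.intensities.shape[0]:
            raise ValueError("metadata rows must match the number of spectra")
        self.metadata = self.metadata.reset_index(drop=True)

    def __len__(self) -> int:
        return self.intensities.shape[0]

    def spectrum(self, i: int) -> RamanSpectrum:
        return RamanSpectrum(
            self.wavenumbers, self.intensities[i], self.metadata.iloc[i].to_dict()
        )

    def __iter__(self) -> Iterator[RamanSpectrum]:
        for i in range(len(self)):
            yield self.spectrum(i)

    def labels(self, factor: str) -> np.ndarray:
        if factor not in self.metadata.columns:
            raise KeyError(f"unknown factor {factor!r}")
        return self.metadata[factor].to_numpy()

    def groupby(self, factors: str | Sequence[str]):
        """Yield ``(key, SpectrumSet)`` per level combination of *factors*."""
        if isinstance(factors, str):
            factors = [factors]
        for key, idx in self.metadata.groupby(list(factors), sort=True).groups.items():
            pos = self.metadata.index.get_indexer(idx)
            yield key, SpectrumSet(
                self.wavenumbers, self.intensities[pos], self.metadata.iloc[pos]
            )

    @classmethod
    def from_spectra(cls, spectra: Iterable[RamanSpectrum]) -> "SpectrumSet":
        spectra = list(spectra)
        if not spectra:
            raise ValueError("empty spectrum list")
        grid = spectra[0].wavenumbers
        for s in spectra[1:]:
            if s.wavenumbers.shape != grid.shape or not np.array_equal(
                s.wavenumbers, grid
            ):
                raise ValueError("all spectra must share an identical wavenumber grid")
        return cls(
            grid,
            np.vstack([s.intensities for s in spectra]),
            pd.DataFrame([s.metadata for s in spectra]),
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_spectrum_table(path, metadata: Mapping | None = None) -> RamanSpectrum:
    """Read a two-column (wavenumber, intensity) text table.

    Comma- or whitespace-delimited, optional single header line.  Rows that
    fail to parse are reported with their 1-based line number.  Descending
    grids are sorted ascending with a warning; duplicate wavenumbers are
    rejected.
    """
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) < 2:
                raise ValueError(f"{path.name}: line {lineno}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1 and not rows:
                    continue  # header line
                raise ValueError(
                    f"{path.name}: line {lineno}: non-numeric row {line!r}"
                ) from None
    if not rows:
        raise ValueError(f"{path.name}: no numeric data rows")
    wn = np.array([r[0] for r in rows])
    inten = np.array([r[1] for r in rows])
    if np.unique(wn).size != wn.size:
        raise ValueError(f"{path.name}: duplicate wavenumbers present")
    if np.any(np.diff(wn) < 0):
        warnings.warn(f"{path.name}: wavenumbers not ascending; sorting", stacklevel=2)
        order = np.argsort(wn)
        wn, inten = wn[order], inten[order]
    return RamanSpectrum(wn, inten, dict(metadata or {}))


def write_spectrum_table(spectrum: RamanSpectrum, path) -> Path:
    """Write a spectrum as tab-separated text at full (repr) precision."""
    if len(spectrum) == 0:
        raise ValueError("refusing to write an empty spectrum")
    path = Path(path)
    with open(path, "w") as fh:
        for w, i in zip(spectrum.wavenumbers, spectrum.intensities):
            fh.write(f"{float(w)!r}\t{float(i)!r}\n")
    return path


def write_spectrum_set(sset: SpectrumSet, out_dir, prefix: str = "spectrum") -> Path:
    """Write one TSV per spectrum plus ``metadata.csv`` keyed by file name."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    md = sset.metadata.copy()
    files = []
    for i, spec in enumerate(sset):
        fname = f"{prefix}_{i:04d}.tsv"
        write_spectrum_table(spec, out_dir / fname)
        files.append(fname)
    md.insert(0, "file", files)
    md.to_csv(out_dir / "metadata.csv", index=False)
    return out_dir


def read_spectrum_set(in_dir, metadata_csv: str = "metadata.csv") -> SpectrumSet:
    in_dir = Path(in_dir)
    md = pd.read_csv(in_dir / metadata_csv)
    spectra = [
        read_spectrum_table(in_dir / row["file"], row.drop("file").to_dict())
        for _, row in md.iterrows()
    ]
    return SpectrumSet.from_spectra(spectra)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def subtract_background(
    spectrum: RamanSpectrum, background: RamanSpectrum
) -> RamanSpectrum:
    """Pointwise subtraction of a paired background trace (same grid).

    Backgrounds are measured per droplet at the droplet's focal plane, so
    no baseline model is fitted here.  Negative residual intensities are
    retained to preserve the noise statistics.
    """
    if not np.array_equal(spectrum.wavenumbers, background.wavenumbers):
        raise ValueError("spectrum and background grids differ")
    return spectrum.copy_with(
        spectrum.intensities - background.intensities, background_subtracted=True
    )


def _parse_method(method) -> tuple[str, float | None]:
    if isinstance(method, (tuple, list)):
        return "peak", float(method[1])
    m = str(method).lower()
    if m.startswith("peak@"):
        return "peak", float(m.split("@", 1)[1])
    if m in ("vector", "simplex", "peak"):
        if m == "peak":
            raise ValueError("peak normalization needs a wavenumber: 'peak@2940'")
        return m, None
    raise ValueError(f"unknown normalization method {method!r}")


def peak_intensity(spectrum: RamanSpectrum, nu: float, window: float = 5.0) -> float:
    """Intensity at band *nu*: max within ``nu +/- window`` cm-1.

    The window absorbs 1-2 cm-1 calibration jitter; ``window=0`` falls back
    to the nearest grid point.
    """
    wn = spectrum.wavenumbers
    if nu < wn[0] or nu > wn[-1]:
        raise ValueError(f"band {nu} cm-1 outside the grid [{wn[0]}, {wn[-1]}]")
    if window <= 0:
        return float(spectrum.intensities[np.argmin(np.abs(wn - nu))])
    sel = (wn >= nu - window) & (wn <= nu + window)
    return float(spectrum.intensities[sel].max())


def normalize_spectrum(spectrum: RamanSpectrum, method) -> RamanSpectrum:
    """Normalize a spectrum.

    method:
      * ``"vector"`` — divide by the Euclidean norm (unit L2).
      * ``"simplex"`` — closure to sum one; if negative intensities are
        present the minimum is first shifted to zero (shift recorded in
        metadata, with a warning).
      * ``"peak@NU"`` — divide by the intensity at the grid point nearest
        *NU* (e.g. the 2940 cm-1 protein peak), so that point equals 1.
    """
    kind, nu = _parse_method(method)
    x = spectrum.intensities
    chain = str(spectrum.metadata.get("preprocessing", ""))
    if kind == "vector":
        norm = float(np.linalg.norm(x))
        if norm == 0:
            raise ValueError("cannot vector-normalize an all-zero spectrum")
        out, tag = x / norm, "vector"
        return spectrum.copy_with(out, preprocessing=_chain(chain, tag))
    if kind == "simplex":
        shift = 0.0
        if np.any(x < 0):
            shift = float(-x.min())
            warnings.warn(
                "negative intensities under simplex normalization; "
                f"shifting minimum to zero (shift={shift:.4g})",
                stacklevel=2,
            )
            x = x + shift
        total = float(x.sum())
        if total == 0:
            raise ValueError("cannot simplex-normalize: intensities sum to zero")
        return spectrum.copy_with(
            x / total,
            preprocessing=_chain(chain, "simplex"),
            simplex_shift=shift,
        )
    # peak@nu: anchor the named grid point itself at 1
    ref = peak_intensity(spectrum, nu, window=0.0)
    if ref <= 0:
        raise ValueError(f"peak normalization undefined: I({nu}) = {ref}")
    return spectrum.copy_with(
        spectrum.intensities / ref, preprocessing=_chain(chain, f"peak@{nu:g}")
    )


def _chain(existing: str, step: str) -> str:
    return f"{existing}>{step}" if existing else step


def normalize_set(sset: SpectrumSet, methods: Sequence | str) -> SpectrumSet:
    """Apply a normalization chain to every spectrum of a set, in order."""
    if isinstance(methods, str):
        methods = [m for m in methods.split(",") if m]
    spectra = list(sset)
    for method in methods:
        spectra = [normalize_spectrum(s, method) for s in spectra]
    return SpectrumSet.from_spectra(spectra)


# ---------------------------------------------------------------------------
# Group averaging
# ---------------------------------------------------------------------------

@dataclass
class GroupStats:
    """Per-group mean spectrum and per-point sample SD (ddof=1).

    ``sds[key]`` is None for singleton groups (SD undefined), and such
    groups are listed in ``singleton_groups``.
    """

    wavenumbers: np.ndarray
    means: dict
    sds: dict
    counts: dict
    factors: tuple

    @property
    def singleton_groups(self) -> list:
        return [k for k, n in self.counts.items() if n < 2]


def group_average(sset: SpectrumSet, factors: str | Sequence[str]) -> GroupStats:
    """Mean and sample SD per wavenumber within each factor-level group."""
    if isinstance(factors, str):
        factors = (factors,)
    means, sds, counts = {}, {}, {}
    for key, sub in sset.groupby(list(factors)):
        means[key] = sub.intensities.mean(axis=0)
        counts[key] = len(sub)
        sds[key] = sub.intensities.std(axis=0, ddof=1) if len(sub) >= 2 else None
    return GroupStats(sset.wavenumbers.copy(), means, sds, counts, tuple(factors))
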