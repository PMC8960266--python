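#!/usr/bin/env python
"""Preprocess the cohort and plot per-group mean spectra with SD bands.

Reads results/cohort (from 01_simulate_cohort.py), applies the clustering
preprocessing chain (vector then simplex normalization; the synthetic
cohort is generated background-free, so no paired subtraction is needed),
and writes per-group means +/- 1 SD over the C-H stretching region.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from ramanld.spectra_prep import group_average, normalize_set, read_spectrum_set

IN = Path("scratch/cohort")
OUT = Path("results")
BIG = Path("scratch")


def main() -> None:
    sset = read_spectrum_set(IN)
    prepped = normalize_set(sset, ["vector", "simplex"])
    stats = group_average(prepped, ["methionine_x", "insulin_x"])

    rows = []
    fig, ax = plt.subplots(figsize=(8, 4))
    sel = (stats.wavenumbers >= 2700) & (stats.wavenumbers <= 3100)
    for key, mean in stats.means.items():
        sd = stats.sds[key]
        label = f"met {key[0]:g}x / ins {key[1]:g}x"
        ax.plot(stats.wavenumbers[sel], mean[sel], label=label, lw=0.8)
        ax.fill_between(
            stats.wavenumbers[sel],
            (mean - sd)[sel],
            (mean + sd)[sel],
            alpha=0.2,
        )
        for wn, m, s in zip(stats.wavenumbers, mean, sd):
            rows.append(
                {
                    "methionine_x": key[0],
                    "insulin_x": key[1],
                    "wavenumber": wn,
                    "mean": m,
                    "sd": s,
                }
            )
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel("normalized intensity")
    ax.legend(fontsize=6)
    fig.tight_layout()
    fig.savefig(OUT / "group_mean_spectra.png", dpi=150)
    pd.DataFrame(rows).to_csv(BIG / "group_mean_spectra.csv", index=False)
    print(f"{len(stats.means)} groups averaged; n per group:", stats.counts)
    print("wrote results/group_mean_spectra.png, scratch/group_mean_spectra.csv")


if __name__ == "__main__":
    main()
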