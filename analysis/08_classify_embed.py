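#!/usr/bin/env python
"""Classify the cohort by factor and embed it with PCA -> t-SNE.

Trains the single-hidden-layer MLP (width 100, L2 2e-4, <= 200
iterations) on the cohort per factor, then embeds the top-10 PC scores
with t-SNE (perplexity 30, no exaggeration) for visualization.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from ramanld.chemometrics_ml import (
    ClassifierConfig,
    EmbeddingConfig,
    embed_pca_tsne,
    train_spectrum_classifier,
)
from ramanld.spectra_prep import read_spectrum_set

IN = Path("scratch/cohort")
OUT = Path("results")


def main() -> None:
    sset = read_spectrum_set(IN)
    summary = {}
    for factor in ("methionine_x", "insulin_x"):
        res = train_spectrum_classifier(sset, factor, ClassifierConfig(seed=0))
        summary[factor] = {
            "held_out_accuracy": res.accuracy,
            "classes": [str(c) for c in res.classes],
            "confusion": res.confusion.to_numpy().tolist(),
        }
        print(f"{factor}: held-out accuracy {res.accuracy:.2f}")
    (OUT / "classifier_summary.json").write_text(json.dumps(summary, indent=2))

    coords, evr = embed_pca_tsne(sset, EmbeddingConfig(perplexity=30, seed=0))
    coords.to_csv(OUT / "tsne_coordinates.csv", index=False)
    print(f"top-10 PCs explain {100 * evr.sum():.1f}% of variance")

    fig, ax = plt.subplots(figsize=(5, 4.5))
    for (met, ins), sub in coords.groupby(["methionine_x", "insulin_x"]):
        ax.scatter(sub["tsne_1"], sub["tsne_2"], s=8, label=f"met {met:g}x ins {ins:g}x")
    ax.legend(fontsize=6)
    ax.set_xlabel("t-SNE 1"); ax.set_ylabel("t-SNE 2")
    fig.tight_layout()
    fig.savefig(OUT / "tsne_embedding.png", dpi=150)
    print("wrote results/classifier_summary.json, tsne_coordinates.csv, tsne_embedding.png")


if __name__ == "__main__":
    main()
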