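"""Spectral classification and embedding.

Classification uses a single-hidden-layer rectified perceptron (100
hidden units, softmax output, cross-entropy loss with L2 penalty
alpha = 2e-4, Adam first-order updates W_{i+1} = W_i - eps * grad Loss,
at most 200 iterations), on spectra range-normalized to [0, 1].
Visualization uses PCA (top 10 components) followed by t-SNE at
perplexity 30 with no early exaggeration (factor 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA
from sklearn.exceptions import ConvergenceWarning
from sklearn.manifold import TSNE
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier

from .spectra_prep import SpectrumSet

__all__ = [
    "ClassifierConfig",
    "ClassifierResult",
    "EmbeddingConfig",
    "range_normalize",
    "train_spectrum_classifier",
    "embed_pca_tsne",
]


@dataclass
class ClassifierConfig:
    hidden_width: int = 100
    alpha: float = 2e-4  # L2 penalty
    learning_rate_init: float = 1e-3  # eps; the update-rule step size
    max_iter: int = 200
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hidden_width < 1:
            raise ValueError("hidden width must be >= 1")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test fraction must lie in (0, 1)")


@dataclass
class ClassifierResult:
    model: MLPClassifier
    classes: list
    accuracy: float
    confusion: pd.DataFrame
    config: ClassifierConfig


def range_normalize(X: np.ndarray) -> np.ndarray:
    """Min-max scale each spectrum to [0, 1] (same range for all spectra)."""
    X = np.asarray(X, float)
    lo = X.min(axis=1, keepdims=True)
    hi = X.max(axis=1, keepdims=True)
    span = hi - lo
    if np.any(span == 0):
        raise ValueError("constant spectrum cannot be range-normalized")
    return (X - lo) / span


def train_spectrum_classifier(
    sset: SpectrumSet, factor: str, config: ClassifierConfig | None = None
) -> ClassifierResult:
    """Train the MLP on a stratified split and report held-out accuracy."""
    config = config or ClassifierConfig()
    y_raw = sset.labels(factor)
    classes = sorted(pd.unique(y_raw).tolist())
    if len(classes) < 2:
        raise ValueError("need at least 2 classes to classify")
    # categorical factor levels may be numeric (e.g. insulin 0.1x); encode
    # as strings so the classifier treats them as class labels
    encode = {c: str(c) for c in classes}
    y = np.asarray([encode[v] for v in y_raw])
    X = range_normalize(sset.intensities)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X,
        y,
        test_size=config.test_fraction,
        stratify=y,
        random_state=config.seed,
    )
    model = MLPClassifier(
        hidden_layer_sizes=(config.hidden_width,),
        activation="relu",
        solver="adam",
        alpha=config.alpha,
        learning_rate_init=config.learning_rate_init,
        max_iter=config.max_iter,
        random_state=config.seed,
    )
    with warnings.catch_warnings():
        # the iteration cap is part of the protocol, not a failure
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(X_tr, y_tr)
    pred = model.predict(X_te)
    acc = float(np.mean(pred == y_te))
    label_order = [encode[c] for c in classes]
    conf = pd.DataFrame(
        confusion_matrix(y_te, pred, labels=label_order),
        index=classes,
        columns=classes,
    )
    return ClassifierResult(model, classes, acc, conf, config)


@dataclass
class EmbeddingConfig:
    n_components: int = 10
    perplexity: float = 30.0
    early_exaggeration: float = 1.0  # 1 = no exaggeration
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_components < 2:
            raise ValueError("n_components must be >= 2")


def embed_pca_tsne(
    sset: SpectrumSet, config: EmbeddingConfig | None = None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA scores (top components by variance) fed to t-SNE.

    Returns per-spectrum 2-D coordinates joined with the metadata labels,
    plus the PCA explained-variance ratios.  Deterministic for a fixed
    seed.
    """
    config = config or EmbeddingConfig()
    X = sset.intensities
    n = X.shape[0]
    if n <= config.n_components:
        raise ValueError("need more samples than PCA components")
    if config.perplexity >= n / 3:
        raise ValueError("perplexity must be < n / 3")
    if np.any(X.std(axis=1) == 0):
        raise ValueError("degenerate (constant) spectra present")
    pca = PCA(n_components=config.n_components, random_state=config.seed)
    scores = pca.fit_transform(X)
    tsne = TSNE(
        n_components=2,
        perplexity=config.perplexity,
        early_exaggeration=config.early_exaggeration,
        init="pca",
        random_state=config.seed,
    )
    coords = tsne.fit_transform(scores)
    out = sset.metadata.copy()
    out["tsne_1"] = coords[:, 0]
    out["tsne_2"] = coords[:, 1]
    return out, pca.explained_variance_ratio_
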