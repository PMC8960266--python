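"""Peak-ratio extraction and the study's statistical tests.

Named ratios (per LD spectrum, peak intensities by the +/- 5 cm-1
window-max rule):

* ``ch2_ch3``     = I(2850) / I(2935)  — total lipid : protein
* ``cdl_cdp``     = I(2135) / I(2180)  — de novo lipid : de novo protein
* ``cdl_ch2``     = I(2135) / I(2850)  — de novo lipid : total lipid
* ``arrangement`` = I(2850) / I(2880)  — acyl-chain lattice order (inverse)
* ``unsaturation``= I(3010)            — unsaturated-lipid intensity

Statistics: quadrature-propagated ratio-difference contrasts, balanced
two-way ANOVA with sum-to-zero ("constrained") effect constraints, and
two-tailed two-sample t-tests (Welch by default).  For a balanced design
the classical sums of squares coincide for Types I/II/III, so the direct
cell-mean decomposition below is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .spectra_prep import SpectrumSet, peak_intensity

__all__ = [
    "DEFAULT_PEAKS",
    "RATIO_DEFINITIONS",
    "compute_ratios",
    "ratio_contrast",
    "RatioContrast",
    "AnovaTable",
    "anova2_balanced",
    "t_test_two_tailed",
    "TTestResult",
    "adjust_pvalues",
    "significance_marker",
]

DEFAULT_PEAKS = {
    "I2135": 2135.0,
    "I2180": 2180.0,
    "I2850": 2850.0,
    "I2880": 2880.0,
    "I2935": 2935.0,
    "I3010": 3010.0,
}

#: ratio name -> (numerator peak, denominator peak)
RATIO_DEFINITIONS = {
    "ch2_ch3": ("I2850", "I2935"),
    "cdl_cdp": ("I2135", "I2180"),
    "cdl_ch2": ("I2135", "I2850"),
    "arrangement": ("I2850", "I2880"),
}


def compute_ratios(
    sset: SpectrumSet, peaks: dict | None = None, window: float = 5.0
) -> pd.DataFrame:
    """One row per spectrum: metadata, peak intensities, named ratios.

    Ratios with non-positive denominators are NaN and flagged in a
    companion ``<ratio>_defined`` column (never silently dropped).  A
    requested band outside the grid raises, naming the band.
    """
    peaks = dict(DEFAULT_PEAKS if peaks is None else peaks)
    rows = []
    for spec in sset:
        row = dict(spec.metadata)
        for name, nu in peaks.items():
            row[name] = peak_intensity(spec, nu, window=window)
        for rname, (num, den) in RATIO_DEFINITIONS.items():
            if num in row and den in row:
                defined = row[den] > 0
                row[rname] = row[num] / row[den] if defined else float("nan")
                row[f"{rname}_defined"] = bool(defined)
        if "I3010" in row:
            row["unsaturation"] = row["I3010"]
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class RatioContrast:
    """Difference of group means with quadrature-propagated SD."""

    difference: float
    sd: float
    defined: bool


def ratio_contrast(group_x: tuple, group_y: tuple) -> RatioContrast:
    """Contrast two groups given ``(mean, sd)`` each.

    SD propagates in quadrature: ``sqrt(sd_x^2 + sd_y^2)``.  A missing SD
    (None/NaN) flags the contrast rather than raising.
    """
    mean_x, sd_x = group_x
    mean_y, sd_y = group_y
    diff = float(mean_x) - float(mean_y)
    if sd_x is None or sd_y is None or math.isnan(sd_x) or math.isnan(sd_y):
        return RatioContrast(diff, float("nan"), False)
    return RatioContrast(diff, math.hypot(float(sd_x), float(sd_y)), True)


@dataclass
class AnovaTable:
    """Balanced two-factor ANOVA decomposition.

    One row per term (A, B, AxB, error) of sum of squares, df, mean
    square, F, p.  ``degenerate`` marks an all-equal response (0/0 F
    statistics, reported as NaN).
    """

    terms: pd.DataFrame
    factor_a: str = "A"
    factor_b: str = "B"
    degenerate: bool = False

    def __getitem__(self, term: str) -> pd.Series:
        return self.terms.loc[term]

    @property
    def ss_total(self) -> float:
        return float(self.terms["sum_sq"].sum())


def anova2_balanced(
    values, factor_a_labels, factor_b_labels, names: tuple = ("A", "B")
) -> AnovaTable:
    """Balanced two-way ANOVA with sum-to-zero effect constraints.

    Requires a fully balanced design (equal n >= 2 per cell; with n = 1
    the interaction is inestimable).  F is MS_term / MS_error and p comes
    from the F distribution.  For balanced data this classical cell-mean
    decomposition equals the constrained (Type III) sums of squares.
    """
    y = np.asarray(values, dtype=float)
    a = np.asarray(factor_a_labels)
    b = np.asarray(factor_b_labels)
    if not (y.size == a.size == b.size):
        raise ValueError("values and label vectors must have equal length")
    a_levels = np.unique(a)
    b_levels = np.unique(b)
    counts = {
        (ai, bi): int(np.sum((a == ai) & (b == bi)))
        for ai in a_levels
        for bi in b_levels
    }
    ns = set(counts.values())
    if len(ns) != 1:
        raise ValueError(f"unbalanced design: cell counts {sorted(ns)}")
    n = ns.pop()
    if n < 2:
        raise ValueError("n = 1 per cell: interaction inestimable")
    na, nb = len(a_levels), len(b_levels)
    if na < 2 or nb < 2:
        raise ValueError("each factor needs at least 2 levels")

    cells = np.empty((na, nb, n))
    for i, ai in enumerate(a_levels):
        for j, bi in enumerate(b_levels):
            cells[i, j] = y[(a == ai) & (b == bi)]
    grand = cells.mean()
    mean_a = cells.mean(axis=(1, 2))
    mean_b = cells.mean(axis=(0, 2))
    mean_ab = cells.mean(axis=2)

    ss_a = nb * n * np.sum((mean_a - grand) ** 2)
    ss_b = na * n * np.sum((mean_b - grand) ** 2)
    ss_ab = n * np.sum(
        (mean_ab - mean_a[:, None] - mean_b[None, :] + grand) ** 2
    )
    ss_e = np.sum((cells - mean_ab[:, :, None]) ** 2)
    df = {
        names[0]: na - 1,
        names[1]: nb - 1,
        f"{names[0]}:{names[1]}": (na - 1) * (nb - 1),
        "error": na * nb * (n - 1),
    }
    ss = {
        names[0]: ss_a,
        names[1]: ss_b,
        f"{names[0]}:{names[1]}": ss_ab,
        "error": ss_e,
    }
    ms = {k: ss[k] / df[k] for k in ss}
    degenerate = ms["error"] == 0.0
    rows = []
    for term in ss:
        if term == "error":
            f_val, p_val = float("nan"), float("nan")
        elif degenerate:
            f_val, p_val = float("nan"), float("nan")
        else:
            f_val = ms[term] / ms["error"]
            p_val = float(stats.f.sf(f_val, df[term], df["error"]))
        rows.append(
            {
                "term": term,
                "sum_sq": float(ss[term]),
                "df": df[term],
                "mean_sq": float(ms[term]),
                "F": f_val,
                "p": p_val,
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    return AnovaTable(table, names[0], names[1], degenerate=bool(degenerate))


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def t_test_two_tailed(x, y, variant: str = "welch") -> TTestResult:
    """Two-sample two-tailed t-test (Welch default, pooled optional)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs n >= 2")
    if variant not in ("welch", "pooled"):
        raise ValueError(f"unknown t-test variant {variant!r}")
    res = stats.ttest_ind(x, y, equal_var=(variant == "pooled"))
    return TTestResult(float(res.statistic), float(res.df), float(res.pvalue))


def adjust_pvalues(pvalues, method: str = "fdr_bh") -> np.ndarray:
    """Optional multiplicity adjustment across a panel of pairwise tests."""
    from statsmodels.stats.multitest import multipletests

    return multipletests(np.asarray(pvalues, float), method=method)[1]


def significance_marker(p: float, symbol: str = "*") -> str:
    """Figure-style marker at thresholds 0.05 / 0.01 / 0.001 / 0.0001."""
    if np.isnan(p):
        return ""
    for k, thr in enumerate((0.0001, 0.001, 0.01, 0.05)):
        if p < thr:
            return symbol * (4 - k)
    return "ns"
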