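"""Mechanistic diagnostics of codon usage bias.

Three classical plots distinguish mutational pressure from selection:

* **ENC-plot** — observed ENC against GC3s, compared with the ENC expected
  when composition alone drives usage,
  ``ENC_expected = 2 + s + 29/(s^2 + (1-s)^2)``, and the signed departure
  ``ENC_ratio = (expected - actual)/expected``.
* **Neutrality plot** — ordinary least-squares regression of GC12 (mean of
  first- and second-position GC) on GC3; slope near 1 indicates mutation
  dominance, near 0 selection.
* **PR2 plot** — third-position base balance A3/(A3+T3) versus G3/(G3+C3)
  over the five fourfold-degenerate families (Val, Pro, Thr, Ala, Gly);
  (0.5, 0.5) under strand-symmetric, selection-free usage.

Plus the pairwise Pearson correlation matrix of the per-gene parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import CodonCounts, GeneMetrics
from .genetic_code import FOURFOLD_PR2_AMINO_ACIDS, GeneticCode, standard_code

__all__ = [
    "enc_expected",
    "enc_ratio",
    "enc_plot_table",
    "NeutralityResult",
    "neutrality_fit",
    "pr2_coordinates",
    "pr2_table",
    "CorrelationMatrix",
    "parameter_correlations",
    "enc_ratio_histogram",
]

#: Fig.-3-style ENC-ratio histogram bin edges (width 0.05, left-closed)
ENC_RATIO_BINS = np.round(np.arange(-0.15, 0.25 + 1e-9, 0.05), 10)


def enc_expected(gc3s: float, variant: str = "corrected") -> float:
    """Expected ENC under pure compositional (mutation) pressure.

    With ``variant="corrected"`` (default) the denominator is Wright's
    ``s^2 + (1-s)^2``. ``variant="as-printed"`` reproduces a variant that
    circulates in the literature with a first-order ``s`` term in the
    denominator, kept only for audit purposes.
    """
    s = float(gc3s)
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"GC3s must be a fraction in [0, 1], got {s}")
    if variant == "corrected":
        denom = s * s + (1.0 - s) ** 2
    elif variant == "as-printed":
        denom = s + (1.0 - s) ** 2
    else:
        raise ValueError(f"unknown ENC-curve variant {variant!r}")
    return 2.0 + s + 29.0 / denom


def enc_ratio(expected: float, actual: float) -> float:
    """Signed relative departure from the expected curve; positive means the
    gene lies below it (stronger bias than composition alone explains)."""
    if expected <= 0:
        raise ValueError("expected ENC must be positive")
    return (expected - actual) / expected


def enc_plot_table(
    metrics: Sequence[GeneMetrics], variant: str = "corrected"
) -> pd.DataFrame:
    """Per-gene ENC-plot coordinates: GC3s (fraction), observed ENC,
    expected ENC at that GC3s, and the ENC ratio."""
    rows = []
    for m in metrics:
        s = m.gc3s / 100.0
        exp = enc_expected(s, variant=variant)
        rows.append(
            {
                "gene": m.gene_id,
                "gc3s": s,
                "enc_actual": m.enc,
                "enc_expected": exp,
                "enc_ratio": enc_ratio(exp, m.enc),
            }
        )
    return pd.DataFrame(rows)


def enc_ratio_histogram(ratios: Sequence[float]) -> pd.DataFrame:
    """Bin ENC ratios into the standard width-0.05 bins over [-0.15, 0.25]."""
    counts, edges = np.histogram(np.asarray(ratios, dtype=float), bins=ENC_RATIO_BINS)
    return pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "n_genes": counts}
    )


@dataclass
class NeutralityResult:
    """OLS fit of GC12 on GC3 (both as fractions) plus the Pearson test."""

    gc12: np.ndarray
    gc3: np.ndarray
    slope: float
    intercept: float
    pearson_r: float
    p_value: float

    @property
    def n(self) -> int:
        return len(self.gc3)

    def to_frame(self, gene_ids: Sequence[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"gc3": self.gc3, "gc12": self.gc12})
        if gene_ids is not None:
            df.insert(0, "gene", list(gene_ids))
        return df


def neutrality_fit(metrics: Sequence[GeneMetrics] | pd.DataFrame) -> NeutralityResult:
    """Regress per-gene GC12 on GC3 (fractions); Pearson r with a two-sided
    p-value from the t distribution on n-2 degrees of freedom.

    Accepts a list of :class:`GeneMetrics` or any DataFrame with ``gc1``,
    ``gc2`` and ``gc3`` columns in percent.
    """
    if len(metrics) < 3:
        raise ValueError("neutrality fit needs at least 3 genes")
    if isinstance(metrics, pd.DataFrame):
        gc3 = metrics["gc3"].to_numpy(dtype=float) / 100.0
        gc12 = (metrics["gc1"] + metrics["gc2"]).to_numpy(dtype=float) / 2.0 / 100.0
    else:
        gc3 = np.array([m.gc3 / 100.0 for m in metrics])
        gc12 = np.array([m.gc12 / 100.0 for m in metrics])
    if np.allclose(gc3, gc3[0]):
        raise ValueError("neutrality fit undefined: GC3 has zero variance")
    fit = stats.linregress(gc3, gc12)
    return NeutralityResult(
        gc12=gc12,
        gc3=gc3,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        pearson_r=float(fit.rvalue),
        p_value=float(fit.pvalue),
    )


def pr2_coordinates(
    counts: CodonCounts, code: GeneticCode | None = None
) -> tuple[float, float]:
    """(x, y) = (G3/(G3+C3), A3/(A3+T3)) over the five fourfold-degenerate
    families only. A zero denominator yields NaN for that coordinate."""
    code = code or standard_code()
    tally = {"A": 0, "T": 0, "C": 0, "G": 0}
    total = 0
    for aa in FOURFOLD_PR2_AMINO_ACIDS:
        for c in code.families[aa]:
            n = counts.get(c)
            tally[c[2]] += n
            total += n
    if total == 0:
        raise ValueError(
            f"PR2 undefined: no fourfold-family codons in scope {counts.scope!r}"
        )
    at = tally["A"] + tally["T"]
    gc = tally["G"] + tally["C"]
    y = tally["A"] / at if at > 0 else math.nan
    x = tally["G"] / gc if gc > 0 else math.nan
    return x, y


def pr2_table(
    gene_counts: Sequence[CodonCounts], code: GeneticCode | None = None
) -> pd.DataFrame:
    code = code or standard_code()
    rows = []
    for cc in gene_counts:
        x, y = pr2_coordinates(cc, code)
        rows.append({"gene": cc.scope, "g3_over_gc3": x, "a3_over_at3": y})
    return pd.DataFrame(rows)


_CORR_PARAMS = [
    ("codon_counts", "CC"),
    ("gc1", "GC1"),
    ("gc2", "GC2"),
    ("gc3", "GC3"),
    ("gcall", "GCall"),
    ("gc3s", "GC3s"),
    ("enc", "ENC"),
    ("cai", "CAI"),
    ("cbi", "CBI"),
    ("fop", "Fop"),
]


@dataclass
class CorrelationMatrix:
    """Symmetric Pearson r and two-sided p matrices over codon parameters."""

    r: pd.DataFrame
    p: pd.DataFrame

    def stars(self) -> pd.DataFrame:
        """Significance flags: '**' at p<0.01, '*' at p<0.05, '' otherwise."""
        def star(p: float) -> str:
            if math.isnan(p):
                return ""
            if p < 0.01:
                return "**"
            if p < 0.05:
                return "*"
            return ""

        return self.p.map(star)


def parameter_correlations(metrics_frame: pd.DataFrame) -> CorrelationMatrix:
    """Pairwise Pearson correlations (with p-values) of the per-gene codon
    parameters present in `metrics_frame` (columns as written by
    :func:`cubtk.codon_metrics.metrics_to_frame`)."""
    cols = [(c, label) for c, label in _CORR_PARAMS if c in metrics_frame.columns]
    if len(metrics_frame) < 3:
        raise ValueError("correlation analysis needs at least 3 genes")
    labels = [label for _, label in cols]
    n = len(labels)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    data = [metrics_frame[c].to_numpy(dtype=float) for c, _ in cols]
    for i in range(n):
        for j in range(i, n):
            xi, xj = data[i], data[j]
            if i == j:
                r[i, j] = 1.0
                p[i, j] = 0.0
                continue
            ok = ~(np.isnan(xi) | np.isnan(xj))
            if ok.sum() < 3 or np.allclose(xi[ok], xi[ok][0]) or np.allclose(xj[ok], xj[ok][0]):
                continue
            res = stats.pearsonr(xi[ok], xj[ok])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    return CorrelationMatrix(
        r=pd.DataFrame(r, index=labels, columns=labels),
        p=pd.DataFrame(p, index=labels, columns=labels),
    )
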