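"""Diagnostic figures: ENC-plot, ENC-ratio histogram, neutrality plot,
PR2 plot and the comparative dendrogram. Each function draws on a supplied
or fresh matplotlib Axes and returns it."""

from __future__ import annotations

import numpy as np

from . import bias_diagnostics as diag


def _ax(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def enc_plot(enc_table, ax=None, variant: str = "corrected"):
    """Observed ENC vs GC3s with the expected-under-mutation curve."""
    ax = _ax(ax)
    s = np.linspace(0.005, 0.995, 200)
    ax.plot(s, [diag.enc_expected(v, variant) for v in s], "k-", lw=1, label="expected")
    ax.scatter(enc_table["gc3s"], enc_table["enc_actual"], s=18, label="genes")
    ax.set_xlabel("GC3s")
    ax.set_ylabel("ENC")
    ax.set_ylim(15, 65)
    ax.legend(frameon=False)
    return ax


def enc_ratio_hist(enc_table, ax=None):
    ax = _ax(ax)
    hist = diag.enc_ratio_histogram(enc_table["enc_ratio"])
    ax.bar(hist["bin_left"], hist["n_genes"], width=0.05, align="edge", edgecolor="k")
    ax.set_xlabel("ENC ratio")
    ax.set_ylabel("number of genes")
    return ax


def neutrality_plot(result, ax=None):
    """GC12 against GC3 with the fitted regression line."""
    ax = _ax(ax)
    ax.scatter(result.gc3, result.gc12, s=18)
    xs = np.array([result.gc3.min(), result.gc3.max()])
    ax.plot(xs, result.intercept + result.slope * xs, "r-", lw=1)
    ax.set_xlabel("GC3")
    ax.set_ylabel("GC12")
    return ax


def pr2_plot(pr2_table, ax=None):
    """Third-position base balance over the fourfold families."""
    ax = _ax(ax)
    ax.scatter(pr2_table["g3_over_gc3"], pr2_table["a3_over_at3"], s=18)
    ax.axhline(0.5, color="k", lw=0.8)
    ax.axvline(0.5, color="k", lw=0.8)
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+T3)")
    return ax


def dendrogram_plot(cluster_result, ax=None):
    from scipy.cluster import hierarchy

    ax = _ax(ax)
    hierarchy.dendrogram(
        cluster_result.linkage_matrix,
        labels=list(cluster_result.labels),
        orientation="right",
        ax=ax,
    )
    ax.set_xlabel("squared Euclidean distance")
    return ax
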