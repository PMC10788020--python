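"""Packaged reference tables.

Small published reference values for the 28 protein-coding genes of the
*Hemerocallis citrina* mitochondrial genome, shipped as plain TSV so that
rule-level analyses (neutrality regression, optimal-codon flagging) can be
exercised and checked without any sequence download.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_hcitrina_gene_metrics", "load_hcitrina_group_rscu"]


def _read(name: str) -> pd.DataFrame:
    ref = resources.files("cubtk.data").joinpath(name)
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def load_hcitrina_gene_metrics() -> pd.DataFrame:
    """Published per-gene characteristic parameters of the 28 H. citrina
    mitochondrial protein-coding genes: codon counts, GC1/GC2/GC3/GCall
    (percent), CAI, CBI, Fop and ENC."""
    return _read("hcitrina_mt_gene_metrics.tsv")


def load_hcitrina_group_rscu() -> pd.DataFrame:
    """Published high-/low-bias group RSCU contrast for the 59 synonymous
    codons of the H. citrina mitogenome: RSCU_high, RSCU_low, delta RSCU,
    and the published optimal-codon annotation (0/1)."""
    return _read("hcitrina_mt_group_rscu.tsv")
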