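"""Per-gene and pooled codon-composition indices.

Implements the classical codon-usage statistics: codon counts, positional
GC content (GC1/GC2/GC3/GCall), silent-site base composition (A3s/T3s/
C3s/G3s and GC3s with availability normalisation), relative synonymous
codon usage (RSCU), Wright's effective number of codons (ENC), the codon
adaptation index (CAI) with relative-adaptiveness weights, the codon bias
index (CBI) and the frequency of optimal codons (Fop).

All statistics are functions of a gene's (or pooled set's) sense-codon
counts; the terminal stop never contributes. Percentages are carried at
full precision; rounding happens only in report writers.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cds_io import CodingSequence
from .genetic_code import GeneticCode, dna_to_rna, standard_code

__all__ = [
    "CodonCounts",
    "RSCUProfile",
    "GeneMetrics",
    "count_codons",
    "pool_counts",
    "positional_gc",
    "silent_site_composition",
    "rscu",
    "enc",
    "reference_weights",
    "cai",
    "fop",
    "cbi",
]


@dataclass
class CodonCounts:
    """Sense-codon count vector for one gene or a pooled set."""

    counts: dict[str, int]
    scope: str = "pooled"

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = dict(self.counts)
        for codon, n in other.counts.items():
            merged[codon] = merged.get(codon, 0) + n
        return CodonCounts(counts=merged, scope="pooled")

    def to_series(self, code: GeneticCode | None = None) -> pd.Series:
        code = code or standard_code()
        return pd.Series(
            {c: self.get(c) for c in code.sense_codons}, name=self.scope, dtype=int
        )


def count_codons(gene: CodingSequence) -> CodonCounts:
    counts: dict[str, int] = {}
    for codon in gene.codons:
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCounts(counts=counts, scope=gene.gene_id)


def pool_counts(counts: Iterable[CodonCounts], scope: str = "pooled") -> CodonCounts:
    pooled: dict[str, int] = {}
    for cc in counts:
        for codon, n in cc.counts.items():
            pooled[codon] = pooled.get(codon, 0) + n
    return CodonCounts(counts=pooled, scope=scope)


def positional_gc(counts: CodonCounts) -> tuple[float, float, float, float]:
    """(GC1, GC2, GC3, GCall) as percentages over all counted codons."""
    total = counts.total
    if total == 0:
        raise ValueError(f"positional GC undefined: no codons in scope {counts.scope!r}")
    gc = [0, 0, 0]
    for codon, n in counts.counts.items():
        for k in range(3):
            if codon[k] in "GC":
                gc[k] += n
    gc1, gc2, gc3 = (100.0 * g / total for g in gc)
    return gc1, gc2, gc3, (gc1 + gc2 + gc3) / 3.0


def silent_site_composition(
    counts: CodonCounts, code: GeneticCode | None = None
) -> tuple[float, float, float, float, float]:
    """(A3s, T3s, C3s, G3s, GC3s) percentages over synonymous codons.

    GC3s is the fraction of synonymous codons ending G or C. Each X3s is
    normalised by availability: its denominator counts only codons in
    families that contain an X-ending synonym, so the four values need not
    sum to 100. An X3s with an empty denominator is returned as NaN.
    """
    code = code or standard_code()
    third_n = {"A": 0, "T": 0, "C": 0, "G": 0}
    avail_n = {"A": 0, "T": 0, "C": 0, "G": 0}
    n_syn = 0
    gc3s_n = 0
    for aa, family in code.families.items():
        fam_total = sum(counts.get(c) for c in family)
        if fam_total == 0:
            continue
        n_syn += fam_total
        fam_thirds = {c[2] for c in family}
        for base in fam_thirds:
            avail_n[base] += fam_total
        for c in family:
            n = counts.get(c)
            third_n[c[2]] += n
            if c[2] in "GC":
                gc3s_n += n
    if n_syn == 0:
        raise ValueError(
            f"silent-site composition undefined: no synonymous codons in {counts.scope!r}"
        )
    x3s = tuple(
        100.0 * third_n[b] / avail_n[b] if avail_n[b] > 0 else math.nan
        for b in ("A", "T", "C", "G")
    )
    return (*x3s, 100.0 * gc3s_n / n_syn)


@dataclass
class RSCUProfile:
    """RSCU per synonymous codon; AUG and UGG fixed at 1.0 by convention.

    A family with zero total usage yields NaN entries (not 0) for its codons.
    """

    values: dict[str, float]
    scope: str = "pooled"

    def get(self, codon: str) -> float:
        return self.values[codon]

    def to_series(self, rna: bool = False) -> pd.Series:
        vals = self.values
        if rna:
            vals = {dna_to_rna(c): v for c, v in vals.items()}
        return pd.Series(dict(sorted(vals.items())), name=self.scope, dtype=float)


def rscu(counts: CodonCounts, code: GeneticCode | None = None) -> RSCUProfile:
    """Relative synonymous codon usage: observed over family-uniform expectation.

    RSCU_ij = k * x_ij / sum_family(x), with k the family degeneracy; family
    sums therefore equal the degeneracy whenever the family is used.
    """
    code = code or standard_code()
    values: dict[str, float] = {"ATG": 1.0, "TGG": 1.0}
    for aa, family in code.families.items():
        fam_total = sum(counts.get(c) for c in family)
        k = len(family)
        for c in family:
            values[c] = k * counts.get(c) / fam_total if fam_total > 0 else math.nan
    return RSCUProfile(values=values, scope=counts.scope)


def _family_homozygosity(counts: CodonCounts, family: Sequence[str]) -> float | None:
    """Wright's F-hat for one family; None when usage n < 2 (undefined)."""
    xs = [counts.get(c) for c in family]
    n = sum(xs)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in xs)
    return (n * sum_p2 - 1.0) / (n - 1.0)


def enc(counts: CodonCounts, code: GeneticCode | None = None) -> float:
    """Wright's effective number of codons.

    Family homozygosities F-hat = (n*sum p_i^2 - 1)/(n - 1) are averaged
    within each degeneracy class (families with n < 2 or F-hat <= 0 are
    skipped), and ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at 61. A
    missing 3-fold (Ile) class is imputed as F3 = (F2 + F4)/2; any other
    missing class makes the estimate undefined (NaN, with a warning).
    """
    code = code or standard_code()
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.families.items():
        f_hat = _family_homozygosity(counts, family)
        if f_hat is not None and f_hat > 0:
            class_f[len(family)].append(f_hat)

    means = {k: (sum(v) / len(v) if v else None) for k, v in class_f.items()}
    if means[2] is None or means[4] is None or means[6] is None:
        missing = [k for k in (2, 4, 6) if means[k] is None]
        warnings.warn(
            f"ENC undefined for scope {counts.scope!r}: no usable family in "
            f"degeneracy class(es) {missing}"
        )
        return math.nan
    if means[3] is None:
        means[3] = (means[2] + means[4]) / 2.0

    value = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(value, 61.0)


def reference_weights(
    reference: Iterable[CodonCounts] | CodonCounts,
    code: GeneticCode | None = None,
) -> dict[str, float]:
    """Relative adaptiveness w of each synonymous codon in a reference set.

    Pools the reference counts, replaces zero counts by 0.5 within each
    family (so no weight is exactly zero, and log w stays finite), then
    normalises by the family maximum: w_ij = x_ij / max_j x_ij.
    """
    code = code or standard_code()
    if isinstance(reference, CodonCounts):
        pooled = reference
    else:
        refs = list(reference)
        if not refs:
            raise ValueError("empty CAI reference set")
        pooled = pool_counts(refs, scope="cai_reference")
    if pooled.total == 0:
        raise ValueError("CAI reference set has no codons")

    w: dict[str, float] = {}
    for aa, family in code.families.items():
        xs = {c: (pooled.get(c) if pooled.get(c) > 0 else 0.5) for c in family}
        x_max = max(xs.values())
        for c in family:
            w[c] = xs[c] / x_max
    return w


def cai(counts: CodonCounts, w: Mapping[str, float], code: GeneticCode | None = None) -> float:
    """Codon adaptation index: geometric mean of w over synonymous codon
    occurrences (AUG/UGG excluded)."""
    code = code or standard_code()
    log_sum = 0.0
    n = 0
    for c in code.synonymous_codons:
        x = counts.get(c)
        if x == 0:
            continue
        log_sum += x * math.log(w[c])
        n += x
    if n == 0:
        raise ValueError(f"CAI undefined: no synonymous codons in scope {counts.scope!r}")
    return math.exp(log_sum / n)


def _considered_families(
    optimal_set: frozenset[str] | set[str], code: GeneticCode
) -> list[tuple[str, tuple[str, ...]]]:
    if not optimal_set:
        raise ValueError("empty optimal-codon set")
    syn = set(code.synonymous_codons)
    stray = set(optimal_set) - syn
    if stray:
        raise ValueError(f"optimal set contains non-synonymous codons: {sorted(stray)}")
    return [
        (aa, fam)
        for aa, fam in code.families.items()
        if any(c in optimal_set for c in fam)
    ]


def fop(
    counts: CodonCounts,
    optimal_set: frozenset[str] | set[str],
    code: GeneticCode | None = None,
) -> float:
    """Frequency of optimal codons: N_opt / N_syn over families that contain
    at least one optimal codon."""
    code = code or standard_code()
    n_opt = 0
    n_syn = 0
    for aa, fam in _considered_families(optimal_set, code):
        for c in fam:
            x = counts.get(c)
            n_syn += x
            if c in optimal_set:
                n_opt += x
    return n_opt / n_syn if n_syn else math.nan


def cbi(
    counts: CodonCounts,
    optimal_set: frozenset[str] | set[str],
    code: GeneticCode | None = None,
) -> float:
    """Codon bias index: (N_opt - N_rand)/(N_syn - N_rand), where N_rand is
    the optimal-codon count expected under uniform synonymous usage."""
    code = code or standard_code()
    n_opt = 0
    n_syn = 0
    n_rand = 0.0
    for aa, fam in _considered_families(optimal_set, code):
        fam_n = sum(counts.get(c) for c in fam)
        k_opt = sum(c in optimal_set for c in fam)
        n_syn += fam_n
        n_rand += fam_n * k_opt / len(fam)
        n_opt += sum(counts.get(c) for c in fam if c in optimal_set)
    denom = n_syn - n_rand
    return (n_opt - n_rand) / denom if denom > 0 else math.nan


@dataclass
class GeneMetrics:
    """One row of the per-gene characteristic-parameter table."""

    gene_id: str
    cc: int
    gc1: float
    gc2: float
    gc3: float
    gcall: float
    a3s: float
    t3s: float
    c3s: float
    g3s: float
    gc3s: float
    enc: float
    cai: float = math.nan
    cbi: float = math.nan
    fop: float = math.nan

    @property
    def gc12(self) -> float:
        return (self.gc1 + self.gc2) / 2.0


def compute_composition_metrics(
    gene: CodingSequence, code: GeneticCode | None = None
) -> GeneMetrics:
    """Composition indices and ENC for one gene (CAI/CBI/Fop are filled in
    later, once a reference set and an optimal-codon set exist)."""
    code = code or standard_code()
    counts = count_codons(gene)
    gc1, gc2, gc3, gcall = positional_gc(counts)
    a3s, t3s, c3s, g3s, gc3s = silent_site_composition(counts, code)
    return GeneMetrics(
        gene_id=gene.gene_id,
        cc=counts.total,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gcall=gcall,
        a3s=a3s,
        t3s=t3s,
        c3s=c3s,
        g3s=g3s,
        gc3s=gc3s,
        enc=enc(counts, code),
    )


def metrics_to_frame(metrics: Sequence[GeneMetrics]) -> pd.DataFrame:
    """Gene-per-row DataFrame in the conventional column order."""
    return pd.DataFrame(
        {
            "gene": [m.gene_id for m in metrics],
            "codon_counts": [m.cc for m in metrics],
            "gc1": [m.gc1 for m in metrics],
            "gc2": [m.gc2 for m in metrics],
            "gc3": [m.gc3 for m in metrics],
            "gcall": [m.gcall for m in metrics],
            "gc3s": [m.gc3s for m in metrics],
            "a3s": [m.a3s for m in metrics],
            "t3s": [m.t3s for m in metrics],
            "c3s": [m.c3s for m in metrics],
            "g3s": [m.g3s for m in metrics],
            "cai": [m.cai for m in metrics],
            "cbi": [m.cbi for m in metrics],
            "fop": [m.fop for m in metrics],
            "enc": [m.enc for m in metrics],
        }
    )
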