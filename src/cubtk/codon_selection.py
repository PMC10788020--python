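"""High-frequency and optimal codon identification.

High-frequency codons are those with pooled RSCU strictly greater than 1.
Optimal codons are found by the ENC-extreme group contrast: genes are
ranked by ENC, the lowest 10% form the high-bias group and the highest 10%
the low-bias group, RSCU is computed on each group's pooled counts, and a
codon is optimal when its high-bias-group RSCU is strictly greater than 1
and dRSCU = RSCU_high - RSCU_low strictly exceeds 0.08.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import pandas as pd

from .codon_metrics import CodonCounts, GeneMetrics, RSCUProfile, pool_counts, rscu
from .genetic_code import GeneticCode, aa_three_letter, dna_to_rna, standard_code

__all__ = [
    "BiasGroups",
    "high_frequency_codons",
    "build_bias_groups",
    "optimal_codons",
    "flag_optimal",
]


def high_frequency_codons(
    pooled_rscu: RSCUProfile, code: GeneticCode | None = None
) -> frozenset[str]:
    """Codons with pooled RSCU strictly greater than 1 (AUG/UGG excluded)."""
    code = code or standard_code()
    return frozenset(
        c
        for c in code.synonymous_codons
        if not math.isnan(pooled_rscu.get(c)) and pooled_rscu.get(c) > 1.0
    )


def _round_half_up(x: float) -> int:
    return int(Decimal(str(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class BiasGroups:
    """ENC-extreme gene groups and their pooled codon counts."""

    high_bias: tuple[str, ...]  # lowest-ENC genes (strongest bias)
    low_bias: tuple[str, ...]  # highest-ENC genes (weakest bias)
    high_counts: CodonCounts
    low_counts: CodonCounts
    fraction: float


def build_bias_groups(
    metrics: Sequence[GeneMetrics],
    gene_counts: Mapping[str, CodonCounts],
    fraction: float = 0.10,
) -> BiasGroups:
    """Split genes into ENC-extreme groups of size max(1, round-half-up(f*N)).

    Genes are ordered by ENC ascending with ties broken lexicographically by
    gene id; the first k form the high-bias group, the last k the low-bias
    group. Raises when the groups would overlap (2k > N).
    """
    usable = [m for m in metrics if not math.isnan(m.enc)]
    if len(usable) < 2:
        raise ValueError("bias groups need at least 2 genes with defined ENC")
    k = max(1, _round_half_up(fraction * len(usable)))
    if 2 * k > len(usable):
        raise ValueError(
            f"groups overlap: group size {k} twice exceeds {len(usable)} genes"
        )
    ranked = sorted(usable, key=lambda m: (m.enc, m.gene_id))
    high = tuple(m.gene_id for m in ranked[:k])
    low = tuple(m.gene_id for m in ranked[-k:])
    return BiasGroups(
        high_bias=high,
        low_bias=low,
        high_counts=pool_counts([gene_counts[g] for g in high], scope="high_bias"),
        low_counts=pool_counts([gene_counts[g] for g in low], scope="low_bias"),
        fraction=fraction,
    )


def flag_optimal(
    rscu_high: pd.Series, delta_rscu: pd.Series, delta_threshold: float = 0.08
) -> pd.Series:
    """The optimal-codon rule: high-bias-group RSCU strictly > 1 AND
    dRSCU strictly > `delta_threshold`. NaN entries are never optimal."""
    return (rscu_high > 1.0) & (delta_rscu > delta_threshold)


def optimal_codons(
    groups: BiasGroups,
    pooled_rscu: RSCUProfile | None = None,
    delta_threshold: float = 0.08,
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Per-codon report of the group contrast (Table-3 shape).

    Columns: amino_acid, codon (RNA alphabet), rscu_high, rscu_low,
    delta_rscu, high_frequency (pooled whole-set RSCU > 1, when a pooled
    profile is supplied), optimal. Rows ordered by amino acid then codon.
    A codon whose family is absent from either group has NaN group RSCU and
    is excluded from the optimal set with a warning.
    """
    code = code or standard_code()
    r_high = rscu(groups.high_counts, code)
    r_low = rscu(groups.low_counts, code)
    hi_freq = (
        high_frequency_codons(pooled_rscu, code) if pooled_rscu is not None else None
    )

    rows = []
    for aa in sorted(code.families, key=aa_three_letter):
        for c in code.families[aa]:
            rh, rl = r_high.get(c), r_low.get(c)
            rows.append(
                {
                    "amino_acid": aa_three_letter(aa),
                    "codon": dna_to_rna(c),
                    "rscu_high": rh,
                    "rscu_low": rl,
                    "delta_rscu": rh - rl,
                    "high_frequency": (c in hi_freq) if hi_freq is not None else pd.NA,
                }
            )
    df = pd.DataFrame(rows).sort_values(["amino_acid", "codon"], ignore_index=True)

    undefined = df["rscu_high"].isna() | df["rscu_low"].isna()
    if undefined.any():
        warnings.warn(
            "family absent from a bias group; codons excluded from the optimal "
            f"set: {', '.join(df.loc[undefined, 'codon'])}"
        )
    df["optimal"] = (
        flag_optimal(df["rscu_high"], df["delta_rscu"], delta_threshold) & ~undefined
    )
    return df
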