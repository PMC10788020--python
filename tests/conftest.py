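"""Shared fixtures: the standard code, toy gene builders, and count helpers."""

from __future__ import annotations

import pytest

from cubtk.cds_io import CodingSequence, RawCds
from cubtk.codon_metrics import CodonCounts
from cubtk.genetic_code import standard_code


@pytest.fixture(scope="session")
def code():
    return standard_code()


def make_cds(gene_id: str, body_codons: list[str], stop: str = "TAA") -> RawCds:
    """Raw candidate: ATG + body codons + stop."""
    return RawCds(gene_id=gene_id, sequence="ATG" + "".join(body_codons) + stop)


def make_gene(gene_id: str, body_codons: list[str], stop: str = "TAA") -> CodingSequence:
    """Validated gene: ATG + body codons + stop, codons pre-split."""
    seq = "ATG" + "".join(body_codons) + stop
    return CodingSequence(
        gene_id=gene_id, sequence=seq, codons=("ATG", *body_codons)
    )


def counts_from_usage(code, usage: dict[str, list[int]], scope: str = "toy") -> CodonCounts:
    """CodonCounts from per-family count lists (codons in sorted family order)."""
    counts: dict[str, int] = {}
    for aa, xs in usage.items():
        family = code.families[aa]
        assert len(xs) == len(family)
        for c, x in zip(family, xs):
            if x:
                counts[c] = x
    return CodonCounts(counts=counts, scope=scope)
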