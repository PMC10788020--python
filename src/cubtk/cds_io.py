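"""Reading, validating and filtering coding sequences.

A candidate CDS enters the analysis only if it starts with ATG, ends with a
stop codon (TAA/TAG/TGA), is at least ``min_length_bp`` long (default
300 bp, inclusive), has a length that is an exact multiple of three,
contains only unambiguous bases, has no internal stop codon, and is not an
exact duplicate of an earlier sequence. Every candidate, accepted or not,
is accounted for in a :class:`FilterReport`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import START_CODON, STOP_CODONS

__all__ = [
    "CodingSequence",
    "RawCds",
    "FilterReport",
    "read_cds",
    "filter_cds",
    "write_fasta",
]


@dataclass(frozen=True)
class RawCds:
    """An unvalidated CDS candidate as read from a file."""

    gene_id: str
    sequence: str
    source_record: str = ""


@dataclass(frozen=True)
class CodingSequence:
    """One validated CDS.

    ``sequence`` is the full nucleotide string including the terminal stop;
    ``codons`` holds the sense codons only (terminal stop stripped), which
    is what every downstream statistic counts.
    """

    gene_id: str
    sequence: str
    codons: tuple[str, ...]
    source_record: str = ""

    def __len__(self) -> int:
        return len(self.codons)


@dataclass
class FilterRecord:
    gene_id: str
    accepted: bool
    reasons: tuple[str, ...] = ()


@dataclass
class FilterReport:
    """Per-candidate audit trail of the CDS filters."""

    records: list[FilterRecord] = field(default_factory=list)

    @property
    def n_accepted(self) -> int:
        return sum(r.accepted for r in self.records)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "accepted": ["yes" if r.accepted else "no" for r in self.records],
                "reasons": [";".join(r.reasons) for r in self.records],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)


def _feature_gene_id(feature, record, index: int) -> str:
    for key in ("gene", "locus_tag", "protein_id", "product"):
        if key in feature.qualifiers:
            return str(feature.qualifiers[key][0])
    return f"{record.id}_CDS{index}"


def read_cds(path: str | Path, format: str = "fasta") -> list[RawCds]:
    """Read raw CDS candidates from a FASTA or GenBank flat file.

    For GenBank input, CDS features are extracted with join() segments
    concatenated in feature order and minus-strand features
    reverse-complemented (1-based inclusive coordinates, as in the format).
    A CDS feature whose sequence cannot be extracted is skipped with a
    warning.
    """
    path = Path(path)
    if format not in ("fasta", "genbank"):
        raise ValueError(f"unknown format {format!r}; expected 'fasta' or 'genbank'")
    if not path.exists():
        raise FileNotFoundError(path)

    candidates: list[RawCds] = []
    if format == "fasta":
        for rec in SeqIO.parse(str(path), "fasta"):
            if not rec.id:
                raise ValueError(f"{path}: record with empty identifier")
            candidates.append(
                RawCds(gene_id=rec.id, sequence=str(rec.seq).upper(), source_record=path.name)
            )
    else:
        try:
            records = list(SeqIO.parse(str(path), "genbank"))
        except Exception as exc:  # malformed flat file
            raise ValueError(f"{path}: unparseable GenBank file ({exc})") from exc
        for rec in records:
            idx = 0
            for feature in rec.features:
                if feature.type != "CDS":
                    continue
                idx += 1
                gene_id = _feature_gene_id(feature, rec, idx)
                try:
                    seq = str(feature.extract(rec.seq)).upper()
                except Exception as exc:
                    warnings.warn(
                        f"{path}: CDS feature {gene_id} in {rec.id} has no "
                        f"extractable sequence ({exc}); skipped"
                    )
                    continue
                candidates.append(RawCds(gene_id=gene_id, sequence=seq, source_record=rec.id))
    return candidates


def _codonize(sequence: str) -> list[str]:
    return [sequence[i : i + 3] for i in range(0, len(sequence) - len(sequence) % 3, 3)]


def validate_candidate(candidate: RawCds, min_length_bp: int = 300) -> tuple[str, ...]:
    """Return the tuple of filter-failure reasons for one candidate (empty = pass).

    Duplicate detection is a set-level property and lives in
    :func:`filter_cds`; this checks the per-sequence rules only.
    """
    seq = candidate.sequence
    reasons: list[str] = []
    if any(base not in "ACGT" for base in seq):
        reasons.append("ambiguous_base")
    if not seq.startswith(START_CODON):
        reasons.append("bad_start")
    if len(seq) % 3 != 0:
        reasons.append("not_multiple_of_3")
    if len(seq) < 3 or (len(seq) % 3 == 0 and seq[-3:] not in STOP_CODONS):
        reasons.append("bad_stop")
    if len(seq) < min_length_bp:
        reasons.append("too_short")
    if len(seq) % 3 == 0 and len(seq) >= 6:
        if any(c in STOP_CODONS for c in _codonize(seq)[:-1]):
            reasons.append("internal_stop")
    return tuple(reasons)


def filter_cds(
    candidates: Sequence[RawCds],
    min_length_bp: int = 300,
) -> tuple[list[CodingSequence], FilterReport]:
    """Apply the CDS inclusion filters; return kept genes and the audit report.

    Exact duplicate sequences are removed keeping the first occurrence in
    input order; input order of kept genes is preserved. Raises if no gene
    passes (an empty analysis set is always an input problem, never a
    silent result).
    """
    if not candidates:
        raise ValueError("no CDS candidates supplied")

    report = FilterReport()
    kept: list[CodingSequence] = []
    seen: set[str] = set()
    for cand in candidates:
        reasons = list(validate_candidate(cand, min_length_bp=min_length_bp))
        if not reasons and cand.sequence in seen:
            reasons.append("duplicate")
        if reasons:
            report.records.append(
                FilterRecord(gene_id=cand.gene_id, accepted=False, reasons=tuple(reasons))
            )
            continue
        seen.add(cand.sequence)
        codons = tuple(_codonize(cand.sequence)[:-1])  # strip terminal stop
        kept.append(
            CodingSequence(
                gene_id=cand.gene_id,
                sequence=cand.sequence,
                codons=codons,
                source_record=cand.source_record,
            )
        )
        report.records.append(FilterRecord(gene_id=cand.gene_id, accepted=True))

    if not kept:
        raise ValueError(
            "no genes pass the CDS filters "
            f"({len(candidates)} candidates, all rejected)"
        )
    return kept, report


def write_fasta(genes: Iterable[CodingSequence], path: str | Path) -> None:
    """Write validated genes (full sequence, terminal stop included) to FASTA."""
    records = [
        SeqRecord(Seq(g.sequence), id=g.gene_id, description="")
        for g in genes
    ]
    SeqIO.write(records, str(path), "fasta")
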