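"""Standard genetic code and the synonymous-family partition used throughout.

Codon-usage statistics operate on the 59 "synonymous-analysis" codons: the
61 sense codons of the standard code (NCBI translation table 1) minus the
two singleton codons AUG (Met) and UGG (Trp), which carry no synonymous
choice. Families are grouped by degeneracy class: nine 2-fold, one 3-fold
(Ile), five 4-fold (Val, Pro, Thr, Ala, Gly) and three 6-fold (Leu, Ser,
Arg) amino acids. All internal computation uses the DNA alphabet; codons
are transcribed to RNA only at presentation boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

#: the five fourfold-degenerate families used for PR2-plot analysis
FOURFOLD_PR2_AMINO_ACIDS = ("V", "P", "T", "A", "G")

_AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}


def dna_to_rna(codon: str) -> str:
    return codon.replace("T", "U")


def rna_to_dna(codon: str) -> str:
    return codon.replace("U", "T")


def aa_three_letter(aa: str) -> str:
    return _AA3[aa]


@dataclass(frozen=True)
class GeneticCode:
    """Codon -> amino-acid map plus the synonymous family partition.

    Attributes
    ----------
    codon_to_aa : dict
        Map over the 61 sense codons (DNA alphabet, upper case).
    families : dict
        Amino acid (one-letter) -> tuple of synonymous codons, for the 18
        amino acids with two or more codons (AUG/UGG excluded).
    """

    codon_to_aa: dict[str, str]
    families: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        fams: dict[str, list[str]] = {}
        for codon, aa in self.codon_to_aa.items():
            fams.setdefault(aa, []).append(codon)
        object.__setattr__(
            self,
            "families",
            {
                aa: tuple(sorted(codons))
                for aa, codons in fams.items()
                if len(codons) > 1
            },
        )

    @property
    def sense_codons(self) -> tuple[str, ...]:
        return tuple(sorted(self.codon_to_aa))

    @property
    def synonymous_codons(self) -> tuple[str, ...]:
        """The 59 codons belonging to a multi-codon family, sorted."""
        return tuple(sorted(c for fam in self.families.values() for c in fam))

    def degeneracy(self, aa: str) -> int:
        return len(self.families[aa])

    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Degeneracy (2/3/4/6) -> amino acids in that class."""
        out: dict[int, list[str]] = {}
        for aa, fam in self.families.items():
            out.setdefault(len(fam), []).append(aa)
        return {k: tuple(sorted(v)) for k, v in out.items()}

    def family_of(self, codon: str) -> str | None:
        """Amino acid of `codon` if it is a synonymous-analysis codon."""
        aa = self.codon_to_aa.get(codon)
        if aa is None or aa not in self.families:
            return None
        return aa


@lru_cache(maxsize=None)
def standard_code() -> GeneticCode:
    """The standard genetic code (NCBI translation table 1)."""
    table = CodonTable.unambiguous_dna_by_id[1]
    return GeneticCode(codon_to_aa=dict(table.forward_table))
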