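"""RSCU-based comparison of species: 59-codon matrix and hierarchical clustering.

Each species is summarised by the RSCU vector of its pooled codon counts
over the 59 synonymous-analysis codons; species are then clustered
agglomeratively on pairwise squared Euclidean distances (between-groups
average linkage by default). Rows are sorted by species label before
linkage, so the topology is independent of input order.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform
from skbio.tree import TreeNode

from .cds_io import CodingSequence
from .codon_metrics import CodonCounts, count_codons, pool_counts, rscu
from .genetic_code import GeneticCode, dna_to_rna, standard_code

__all__ = ["rscu_matrix", "ClusterResult", "cluster"]

_LINKAGES = ("average", "complete", "single")


def rscu_matrix(
    species_cds: Mapping[str, Sequence[CodingSequence]] | Mapping[str, CodonCounts],
    code: GeneticCode | None = None,
) -> pd.DataFrame:
    """Species-by-codon RSCU matrix (columns: the 59 codons, RNA alphabet).

    Accepts per-species filtered CDS lists or pre-pooled codon counts.
    Raises if any species leaves a synonymous family unused (the resulting
    NaN column would poison the distance computation).
    """
    code = code or standard_code()
    if len(species_cds) < 2:
        raise ValueError("RSCU matrix needs at least 2 species")
    rows = {}
    for species, value in species_cds.items():
        if isinstance(value, CodonCounts):
            pooled = value
        else:
            pooled = pool_counts([count_codons(g) for g in value], scope=species)
        profile = rscu(pooled, code)
        row = {dna_to_rna(c): profile.get(c) for c in code.synonymous_codons}
        empty = sorted(c for c, v in row.items() if np.isnan(v))
        if empty:
            fams = sorted({code.family_of(c.replace("U", "T")) for c in empty})
            raise ValueError(
                f"species {species!r} has empty synonymous families {fams}; "
                "RSCU undefined for their codons"
            )
        rows[species] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index")
    return matrix.reindex(sorted(matrix.columns), axis=1)


@dataclass
class ClusterResult:
    """Agglomerative clustering of species RSCU profiles.

    `linkage_matrix` is in scipy format over `labels` (sorted species
    names); `merge heights` are carried into newick branch lengths.
    """

    labels: tuple[str, ...]
    linkage_matrix: np.ndarray
    method: str
    distances: pd.DataFrame  # square, squared-Euclidean

    def tree(self) -> TreeNode:
        return TreeNode.from_linkage_matrix(self.linkage_matrix, list(self.labels))

    def to_newick(self) -> str:
        buf = io.StringIO()
        self.tree().write(buf, format="newick")
        return buf.getvalue().strip()

    def cophenetic(self) -> pd.DataFrame:
        d = hierarchy.cophenet(self.linkage_matrix)
        return pd.DataFrame(
            squareform(d), index=list(self.labels), columns=list(self.labels)
        )

    def top_split(self) -> tuple[frozenset[str], frozenset[str]]:
        """Leaf labels of the two subtrees below the root merge."""
        n = len(self.labels)
        members: dict[int, frozenset[str]] = {
            i: frozenset([lab]) for i, lab in enumerate(self.labels)
        }
        for step, (a, b, _h, _n) in enumerate(self.linkage_matrix):
            members[n + step] = members[int(a)] | members[int(b)]
        a, b = int(self.linkage_matrix[-1, 0]), int(self.linkage_matrix[-1, 1])
        return members[a], members[b]


def cluster(matrix: pd.DataFrame, linkage: str = "average") -> ClusterResult:
    """Hierarchical clustering of the RSCU matrix on squared Euclidean
    distances with the given linkage (average/complete/single)."""
    if linkage not in _LINKAGES:
        raise ValueError(f"linkage must be one of {_LINKAGES}, got {linkage!r}")
    if len(matrix) < 2:
        raise ValueError("clustering needs at least 2 species")
    if matrix.isna().any().any():
        bad = sorted(matrix.index[matrix.isna().any(axis=1)])
        raise ValueError(f"RSCU matrix contains NaN entries for species {bad}")
    ordered = matrix.sort_index()
    condensed = pdist(ordered.to_numpy(dtype=float), metric="sqeuclidean")
    z = hierarchy.linkage(condensed, method=linkage)
    return ClusterResult(
        labels=tuple(ordered.index),
        linkage_matrix=z,
        method=linkage,
        distances=pd.DataFrame(
            squareform(condensed), index=list(ordered.index), columns=list(ordered.index)
        ),
    )
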