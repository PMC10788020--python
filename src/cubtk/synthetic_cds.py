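"""Synthetic CDS generator with known, controllable codon-usage structure.

Genes are built as a forced ATG start, a run of sense codons drawn i.i.d.
from a regime-specific per-family distribution (after an amino-acid
sequence drawn uniformly over the 20 amino acids), and a single terminal
stop codon — so every generated gene passes the CDS filters by
construction and its true codon-usage regime is recorded alongside.

Bias modes
----------
uniform
    every synonymous codon equiprobable within its family (ENC -> 61).
single_codon
    one codon per family (ENC = 20 in the long-gene limit).
dirichlet
    per-family codon probabilities drawn once per regime from a symmetric
    Dirichlet; smaller concentration = stronger skew.
gc3_target
    probability mass `gc3_level` on G/C-ending synonyms within each family
    (silent-site composition dial; first/second positions untouched).
mutation_equilibrium
    codons drawn jointly over the 61 sense codons with probability
    proportional to the product of per-position base probabilities at GC
    level `gc3_level` — the neutral regime in which GC12 tracks GC3.
custom_weights
    caller-supplied per-family weights.

The default gene-length range (101-673 codons) matches the span observed
in plant mitochondrial protein-coding gene sets.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cds_io import CodingSequence
from .genetic_code import GeneticCode, standard_code

__all__ = ["SyntheticSpec", "TruthRecord", "gc3_dial", "mutation_equilibrium", "generate_geneset", "default_preferred_set"]

_STOPS = ("TAA", "TAG", "TGA")
BIAS_MODES = (
    "uniform",
    "single_codon",
    "dirichlet",
    "gc3_target",
    "mutation_equilibrium",
    "custom_weights",
)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic gene set; the seed fully determines output."""

    n_genes: int = 28
    length_range: tuple[int, int] = (101, 673)
    lengths: tuple[int, ...] | None = None
    bias_mode: str = "uniform"
    concentration: float = 1.0
    gc3_level: float | tuple[float, float] = 0.5
    high_bias_fraction: float = 0.0
    preferred_set: frozenset[str] | None = None
    preferred_weight: float = 0.8
    custom_weights: Mapping[str, Mapping[str, float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.bias_mode not in BIAS_MODES:
            raise ValueError(f"bias_mode must be one of {BIAS_MODES}")
        lengths = self.lengths or self.length_range
        if min(lengths) < 2:
            raise ValueError("gene lengths must be >= 2 codons")
        levels = (
            self.gc3_level if isinstance(self.gc3_level, tuple) else (self.gc3_level,)
        )
        if any(not 0.0 <= g <= 1.0 for g in levels):
            raise ValueError("gc3_level must lie in [0, 1]")
        if not 0.0 <= self.high_bias_fraction <= 1.0:
            raise ValueError("high_bias_fraction must lie in [0, 1]")
        if not 0.0 < self.preferred_weight < 1.0:
            raise ValueError("preferred_weight must lie in (0, 1)")


@dataclass
class TruthRecord:
    """Ground truth of a generated set: regimes, probability tables, seed."""

    seed: int
    regimes: tuple[str, ...]  # per-gene: "base" or "biased"
    tables: dict[str, dict[str, dict[str, float]]]  # regime -> aa -> codon -> p
    gc3_levels: tuple[float, ...]  # per-gene dial level (NaN when unused)
    realized_gc3: tuple[float, ...]
    preferred_set: tuple[str, ...] = ()

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "regimes": list(self.regimes),
            "tables": self.tables,
            "gc3_levels": list(self.gc3_levels),
            "realized_gc3": list(self.realized_gc3),
            "preferred_set": list(self.preferred_set),
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def gc3_dial(level: float, code: GeneticCode | None = None) -> dict[str, dict[str, float]]:
    """Per-family codon probabilities placing mass `level` on G/C-ending
    synonyms (uniform within each side); one-sided families stay uniform."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("gc3 level must lie in [0, 1]")
    code = code or standard_code()
    table: dict[str, dict[str, float]] = {}
    for aa, family in code.families.items():
        gc_side = [c for c in family if c[2] in "GC"]
        at_side = [c for c in family if c[2] in "AT"]
        if not gc_side or not at_side:
            table[aa] = {c: 1.0 / len(family) for c in family}
            continue
        table[aa] = {c: level / len(gc_side) for c in gc_side}
        table[aa].update({c: (1.0 - level) / len(at_side) for c in at_side})
    return table


def mutation_equilibrium(
    level: float, code: GeneticCode | None = None
) -> dict[str, float]:
    """Joint distribution over the 61 sense codons at nucleotide GC level
    `level`: p(codon) proportional to the product of per-position base
    probabilities (G and C each level/2, A and T each (1-level)/2)."""
    if not 0.0 <= level <= 1.0:
        raise ValueError("GC level must lie in [0, 1]")
    code = code or standard_code()
    base_p = {"G": level / 2, "C": level / 2, "A": (1 - level) / 2, "T": (1 - level) / 2}
    raw = {c: base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in code.sense_codons}
    total = sum(raw.values())
    if total == 0:  # level exactly 0 or 1 leaves some sense codons reachable anyway
        raise ValueError(f"degenerate mutation-equilibrium distribution at level {level}")
    return {c: p / total for c, p in raw.items()}


def default_preferred_set(code: GeneticCode | None = None) -> frozenset[str]:
    """One preferred codon per family: the alphabetically first T-ending
    synonym, falling back to A-ending (mimics organellar A/T preference)."""
    code = code or standard_code()
    chosen = []
    for aa, family in code.families.items():
        for suffix in ("T", "A"):
            side = [c for c in family if c[2] == suffix]
            if side:
                chosen.append(min(side))
                break
        else:  # every standard family has an A- or T-ending member
            chosen.append(min(family))
    return frozenset(chosen)


def _preferred_table(
    preferred: frozenset[str], weight: float, code: GeneticCode
) -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {}
    for aa, family in code.families.items():
        pref = [c for c in family if c in preferred]
        rest = [c for c in family if c not in preferred]
        if not pref or not rest:
            table[aa] = {c: 1.0 / len(family) for c in family}
            continue
        table[aa] = {c: weight / len(pref) for c in pref}
        table[aa].update({c: (1.0 - weight) / len(rest) for c in rest})
    return table


def _normalised_custom(
    weights: Mapping[str, Mapping[str, float]], code: GeneticCode
) -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {}
    for aa, family in code.families.items():
        w = {c: float(weights.get(aa, {}).get(c, 0.0)) for c in family}
        total = sum(w.values())
        if total <= 0:
            table[aa] = {c: 1.0 / len(family) for c in family}
        else:
            table[aa] = {c: v / total for c, v in w.items()}
    return table


def _regime_table(
    spec: SyntheticSpec, level: float, rng: np.random.Generator, code: GeneticCode
) -> dict[str, dict[str, float]]:
    mode = spec.bias_mode
    if mode == "uniform":
        return {aa: {c: 1.0 / len(f) for c in f} for aa, f in code.families.items()}
    if mode == "single_codon":
        return {
            aa: {c: (1.0 if c == min(f) else 0.0) for c in f}
            for aa, f in code.families.items()
        }
    if mode == "dirichlet":
        table = {}
        for aa, family in code.families.items():
            probs = rng.dirichlet([spec.concentration] * len(family))
            table[aa] = dict(zip(family, probs.tolist()))
        return table
    if mode == "gc3_target":
        return gc3_dial(level, code)
    if mode == "custom_weights":
        if spec.custom_weights is None:
            raise ValueError("bias_mode 'custom_weights' requires custom_weights")
        return _normalised_custom(spec.custom_weights, code)
    raise AssertionError(mode)


def _draw_codons_by_family(
    n: int,
    table: Mapping[str, Mapping[str, float]],
    rng: np.random.Generator,
    code: GeneticCode,
) -> list[str]:
    """Draw amino acids uniformly over the 20, then a codon per residue."""
    aa20 = sorted(set(code.codon_to_aa.values()))
    aas = rng.choice(aa20, size=n)
    codons = np.empty(n, dtype=object)
    for aa in np.unique(aas):
        idx = np.flatnonzero(aas == aa)
        if aa == "M":
            codons[idx] = "ATG"
        elif aa == "W":
            codons[idx] = "TGG"
        else:
            family = list(table[aa])
            probs = np.array([table[aa][c] for c in family])
            codons[idx] = rng.choice(family, size=len(idx), p=probs)
    return codons.tolist()


def generate_geneset(
    spec: SyntheticSpec, code: GeneticCode | None = None
) -> tuple[list[CodingSequence], TruthRecord]:
    """Generate a validated CDS set plus its ground-truth record."""
    code = code or standard_code()
    rng = np.random.default_rng(spec.seed)

    if spec.lengths is not None:
        if len(spec.lengths) != spec.n_genes:
            raise ValueError("lengths must list one codon count per gene")
        lengths = np.asarray(spec.lengths)
    else:
        lo, hi = spec.length_range
        lengths = rng.integers(lo, hi + 1, size=spec.n_genes)

    n_biased = int(round(spec.high_bias_fraction * spec.n_genes))
    regimes = tuple(
        "biased" if i < n_biased else "base" for i in range(spec.n_genes)
    )
    preferred = spec.preferred_set
    if n_biased and preferred is None:
        preferred = default_preferred_set(code)

    per_gene_level = isinstance(spec.gc3_level, tuple)
    fixed_level = spec.gc3_level if not per_gene_level else None

    base_table = None
    if not per_gene_level and spec.bias_mode != "mutation_equilibrium":
        base_table = _regime_table(spec, fixed_level, rng, code)
    biased_table = (
        _preferred_table(preferred, spec.preferred_weight, code) if n_biased else None
    )

    tables: dict[str, dict[str, dict[str, float]]] = {}
    if base_table is not None:
        tables["base"] = base_table
    elif spec.bias_mode == "mutation_equilibrium" and not per_gene_level:
        # family-conditional probabilities implied by the joint codon draw
        joint = mutation_equilibrium(float(fixed_level), code)
        tables["base"] = {
            aa: {c: joint[c] / sum(joint[x] for x in fam) for c in fam}
            for aa, fam in code.families.items()
        }
    if biased_table is not None:
        tables["biased"] = biased_table

    genes: list[CodingSequence] = []
    levels: list[float] = []
    realized: list[float] = []
    for i in range(spec.n_genes):
        length = int(lengths[i])
        if per_gene_level:
            level = float(rng.uniform(*spec.gc3_level))
        else:
            level = float(fixed_level) if fixed_level is not None else float("nan")
        levels.append(level)

        if regimes[i] == "biased":
            body = _draw_codons_by_family(length - 1, biased_table, rng, code)
        elif spec.bias_mode == "mutation_equilibrium":
            dist = mutation_equilibrium(level, code)
            sense = sorted(dist)
            probs = np.array([dist[c] for c in sense])
            body = rng.choice(sense, size=length - 1, p=probs).tolist()
        else:
            table = base_table
            if table is None:  # per-gene gc3_target level
                table = _regime_table(spec, level, rng, code)
            body = _draw_codons_by_family(length - 1, table, rng, code)

        codons = ["ATG", *body]
        stop = str(rng.choice(_STOPS))
        sequence = "".join(codons) + stop
        realized.append(sum(c[2] in "GC" for c in codons) / len(codons))
        genes.append(
            CodingSequence(
                gene_id=f"synth_{i + 1:03d}",
                sequence=sequence,
                codons=tuple(codons),
                source_record="synthetic",
            )
        )

    truth = TruthRecord(
        seed=spec.seed,
        regimes=regimes,
        tables=tables,
        gc3_levels=tuple(levels),
        realized_gc3=tuple(realized),
        preferred_set=tuple(sorted(preferred)) if preferred else (),
    )
    return genes, truth
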