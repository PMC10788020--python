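"""Codon-composition indices against hand counts and brute-force oracles."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cubtk.codon_metrics import (
    CodonCounts,
    cai,
    cbi,
    count_codons,
    enc,
    fop,
    pool_counts,
    positional_gc,
    reference_weights,
    rscu,
    silent_site_composition,
)

from conftest import counts_from_usage, make_gene


def test_count_codons_direct():
    gene = make_gene("g", ["GCT", "GCT"])
    counts = count_codons(gene)
    assert counts.counts == {"ATG": 1, "GCT": 2}
    assert counts.total == len(gene.codons) == 3


def test_positional_gc_hand_counts():
    assert positional_gc(CodonCounts({"GCG": 7})) == (100.0, 100.0, 100.0, 100.0)
    # ATG GCT GCT: positions 1 (A,G,G), 2 (T,C,C), 3 (G,T,T) by hand
    gc1, gc2, gc3, gcall = positional_gc(CodonCounts({"ATG": 1, "GCT": 2}))
    assert gc1 == pytest.approx(200 / 3)
    assert gc2 == pytest.approx(200 / 3)
    assert gc3 == pytest.approx(100 / 3)
    assert gcall == pytest.approx(500 / 9)  # 55.56
    with pytest.raises(ValueError):
        positional_gc(CodonCounts({}))


def test_silent_sites_phe_only(code):
    counts = counts_from_usage(code, {"F": [10, 10]})  # TTC, TTT equally
    a3s, t3s, c3s, g3s, gc3s = silent_site_composition(counts, code)
    assert (t3s, c3s, gc3s) == (50.0, 50.0, 50.0)
    assert math.isnan(a3s) and math.isnan(g3s)  # no A/G-ending synonym available


def test_silent_sites_uniform_59(code):
    counts = CodonCounts({c: 5 for c in code.synonymous_codons})
    *_, gc3s = silent_site_composition(counts, code)
    # 29 of the 59 synonymous codons end G or C (enumeration)
    assert gc3s == pytest.approx(100 * 29 / 59)


def test_silent_sites_exclude_atg_tgg(code):
    counts = CodonCounts({"ATG": 50, "TGG": 50, "TTT": 4, "TTC": 4})
    a3s, t3s, c3s, g3s, gc3s = silent_site_composition(counts, code)
    assert (t3s, c3s, gc3s) == (50.0, 50.0, 50.0)


def test_rscu_balanced_and_extreme(code):
    balanced = rscu(counts_from_usage(code, {"F": [10, 10]}), code)
    assert balanced.get("TTC") == balanced.get("TTT") == 1.0
    skewed = rscu(counts_from_usage(code, {"F": [20, 0]}), code)
    assert skewed.get("TTC") == 2.0 and skewed.get("TTT") == 0.0
    # unused family reported NA, not zero
    assert math.isnan(skewed.get("GCT"))
    assert skewed.get("ATG") == 1.0


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=50), min_size=59, max_size=59))
def test_rscu_family_sums_equal_degeneracy(xs):
    from cubtk.genetic_code import standard_code

    code = standard_code()
    counts = CodonCounts(dict(zip(code.synonymous_codons, xs)))
    profile = rscu(counts, code)
    for aa, family in code.families.items():
        values = [profile.get(c) for c in family]
        if any(math.isnan(v) for v in values):
            assert all(math.isnan(v) for v in values)
        else:
            assert sum(values) == pytest.approx(len(family))
            assert all(v >= 0 for v in values)


def _brute_force_enc(code, counts):
    """Independent exact-arithmetic evaluation of Wright's estimator."""
    class_f = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.families.items():
        xs = [counts.get(c) for c in family]
        n = sum(xs)
        if n < 2:
            continue
        f_hat = (Fraction(n) * sum(Fraction(x, n) ** 2 for x in xs) - 1) / (n - 1)
        if f_hat > 0:
            class_f[len(family)].append(f_hat)
    means = {k: sum(v) / len(v) for k, v in class_f.items() if v}
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2
    value = 2 + 9 / means[2] + 1 / means[3] + 5 / means[4] + 3 / means[6]
    return min(float(value), 61.0)


def test_enc_lower_bound_single_codon(code):
    usage = {aa: [0] * len(fam) for aa, fam in code.families.items()}
    for aa in usage:
        usage[aa][0] = 10
    assert enc(counts_from_usage(code, usage), code) == pytest.approx(20.0)


def test_enc_matches_brute_force_oracle(code):
    usage = {}
    for aa, fam in code.families.items():
        if len(fam) == 2:
            usage[aa] = [3, 1]
        elif len(fam) == 3:
            usage[aa] = [2, 1, 1]
        elif len(fam) == 4:
            usage[aa] = [2, 1, 1, 1]  # perturbed: uniform usage has F-hat = 0
        else:
            usage[aa] = [2, 1, 1, 1, 1, 1]
    counts = counts_from_usage(code, usage)
    assert enc(counts, code) == pytest.approx(_brute_force_enc(code, counts), abs=1e-9)


def test_enc_uniform_small_families_undefined(code):
    # fully uniform 4-fold/6-fold usage at minimal counts gives F-hat = 0
    # in every family of those classes; the estimator is then undefined
    usage = {aa: [1] * len(fam) for aa, fam in code.families.items()}
    for aa, fam in code.families.items():
        if len(fam) == 2:
            usage[aa] = [3, 1]
    with pytest.warns(UserWarning, match="ENC undefined"):
        assert math.isnan(enc(counts_from_usage(code, usage), code))


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=2**31 - 1))
def test_enc_within_bounds_on_random_genes(seed):
    from cubtk.synthetic_cds import SyntheticSpec, generate_geneset

    genes, _ = generate_geneset(
        SyntheticSpec(n_genes=1, length_range=(150, 400), bias_mode="dirichlet",
                      concentration=0.5, seed=seed)
    )
    value = enc(count_codons(genes[0]))
    assert math.isnan(value) or 20.0 <= value <= 61.0


def test_reference_weights_rules(code):
    w = reference_weights(counts_from_usage(code, {"F": [30, 10]}), code)
    assert w["TTC"] == 1.0 and w["TTT"] == pytest.approx(1 / 3)
    w = reference_weights(counts_from_usage(code, {"F": [8, 0]}), code)
    assert w["TTT"] == pytest.approx(0.5 / 8)  # zero replaced by 0.5
    balanced = reference_weights(CodonCounts({c: 4 for c in code.synonymous_codons}), code)
    assert all(v == 1.0 for v in balanced.values())
    with pytest.raises(ValueError):
        reference_weights([], code)


def test_cai_examples_and_invariance(code):
    w = reference_weights(counts_from_usage(code, {"F": [30, 10], "K": [20, 5]}), code)
    best = counts_from_usage(code, {"F": [10, 0], "K": [8, 0]})
    assert cai(best, w, code) == pytest.approx(1.0)
    two = CodonCounts({"TTC": 1, "TTT": 1})
    w2 = {"TTC": 1.0, "TTT": 0.25}
    assert cai(two, w2, code) == pytest.approx(0.5)  # sqrt(1 * 0.25)
    doubled = CodonCounts({"TTC": 2, "TTT": 2})
    assert cai(doubled, w2, code) == pytest.approx(cai(two, w2, code))


def test_fop_cbi_limits(code):
    optimal = {"TTC", "AAA", "GCT"}
    pure = counts_from_usage(code, {"F": [5, 0], "K": [3, 0], "A": [0, 0, 0, 4]})
    assert fop(pure, optimal, code) == 1.0
    assert cbi(pure, optimal, code) == pytest.approx(1.0)
    uniform = counts_from_usage(
        code, {"F": [6, 6], "K": [6, 6], "A": [6, 6, 6, 6]}
    )
    assert cbi(uniform, optimal, code) == pytest.approx(0.0)
    with pytest.raises(ValueError):
        fop(uniform, set(), code)
    with pytest.raises(ValueError):
        fop(uniform, {"ATG"}, code)


def test_cbi_against_brute_force_nrand(code):
    optimal = {"TTT", "GCT", "GCA", "CTT"}
    usage = {"F": [2, 7], "A": [1, 0, 3, 9], "L": [1, 2, 3, 4, 5, 6]}
    counts = counts_from_usage(code, usage)
    # enumerate N_rand family by family with exact fractions
    n_rand = Fraction(0)
    n_syn = n_opt = 0
    for aa, xs in usage.items():
        fam = code.families[aa]
        k_opt = sum(c in optimal for c in fam)
        n_fam = sum(xs)
        n_syn += n_fam
        n_rand += Fraction(n_fam * k_opt, len(fam))
        n_opt += sum(x for c, x in zip(fam, xs) if c in optimal)
    expected = (n_opt - n_rand) / (n_syn - n_rand)
    assert cbi(counts, optimal, code) == pytest.approx(float(expected), abs=1e-12)


def test_pooled_equals_concatenated(code):
    g1 = make_gene("a", ["GCT", "TTT", "AAA", "CTT", "ATT"] * 40)
    g2 = make_gene("b", ["GCC", "TTC", "AAG", "CTA", "ATC"] * 35)
    pooled = pool_counts([count_codons(g1), count_codons(g2)])
    concat = make_gene("ab", list(g1.codons[1:]) + ["ATG"] + list(g2.codons[1:]))
    merged = count_codons(concat)
    assert pooled.counts == merged.counts
    assert positional_gc(pooled) == positional_gc(merged)
    assert enc(pooled, code) == enc(merged, code)


def test_gcall_is_mean_of_positions():
    rng = np.random.default_rng(11)
    from cubtk.synthetic_cds import SyntheticSpec, generate_geneset
    from cubtk.codon_metrics import compute_composition_metrics

    genes, _ = generate_geneset(SyntheticSpec(n_genes=5, seed=int(rng.integers(1000))))
    for g in genes:
        m = compute_composition_metrics(g)
        assert m.gcall == pytest.approx((m.gc1 + m.gc2 + m.gc3) / 3, abs=0.01)
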