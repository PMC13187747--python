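"""RSCU, ENC, positional GC, skews, CAI — examples, properties and oracles.

The brute-force oracles here recompute each statistic directly from raw
triplet lists with independent code (plain Python loops over family members),
never through the implementation under test.
"""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mitocodon.codon_metrics import (
    CodonCountTable,
    compute_cai,
    compute_enc,
    compute_rscu,
    compute_skews,
    count_codons,
    merge_counts,
    positional_gc,
    reference_weights,
)
from mitocodon.sequence_io import CodingSequence, reverse_complement

from conftest import make_cds


# ---------------------------------------------------------------------- oracles

def brute_force_rscu(codon_list, code):
    """RSCU from a raw triplet list: count family totals by looping."""
    out = {}
    for aa, fam in code.families.items():
        tot = sum(1 for c in codon_list if c in fam)
        if tot == 0:
            continue
        for c in fam:
            out[c] = sum(1 for x in codon_list if x == c) * len(fam) / tot
    return out


def brute_force_enc(codon_list, code):
    """Wright's ENC recomputed from scratch (full class counts, CodonW-style)."""
    class_count = Counter(len(f) for f in code.families.values())
    fbar = {}
    for k in sorted(class_count):
        if k < 2:
            continue
        fs = []
        for fam in code.families.values():
            if len(fam) != k:
                continue
            n = sum(1 for c in codon_list if c in fam)
            if n < 2:
                continue
            s = sum((sum(1 for c in codon_list if c == cod) / n) ** 2 for cod in fam)
            f = (n * s - 1) / (n - 1)
            fs.append(f if f > 0 else 1 / k)
        if fs:
            fbar[k] = sum(fs) / len(fs)
    degeneracies = sorted(k for k in class_count if k >= 2)
    enc = class_count.get(1, 0)
    for i, k in enumerate(degeneracies):
        f = fbar.get(k)
        if f is None:
            lo = fbar.get(degeneracies[i - 1]) if i > 0 else None
            hi = fbar.get(degeneracies[i + 1]) if i + 1 < len(degeneracies) else None
            if lo is None or hi is None:
                continue
            f = (lo + hi) / 2
        enc += class_count[k] / f
    return min(enc, len([c for f in code.families.values() for c in f]))


# ---------------------------------------------------------------------- counts

class TestCounts:
    def test_simple_triplets(self, code1):
        t = count_codons(make_cds("ATGAAATTT", code=code1))
        assert t.counts == {"ATG": 1, "AAA": 1, "TTT": 1}
        assert t.total_codons == 3

    def test_ambiguous_codon_excluded(self, code1):
        t = count_codons(make_cds("AANAAA", code=code1))
        assert t.counts == {"AAA": 1} and t.ambiguous == 1

    def test_stops_tracked_separately(self, code1):
        t = count_codons(make_cds("ATGTAA", code=code1))
        assert t.counts == {"ATG": 1} and t.stop_counts == {"TAA": 1}
        assert t.total_codons == 1

    def test_non_multiple_of_three_raises(self, code1):
        with pytest.raises(ValueError):
            count_codons(make_cds("ATGA", code=code1))

    def test_merge_equals_concatenated_counting(self, code1, random_small_genes):
        parts = [count_codons(g) for g in random_small_genes[:8]]
        merged = merge_counts(parts, "m")
        joint = count_codons(
            make_cds("".join(g.sequence for g in random_small_genes[:8]), code=code1)
        )
        assert merged.counts == joint.counts


# ---------------------------------------------------------------------- RSCU

class TestRSCU:
    def test_equal_use_gives_one(self, code1):
        prof = compute_rscu(CodonCountTable("u", {"GAA": 2, "GAG": 2}, code1))
        assert prof.rscu["GAA"] == prof.rscu["GAG"] == 1.0

    def test_three_to_one_family(self, code1):
        prof = compute_rscu(CodonCountTable("u", {"GAA": 3, "GAG": 1}, code1))
        assert prof.rscu["GAA"] == 1.5 and prof.rscu["GAG"] == 0.5
        assert prof.strongly_preferred() == ["GAA"]

    def test_exclusive_codon_attains_family_size(self, code1):
        prof = compute_rscu(CodonCountTable("u", {"GCT": 4}, code1))
        assert prof.rscu["GCT"] == 4.0
        assert prof.rscu["GCC"] == prof.rscu["GCA"] == prof.rscu["GCG"] == 0.0

    def test_unobserved_family_missing_not_zero(self, code1):
        prof = compute_rscu(CodonCountTable("u", {"GAA": 1}, code1))
        assert "TGT" not in prof.rscu  # Cys unobserved

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_family_sum_equals_family_size(self, code1, seed):
        rng = np.random.default_rng(seed)
        sense = list(code1.sense_codons)
        counts = {c: int(n) for c, n in
                  zip(sense, rng.poisson(2, len(sense))) if n > 0}
        if not counts:
            return
        prof = compute_rscu(CodonCountTable("u", counts, code1))
        for aa, fam in code1.families.items():
            vals = [prof.rscu[c] for c in fam if c in prof.rscu]
            if vals:
                assert math.isclose(sum(vals), len(fam), rel_tol=1e-12)
                assert all(0 <= v <= len(fam) for v in vals)

    def test_matches_brute_force_on_random_genes(self, code1, random_small_genes):
        for gene in random_small_genes:
            expected = brute_force_rscu(gene.codons, code1)
            got = compute_rscu(count_codons(gene)).rscu
            assert set(got) == set(expected)
            for c in got:
                assert math.isclose(got[c], expected[c], rel_tol=1e-12)


# ---------------------------------------------------------------------- ENC

class TestENC:
    def test_one_codon_per_family_is_20(self, code1):
        seq = "".join(fam[0] * 10 for fam in code1.families.values())
        assert compute_enc(count_codons(make_cds(seq, code=code1))) == 20.0

    def test_equal_usage_capped_at_61(self, code1):
        counts = CodonCountTable("u", {c: 12 for c in code1.sense_codons}, code1)
        res = compute_enc(counts, details=True)
        assert res.value == 61.0 and res.capped

    def test_equal_usage_capped_at_62_under_table5(self, code5):
        counts = CodonCountTable("u", {c: 12 for c in code5.sense_codons}, code5)
        assert compute_enc(counts) == 62.0

    def test_single_two_fold_family_homozygosity(self, code1):
        # counts (3,1): F = (4*0.625-1)/3 = 0.5, i.e. 2 effective codons in family
        res = compute_enc(
            CodonCountTable("u", {"GAA": 3, "GAG": 1}, code1), details=True
        )
        # only the 2-fold class has data; edge classes cannot be imputed
        assert res.low_confidence
        assert res.value == pytest.approx(2 + 9 / 0.5)

    def test_undefined_without_degenerate_family(self, code1):
        with pytest.raises(ValueError):
            compute_enc(CodonCountTable("u", {"ATG": 50}, code1))

    def test_never_exceeds_code_cap(self, code1, random_small_genes):
        for gene in random_small_genes:
            assert compute_enc(count_codons(gene)) <= code1.enc_max + 1e-12

    def test_matches_brute_force_on_random_genes(self, code1, random_small_genes):
        for gene in random_small_genes:
            got = compute_enc(count_codons(gene))
            expected = brute_force_enc(gene.codons, code1)
            assert got == pytest.approx(expected, rel=1e-12)


# ---------------------------------------------------------------------- GC / skews

class TestPositionalGC:
    def test_all_gc(self, code1):
        pos = positional_gc(make_cds("GGGCCC", code=code1))
        assert pos.gc1 == pos.gc2 == pos.gc3 == pos.gc12 == 1.0

    def test_all_at(self, code1):
        pos = positional_gc(make_cds("AAATTT", code=code1))
        assert pos.gc1 == pos.gc2 == pos.gc3 == 0.0

    def test_gc12_is_mean_of_gc1_gc2(self, code1, random_small_genes):
        for gene in random_small_genes[:20]:
            pos = positional_gc(gene)
            assert pos.gc12 == pytest.approx((pos.gc1 + pos.gc2) / 2)

    def test_gc3s_undefined_for_met_trp_only(self, code1):
        pos = positional_gc(make_cds("ATGTGG" * 5, code=code1))
        assert math.isnan(pos.gc3s)
        assert pos.gc3 == 1.0  # both ATG and TGG end in G

    def test_gc3s_counts_only_degenerate_codons(self, code1):
        # ATG (single-family) ends G; AAA (2-fold) ends A
        pos = positional_gc(make_cds("ATGAAA", code=code1))
        assert pos.gc3s == 0.0 and pos.gc3 == 0.5


class TestSkews:
    def test_counts_example(self, code1):
        sk = compute_skews("A" * 30 + "T" * 10 + "G" * 5 + "C" * 5)
        assert sk.at_skew == 0.5 and sk.gc_skew == 0.0

    def test_reverse_complement_negates_both(self, random_small_genes):
        for gene in random_small_genes[:20]:
            fwd = compute_skews(gene.sequence)
            rev = compute_skews(reverse_complement(gene.sequence))
            assert fwd.at_skew == pytest.approx(-rev.at_skew)
            assert fwd.gc_skew == pytest.approx(-rev.gc_skew)

    def test_undefined_skew_is_nan(self):
        sk = compute_skews("GGCC")
        assert math.isnan(sk.at_skew) and sk.gc_skew == 0.0


# ---------------------------------------------------------------------- CAI

class TestCAI:
    def test_weights_ratio_to_max(self, code1):
        w = reference_weights(CodonCountTable("r", {"GAA": 30, "GAG": 10}, code1))
        assert w.weights["GAA"] == 1.0
        assert w.weights["GAG"] == pytest.approx(1 / 3)

    def test_zero_count_pseudocount(self, code1):
        w = reference_weights(CodonCountTable("r", {"GCT": 8}, code1))
        assert w.weights["GCC"] == pytest.approx(0.5 / 8)

    def test_equal_counts_all_one(self, code1):
        w = reference_weights(
            CodonCountTable("r", {"GCT": 5, "GCC": 5, "GCA": 5, "GCG": 5}, code1)
        )
        assert all(w.weights[c] == 1.0 for c in ("GCT", "GCC", "GCA", "GCG"))

    def test_all_optimal_gene_scores_one(self, code1):
        ref = CodonCountTable("r", {"GAA": 30, "GAG": 10, "TTT": 20, "TTC": 5}, code1)
        w = reference_weights(ref)
        gene = CodonCountTable("g", {"GAA": 7, "TTT": 3}, code1)
        assert compute_cai(gene, w) == 1.0

    def test_geometric_mean(self, code1):
        ref = CodonCountTable("r", {"GAA": 4, "GAG": 1}, code1)
        w = reference_weights(ref)
        gene = CodonCountTable("g", {"GAA": 1, "GAG": 1}, code1)
        assert compute_cai(gene, w) == pytest.approx(math.sqrt(0.25))

    def test_scale_invariance(self, code1, random_small_genes):
        ref = merge_counts([count_codons(g) for g in random_small_genes[:30]], "ref")
        w = reference_weights(ref)
        for gene in random_small_genes[:10]:
            ct = count_codons(gene)
            doubled = CodonCountTable("d", {c: 2 * n for c, n in ct.counts.items()}, ct.code)
            assert compute_cai(ct, w) == pytest.approx(compute_cai(doubled, w))

    def test_monotone_in_weight_substitution(self, code1):
        ref = CodonCountTable("r", {"GAA": 10, "GAG": 2}, code1)
        w = reference_weights(ref)
        worse = compute_cai(CodonCountTable("g", {"GAA": 3, "GAG": 2}, code1), w)
        better = compute_cai(CodonCountTable("g", {"GAA": 4, "GAG": 1}, code1), w)
        assert better > worse

    def test_missing_when_no_degenerate_codons(self, code1):
        ref = CodonCountTable("r", {"GAA": 10, "GAG": 2}, code1)
        w = reference_weights(ref)
        assert math.isnan(compute_cai(CodonCountTable("g", {"ATG": 5}, code1), w))

    def test_empty_reference_raises(self, code1):
        with pytest.raises(ValueError):
            reference_weights(CodonCountTable("r", {}, code1))
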