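"""Alignment primitives against brute-force oracles."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from annodiff import align
from annodiff.align import (
    BacktranslateError,
    CodonAlignment,
    ProteinAlignment,
    codon_backtranslate,
    global_align_protein,
    global_align_score,
    kmer_candidates,
    load_matrix,
    mask_low_quality_windows,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_affine_score(a: str, b: str, gap_open=11.0, gap_extend=1.0) -> float:
    """Enumerate every gapped global alignment (affine: a length-L gap costs
    open + (L-1)*extend) and return the maximal score."""
    m = load_matrix("BLOSUM62")
    best = [float("-inf")]

    def rec(i, j, state, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "m", score + m[a[i], b[j]])
        if i < len(a):
            rec(i + 1, j, "ga", score - (gap_extend if state == "ga" else gap_open))
        if j < len(b):
            rec(i, j + 1, "gb", score - (gap_extend if state == "gb" else gap_open))

    rec(0, 0, "m", 0.0)
    return best[0]


class TestGlobalAlign:
    def test_identity_case(self):
        pa = global_align_protein("MKV", "MKV")
        assert pa.identity == 1.0

    def test_two_of_three(self):
        pa = global_align_protein("MKV", "MXV")
        assert pa.identity == pytest.approx(2 / 3)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            global_align_protein("", "MKV")

    @pytest.mark.parametrize(
        "a,b",
        [("MKV", "MV"), ("ACDEFG", "ADG"), ("WWW", "W"), ("MK", "KM"), ("HHHHHH", "HH")],
    )
    def test_score_matches_enumeration(self, a, b):
        assert global_align_score(a, b) == pytest.approx(brute_force_affine_score(a, b))

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        st.text(alphabet=AA, min_size=1, max_size=5),
        st.text(alphabet=AA, min_size=1, max_size=5),
    )
    def test_score_matches_enumeration_property(self, a, b):
        assert global_align_score(a, b) == pytest.approx(brute_force_affine_score(a, b))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        st.text(alphabet=AA, min_size=1, max_size=6),
        st.text(alphabet=AA, min_size=1, max_size=6),
    )
    def test_symmetry(self, a, b):
        pa = global_align_protein(a, b)
        pb = global_align_protein(b, a)
        assert pa.score == pytest.approx(pb.score)
        assert pa.identity == pytest.approx(pb.identity)


class TestKmerCandidates:
    def test_identical_proteomes_self_paired(self):
        prots = {"p1": "MKVILLANDERS", "p2": "WWCHQRSTVNNE"}
        cands = kmer_candidates(prots, prots, k=5, min_shared=2)
        assert {(c.query_id, c.subject_id) for c in cands} >= {("p1", "p1"), ("p2", "p2")}

    def test_disjoint_proteins_no_candidates(self):
        assert kmer_candidates({"a": "MKVMKVMKV"}, {"b": "WCHWCHWCH"}, k=5) == []

    def test_recall_on_diverged_pairs(self):
        # 95%-identity pairs must always survive the prefilter
        import numpy as np

        rng = np.random.default_rng(1)
        qs, ss = {}, {}
        for i in range(30):
            seq = "".join(rng.choice(list(AA), size=120))
            mut = list(seq)
            for pos in rng.choice(120, size=6, replace=False):
                mut[pos] = AA[(AA.index(mut[pos]) + 1) % len(AA)]
            qs[f"q{i}"] = seq
            ss[f"s{i}"] = "".join(mut)
        found = {(c.query_id, c.subject_id) for c in kmer_candidates(qs, ss, k=5, min_shared=2)}
        assert all((f"q{i}", f"s{i}") in found for i in range(30))


class TestBacktranslate:
    def test_identical_cds_gap_free(self):
        pa = ProteinAlignment("MK", "MK", 0)
        ca = codon_backtranslate(pa, "ATGAAA", "ATGAAA")
        assert ca.codons_a == ["ATG", "AAA"] and ca.codons_b == ["ATG", "AAA"]
        assert len(ca.usable_columns()) == 2

    def test_protein_gap_becomes_codon_gap(self):
        pa = ProteinAlignment("MKV", "M-V", 0)
        ca = codon_backtranslate(pa, "ATGAAAGTT", "ATGGTT")
        assert ca.codons_b[1] == align.GAP_CODON
        assert ca.codons_a[1] == "AAA"

    def test_degap_retranslate_roundtrip(self):
        from annodiff.seqio import translate

        a, b = "MKVW", "MW"
        cds_a, cds_b = "ATGAAAGTTTGG", "ATGTGG"
        pa = global_align_protein(a, b)
        ca = codon_backtranslate(pa, cds_a, cds_b)
        re_a = "".join(c for c in ca.codons_a if c != align.GAP_CODON)
        re_b = "".join(c for c in ca.codons_b if c != align.GAP_CODON)
        assert translate(re_a) == a and translate(re_b) == b

    def test_length_mismatch_names_gene(self):
        pa = ProteinAlignment("MK", "MK", 0, id_a="geneX", id_b="geneY")
        with pytest.raises(BacktranslateError, match="geneX"):
            codon_backtranslate(pa, "ATGAAATGA", "ATGAAA")


def _codon_aln(codons_a, codons_b):
    return CodonAlignment(list(codons_a), list(codons_b))


class TestMasking:
    def test_identical_alignment_unmasked(self):
        ca = _codon_aln(["ATG"] * 20, ["ATG"] * 20)
        assert not any(mask_low_quality_windows(ca).mask)

    def test_mismatch_block_masked_exactly(self):
        a = ["GAA"] * 30
        b = ["GAA"] * 30
        for i in range(10, 15):  # 15 bp fully mismatched block
            b[i] = "CTT"
        masked = mask_low_quality_windows(_codon_aln(a, b), window_bp=15, min_identity=0.4)
        assert [i for i, m in enumerate(masked.mask) if m] == [10, 11, 12, 13, 14]

    def test_zero_threshold_masks_nothing(self):
        a = ["GAA"] * 10
        b = ["CTT"] * 10
        assert not any(mask_low_quality_windows(_codon_aln(a, b), min_identity=0.0).mask)

    def test_idempotent(self):
        a = ["GAA"] * 30
        b = ["GAA"] * 15 + ["CTT"] * 15
        once = mask_low_quality_windows(_codon_aln(a, b))
        twice = mask_low_quality_windows(once)
        assert once.mask == twice.mask

    def test_masking_never_increases_usable_columns(self):
        a = ["GAA", "CCC", "TTT"] * 8
        b = ["GAA", "GGG", "TAT"] * 8
        ca = _codon_aln(a, b)
        masked = mask_low_quality_windows(ca)
        assert set(masked.usable_columns()) <= set(ca.usable_columns())
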