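"""NG86 Ka/Ks estimator and the population-genetic formulas."""

import itertools
import math
import warnings

import numpy as np
import pytest

from annodiff import divergence as dv
from annodiff.align import CodonAlignment
from annodiff.divergence import (
    ExcludedCodon,
    KaKsEstimate,
    PopGenParams,
    corrected_divergence,
    divergence_time,
    jukes_cantor,
    kaks,
    ne_ratio,
    ng86_sites,
    path_differences,
    relative_rate,
    summarize_identity,
)

ALL_CODONS = ["".join(c) for c in itertools.product("ACGT", repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in dv.STOP_CODONS]


def _aln(cds_a: str, cds_b: str) -> CodonAlignment:
    return CodonAlignment(
        [cds_a[i : i + 3] for i in range(0, len(cds_a), 3)],
        [cds_b[i : i + 3] for i in range(0, len(cds_b), 3)],
    )


class TestSiteCounts:
    @pytest.mark.parametrize(
        "codon,s",
        [("TTT", 1 / 3), ("GGG", 1.0), ("ATG", 0.0), ("AAA", 1 / 3)],
    )
    def test_hand_enumerated_values(self, codon, s):
        got_s, got_n = ng86_sites(codon)
        assert got_s == pytest.approx(s)
        assert got_n == pytest.approx(3 - s)

    def test_site_conservation_over_all_sense_codons(self):
        for codon in SENSE_CODONS:
            s, n = ng86_sites(codon)
            assert s + n == pytest.approx(3.0)
            assert 0.0 <= s <= 3.0

    @pytest.mark.parametrize("codon", ["TAA", "TGA", "ANA"])
    def test_stop_or_ambiguous_excluded(self, codon):
        with pytest.raises(ExcludedCodon):
            ng86_sites(codon)


class TestPathDifferences:
    def test_single_synonymous_step(self):
        assert path_differences("TTT", "TTC") == (1.0, 0.0)

    def test_stop_routed_path_discarded(self):
        # TAT -> TGG: via TGT is viable (two nonsyn steps); via TAG is a stop
        assert path_differences("TAT", "TGG") == (0.0, 2.0)

    def test_two_step_average_over_orderings(self):
        syn, nsyn = path_differences("TTA", "CTG")  # Leu -> Leu, both orders viable
        assert syn + nsyn == pytest.approx(2.0)
        assert syn == pytest.approx(2.0)  # every step stays Leu


class TestKaKs:
    def test_identical_cds(self):
        est = kaks(_aln("ATGAAACCC", "ATGAAACCC"))
        assert est.Ka == 0.0 and est.Ks == 0.0

    def test_single_synonymous_difference_matches_closed_form(self):
        # one syn diff over S = 5/3 sites per sequence: pS = 3/5
        est = kaks(_aln("TTTGGGAAA", "TTCGGGAAA"))
        assert est.Ka == 0.0
        assert est.S == pytest.approx(5 / 3)
        assert est.Ns == pytest.approx(1.0)
        assert est.Ks == pytest.approx(-0.75 * math.log(1 - (4 / 3) * (3 / 5)))

    def test_saturation_is_undefined_not_zero(self):
        # every 4-fold third position differs: pS = 1 >= 3/4
        est = kaks(_aln("GGTCCTACT", "GGGCCGACG"))
        assert est.Ks is None
        assert "ks_saturated" in est.flags
        assert est.omega is None

    def test_all_columns_masked_is_flagged(self):
        ca = _aln("ATGAAA", "ATGAAA")
        ca.mask = [True, True]
        est = kaks(ca)
        assert est.Ks is None and "no_usable_columns" in est.flags

    def test_symmetry_and_conservation(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            codons_a = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=30)]
            codons_b = [SENSE_CODONS[i] for i in rng.integers(len(SENSE_CODONS), size=30)]
            e1 = kaks(CodonAlignment(codons_a, codons_b))
            e2 = kaks(CodonAlignment(codons_b, codons_a))
            assert e1.Ks == e2.Ks and e1.Ka == e2.Ka
            assert e1.S + e1.N == pytest.approx(3 * e1.n_codons_used)

    def test_all_synonymous_differences_give_zero_ka(self):
        est = kaks(_aln("GGTGGACCTAAAAAA", "GGCGGACCTAAAAAA"))
        assert est.Ka == 0.0 and est.Ks is not None and est.Ks > 0


class TestJukesCantor:
    def test_monotone_on_domain(self):
        grid = np.linspace(0, 0.74, 50)
        vals = [jukes_cantor(p) for p in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_saturation_boundary(self):
        assert jukes_cantor(0.75) is None
        assert jukes_cantor(0.0) == 0.0


class TestPopGenFormulas:
    def test_corrected_divergence_worked_example(self):
        # 0.0512 - 0.0183/2 = 0.04205, printed as 0.0421
        assert corrected_divergence(0.0512, 0.0183) == pytest.approx(0.0421, abs=5e-5)

    def test_corrected_divergence_zero_polymorphism(self):
        assert corrected_divergence(0.03, 0.0) == 0.03

    def test_corrected_divergence_floor_warns(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            assert corrected_divergence(0.01, 0.04) == 0.0
            assert len(w) == 1

    def test_divergence_time_closed_form(self):
        params = PopGenParams(u=5.7e-9, pi_s=0.0183, generations_per_year=5)
        gen, years = divergence_time(0.0512, params)
        assert gen == pytest.approx(0.0512 / (2 * 5.7e-9))
        assert gen == pytest.approx(4.49e6, rel=0.001)
        assert years == pytest.approx(gen / 5)

    def test_divergence_time_scaling(self):
        p1 = PopGenParams(u=5.7e-9, pi_s=0.0183, generations_per_year=5)
        p2 = PopGenParams(u=2 * 5.7e-9, pi_s=0.0183, generations_per_year=5)
        assert divergence_time(0.05, p1)[0] == pytest.approx(2 * divergence_time(0.05, p2)[0])
        assert divergence_time(0.0, p1) == (0.0, 0.0)

    @pytest.mark.parametrize(
        "pi_a,pi_b,expected",
        [(0.001, 0.0183, 0.001 / 0.0183), (0.4, 0.4, 1.0), (0.0, 0.2, 0.0)],
    )
    def test_ne_ratio(self, pi_a, pi_b, expected):
        assert ne_ratio(pi_a, pi_b) == pytest.approx(expected)

    def test_ne_ratio_zero_denominator(self):
        with pytest.raises(ValueError):
            ne_ratio(0.01, 0.0)


def _est(ka, ks):
    return KaKsEstimate(ka, ks, 0, 0, 100, 50, 10)


class TestRelativeRate:
    def test_identical_branches_give_zero_deltas(self):
        rr = relative_rate([("g", _est(0.01, 0.1), _est(0.01, 0.1))] * 5)
        assert rr.mean_delta_ks == 0.0 and rr.mean_delta_ka == 0.0

    def test_antisymmetry_under_genome_swap(self):
        per = [("g1", _est(0.01, 0.10), _est(0.02, 0.13)),
               ("g2", _est(0.02, 0.11), _est(0.01, 0.12))]
        fwd = relative_rate(per)
        rev = relative_rate([(g, b, a) for g, a, b in per])
        assert fwd.mean_delta_ks == pytest.approx(-rev.mean_delta_ks)
        assert fwd.mean_delta_ka == pytest.approx(-rev.mean_delta_ka)

    def test_undefined_estimates_excluded_and_counted(self):
        rr = relative_rate(
            [("g1", _est(0.01, 0.1), _est(0.01, 0.1)),
             ("g2", _est(None, None), _est(0.01, 0.1))]
        )
        assert rr.n_excluded == 1 and len(rr.genes) == 1

    def test_no_usable_genes_is_an_error(self):
        with pytest.raises(ValueError):
            relative_rate([("g", _est(None, None), _est(0.1, 0.1))])


class TestIdentitySummary:
    def _pa(self, ident, n=150):
        from annodiff.align import ProteinAlignment

        k = int(round(ident * n))
        return ProteinAlignment("A" * n, "A" * k + "C" * (n - k), 0)

    def test_all_identical(self):
        s = summarize_identity([self._pa(1.0)] * 4)
        assert s.mean_identity == 1.0 and s.fraction_identical == 1.0

    def test_single_half_identity_pair(self):
        s = summarize_identity([self._pa(0.5)])
        assert s.mean_identity == pytest.approx(0.5)
        assert s.fraction_identical == 0.0

    def test_alignment_length_floor(self):
        with pytest.raises(ValueError):
            summarize_identity([self._pa(1.0, n=50)], min_alignment_bp=300)
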