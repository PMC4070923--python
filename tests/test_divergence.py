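"""Distance estimators: class p-distances, JC correction, ratios, Poisson ASD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitocomp.divergence import (
    SaturationError,
    class_ratios,
    class_substitution_frequency,
    gene_class_profile,
    jukes_cantor,
    overall_asd,
    pairwise_class_p_distance,
    poisson_aa_distance,
)


class TestPairwisePDistance:
    def test_identical(self):
        p, n, d = pairwise_class_p_distance("ACGTACGTAC", "ACGTACGTAC", list(range(10)))
        assert (p, n, d) == (0.0, 10, 0)

    def test_one_difference_in_ten(self):
        a = "AAAAAAAAAA"
        b = "AAAAAAAAAT"
        p, n, d = pairwise_class_p_distance(a, b, list(range(10)))
        assert p == pytest.approx(0.1) and d == 1

    def test_restricted_to_site_set(self):
        a, b = "AAAA", "TTTA"
        p, n, _ = pairwise_class_p_distance(a, b, [3])
        assert p == 0.0 and n == 1

    def test_gap_sites_excluded_pairwise(self):
        p, n, _ = pairwise_class_p_distance("A-GT", "AAGA", [0, 1, 2, 3])
        assert n == 3 and p == pytest.approx(1 / 3)

    def test_empty_site_set_rejected(self):
        with pytest.raises(ValueError, match="empty site set"):
            pairwise_class_p_distance("AA", "AA", [])


class TestJukesCantor:
    def test_closed_form_at_half(self):
        assert jukes_cantor(0.5) == pytest.approx(-0.75 * math.log(1 / 3))

    def test_zero(self):
        assert jukes_cantor(0.0) == 0.0

    def test_saturation(self):
        assert math.isinf(jukes_cantor(0.75))
        assert math.isinf(jukes_cantor(0.9))

    @given(st.floats(min_value=0.001, max_value=0.74))
    @settings(max_examples=60, deadline=None)
    def test_correction_exceeds_p_and_is_monotone(self, p):
        d = jukes_cantor(p)
        assert d >= p
        assert jukes_cantor(p * 0.99) <= d


class TestClassSubstitutionFrequency:
    def test_identical_orthologs_have_zero_frequency(self, code5):
        seqs = {f"s{i}": "GGATTTAAAGGA" for i in range(4)}
        profile = gene_class_profile(seqs, code5)
        for fold in (0, 2, 4):
            assert profile[fold].frequency == 0.0
            assert profile[fold].raw_substitutions == 0

    def test_two_sequences_half_different_at_fourfold_sites(self, code5):
        # 4 Gly codons; third positions differ in 2 of 4 -> p = 0.5 at 4-fold sites
        seqs = {"a": "GGAGGAGGAGGA", "b": "GGTGGTGGAGGA"}
        stats = class_substitution_frequency(seqs, 4, code5)
        assert stats.frequency == pytest.approx(-0.75 * math.log(1 / 3))
        assert stats.raw_substitutions == 2

    def test_saturated_pairs_excluded_with_flag(self, code5):
        # a-b and b-c have p = 1 at the four 4-fold sites; a-c is identical
        seqs = {"a": "GGAGGAGGAGGA", "b": "GGTGGTGGTGGT", "c": "GGAGGAGGAGGA"}
        stats = class_substitution_frequency(seqs, 4, code5)
        assert stats.n_saturated_pairs == 2
        assert stats.frequency == 0.0  # mean over the surviving a-c pair

    def test_all_pairs_saturated_raises(self, code5):
        seqs = {"a": "GGAGGAGGAGGA", "b": "GGTGGTGGTGGT"}
        stats = class_substitution_frequency(seqs, 4, code5)
        with pytest.raises(SaturationError):
            _ = stats.frequency


class TestClassRatios:
    def test_substitutions_only_at_zero_fold(self, code5):
        # ATG->TTG: Met->Leu, a 0-fold first-position change; 2- and 4-fold untouched
        seqs = {"a": "ATGGGATTT", "b": "TTGGGATTT"}
        ratios = class_ratios(gene_class_profile(seqs, code5, assignment="reference"))
        assert ratios.r0f_all == 1.0
        assert ratios.r4f_all == 0.0

    def test_nine_one_zero_counts(self, code5):
        profile = gene_class_profile(
            _orthologs_with_counts(code5, n0=9, n2=1, n4=0), code5, assignment="reference"
        )
        ratios = class_ratios(profile)
        assert ratios.r0f_all == pytest.approx(0.9)
        assert sum(ratios.ratios.values()) == pytest.approx(1.0)

    def test_zero_total_substitutions_rejected(self, code5):
        seqs = {"a": "GGATTT", "b": "GGATTT"}
        with pytest.raises(ZeroDivisionError):
            class_ratios(gene_class_profile(seqs, code5))

    def test_ratios_sum_to_one_on_simulated_data(self, code5):
        from mitocomp.simulate import SimulationConfig, simulate_ortholog_set

        o = simulate_ortholog_set(SimulationConfig(seed=42), "gene1")
        ratios = class_ratios(gene_class_profile(o.sequences, code5, assignment="reference"))
        assert sum(ratios.ratios.values()) == pytest.approx(1.0)


def _orthologs_with_counts(code, n0, n2, n4):
    """Two-species pair with exactly n0/n2/n4 differences per fold class.

    Base gene: ATG (0-fold at pos 1) x 10, AAA (2-fold at pos 3) x 10,
    GGA (4-fold at pos 3) x 10. Differences are introduced at the first
    n0/n2/n4 class sites of the second species.
    """
    a = "ATG" * 10 + "AAA" * 10 + "GGA" * 10
    b = list(a)
    for i in range(n0):
        b[3 * i] = "T"  # ATG -> TTG (Leu), non-synonymous 0-fold change
    for i in range(n2):
        b[30 + 3 * i + 2] = "G"  # AAA -> AAG (Lys), synonymous 2-fold change
    for i in range(n4):
        b[60 + 3 * i + 2] = "T"  # GGA -> GGT (Gly), synonymous 4-fold change
    return {"a": a, "b": "".join(b)}


class TestPoissonDistance:
    def test_identical(self):
        assert poisson_aa_distance("MKLV", "MKLV") == 0.0

    def test_half_different(self):
        assert poisson_aa_distance("MK", "ML") == pytest.approx(math.log(2))
        assert poisson_aa_distance("MKAA", "MLAV") == pytest.approx(math.log(2))

    def test_two_in_ten(self):
        a = "MKLVAGHTWY"
        b = "MKLVAGHTAA"
        assert poisson_aa_distance(a, b) == pytest.approx(-math.log(0.8))

    def test_gaps_excluded_pairwise(self):
        assert poisson_aa_distance("MK-V", "MKLV") == 0.0

    def test_saturation_rejected(self):
        with pytest.raises(SaturationError):
            poisson_aa_distance("MK", "LV")


class TestOverallAsd:
    def test_all_identical(self):
        dm = overall_asd({"a": "MKLV", "b": "MKLV", "c": "MKLV"})
        assert dm.asd == 0.0

    def test_three_species_closed_form(self):
        # 10 residues; pairwise p: ab 0.1, ac 0.1, bc 0.2
        a = "AAAAAAAAAA"
        b = "AAAAAAAAAC"
        c = "AAAAAAAAD" + "A"
        dm = overall_asd({"a": a, "b": b, "c": c})
        expected = np.mean([-math.log(0.9), -math.log(0.9), -math.log(0.8)])
        assert dm.asd == pytest.approx(expected)
        assert dm.asd == pytest.approx(0.1446, abs=2e-4)

    def test_matrix_is_symmetric_with_zero_diagonal(self):
        dm = overall_asd({"a": "MKLV", "b": "MKAV", "c": "MKLL"})
        assert np.allclose(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)
        assert dm.distance("a", "b") == pytest.approx(-math.log(0.75))
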