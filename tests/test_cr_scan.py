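"""Motif scanners: poly(T), [TA(A)]n, G+A blocks, tandem repeats, counterparts, hairpins."""

import numpy as np
import pytest

from mitocomp.cr_scan import (
    counterpart_search,
    find_ga_rich_block,
    find_polyt,
    find_taa_stretch,
    hairpin_scan,
    tandem_repeats,
)
from mitocomp.genome import reverse_complement

from _oracles import brute_counterpart, brute_hairpin, brute_tandem


def random_dna(rng, n, at=0.6):
    p = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


class TestPolyT:
    def test_single_run(self):
        hits = [h for h in find_polyt("AATTTTTTAA", min_run=5) if h.strand == "J"]
        assert [(h.start, h.end, h.score) for h in hits] == [(3, 8, 6)]

    def test_no_run(self):
        assert find_polyt("ACACAC", min_run=5) == []

    def test_n_strand_run_reported_on_j_coordinates(self):
        hits = find_polyt("CCAAAAACC", min_run=5)
        assert [(h.start, h.end, h.strand) for h in hits] == [(3, 7, "N")]

    def test_origin_lifts_to_genome_coordinates(self):
        hits = find_polyt("TTTTT", min_run=5, origin=101)
        assert (hits[0].start, hits[0].end) == (101, 105)

    def test_min_run_validation(self):
        with pytest.raises(ValueError):
            find_polyt("TTTT", min_run=2)


class TestTaaStretch:
    def test_greedy_decomposition(self):
        # downstream of the poly-T: TATATAA = TA + TA + TAA -> 3 units, 7 bases
        hits = find_taa_stretch("TTTTTTCTATATAA", min_run=5)
        assert len(hits) == 1
        assert hits[0].score == 3
        assert (hits[0].start, hits[0].end) == (8, 14)

    def test_absent(self):
        assert find_taa_stretch("TTTTTCCCCCC", min_run=5) == []

    def test_unit_count_invariant_to_trailing_noise(self):
        base = find_taa_stretch("TTTTTTCTATATAA", min_run=5)[0]
        noisy = find_taa_stretch("TTTTTTCTATATAA" + "CCGG", min_run=5)[0]
        assert (base.score, base.start, base.end) == (noisy.score, noisy.start, noisy.end)

    def test_taa_preferred_over_ta(self):
        # TAATA: greedy TAA+TA = 2 units; a TA-first split would strand itself
        hits = find_taa_stretch("TTTTTTCTAATA", min_run=5, min_units=2)
        assert len(hits) == 1
        assert hits[0].score == 2
        assert (hits[0].start, hits[0].end) == (8, 12)


class TestGaRichBlock:
    def test_pure_purine_window(self):
        hits = find_ga_rich_block("GAGAGAGAGA", window=10, min_frac=0.9)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(1.0)

    def test_pyrimidine_sequence_has_no_block(self):
        assert find_ga_rich_block("CTCTCTCTCT", window=10, min_frac=0.9) == []

    def test_hand_tallied_fraction(self):
        # 20 bp with 16 purines (4 pyrimidines evenly spread)
        seq = "GAGAC" * 4
        hits = find_ga_rich_block(seq, window=20, min_frac=0.8)
        assert len(hits) == 1
        assert hits[0].score == pytest.approx(0.8)

    def test_restricted_to_region_upstream_of_polyt(self):
        seq = "GGGGAAAAGG" + "TTTTTT" + "GAGAGAGAGA"
        polyt = find_polyt(seq, min_run=6)
        hits = find_ga_rich_block(seq, polyt_hits=polyt, window=10, min_frac=0.9)
        assert len(hits) == 1
        assert hits[0].end <= 10  # the downstream purine block is out of scope


class TestTandemRepeats:
    def test_dinucleotide_array(self):
        (t,) = tandem_repeats("ATATATAT", min_unit=2)
        assert (t.unit, t.copies, t.start, t.end) == ("AT", 4.0, 1, 8)

    def test_no_repeat(self):
        assert tandem_repeats("GATTACA", min_unit=2, min_copies=2) == []

    def test_published_unit_three_copies(self):
        unit = "CCTTTTAAATTTTCC"
        seq = "GGG" + unit * 3 + "AGA"
        hits = [t for t in tandem_repeats(seq, min_unit=4, min_copies=3) if len(t.unit) == 15]
        assert len(hits) == 1
        t = hits[0]
        assert t.unit == unit and t.copies == pytest.approx(3.0)
        assert (t.start, t.end) == (4, 3 + 45)

    def test_fractional_trailing_copy(self):
        # unit ABCD repeated 2x plus its first base again -> copies 9/4
        (t,) = tandem_repeats("TAGC" * 2 + "T", min_unit=2)
        assert t.copies == pytest.approx(9 / 4)
        assert t.span == round(t.unit_length * t.copies)

    def test_agrees_with_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            seq = random_dna(rng, 200, at=0.7)
            ours = [(t.start - 1, t.end - 1, t.unit) for t in tandem_repeats(seq, min_unit=2)]
            assert sorted(ours) == brute_tandem(seq, 2, None, 2.0)


class TestCounterpartSearch:
    def test_exact_substring_is_perfect_hit(self):
        subject = "GGGGATTACACCCC"
        hits = counterpart_search("GATTACA", subject, min_len=7)
        top = hits[0]
        assert top.percent_identity == 100.0
        assert subject[top.subject_start - 1 : top.subject_end] == "GATTACA"
        assert (top.subject_start, top.subject_end, top.strand) == (4, 10, "J")

    def test_reverse_complement_match_on_n_strand(self):
        hits = counterpart_search("AAAAA", "TTTTT", min_len=5)
        assert any(h.strand == "N" and h.percent_identity == 100.0 for h in hits)

    def test_partial_identity_is_fractional(self):
        # 33-base query vs a 33-base subject with 23 positions identical
        rng = np.random.default_rng(5)
        query = random_dna(rng, 33)
        subject = list(query)
        flip = {"A": "C", "C": "A", "G": "T", "T": "G"}
        for i in rng.choice(33, size=10, replace=False):
            subject[i] = flip[subject[i]]
        hits = counterpart_search(query, "".join(subject), min_len=33, min_identity=0.5)
        assert hits[0].identities == 23
        assert hits[0].percent_identity == pytest.approx(100 * 23 / 33, abs=0.05)
        assert round(hits[0].percent_identity, 1) == 69.7

    def test_min_len_equal_to_query_reduces_to_naive_slider(self):
        rng = np.random.default_rng(3)
        subject = random_dna(rng, 120)
        query = subject[40:55]
        hits = counterpart_search(query, subject, min_len=len(query), min_identity=0.99)
        exact = [h for h in hits if h.percent_identity == 100.0 and h.strand == "J"]
        assert any((h.subject_start, h.subject_end) == (41, 55) for h in exact)

    def test_agrees_with_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(23)
        for _ in range(10):
            subject = random_dna(rng, 200)
            query = random_dna(rng, 15)
            ours = {
                (m.query_start - 1, m.subject_start - 1, m.length, m.identities, m.strand)
                for m in counterpart_search(query, subject, min_len=8, min_identity=0.75)
            }
            assert ours == brute_counterpart(query, subject, 8, 0.75)


class TestHairpinScan:
    def test_simple_stem_loop(self):
        hits = hairpin_scan("GGGAAAACCC", min_stem=3, loop_range=(3, 8))
        assert [(h.start, h.end, h.score) for h in hits] == [(1, 10, 3)]

    def test_homopolymer_has_no_hairpin(self):
        assert hairpin_scan("AAAAAAAAAA", min_stem=3, loop_range=(3, 8)) == []

    def test_gu_wobble_not_counted(self):
        # GTG...CAC pairs perfectly; GTG...TAC would need G.T wobble at one end
        assert hairpin_scan("GTGAAAACAC", min_stem=3, loop_range=(3, 8)) != []
        assert hairpin_scan("GTGAAAATAC", min_stem=3, loop_range=(3, 8)) == []

    def test_count_invariant_under_reverse_complement(self):
        rng = np.random.default_rng(9)
        for _ in range(10):
            seq = random_dna(rng, 80)
            a = hairpin_scan(seq, min_stem=3, loop_range=(3, 8))
            b = hairpin_scan(reverse_complement(seq), min_stem=3, loop_range=(3, 8))
            assert len(a) == len(b)

    def test_agrees_with_brute_force_on_random_sequences(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            seq = random_dna(rng, 200)
            ours = {(h.start - 1, h.end - 1, int(h.score)) for h in
                    hairpin_scan(seq, min_stem=3, loop_range=(3, 8))}
            assert ours == brute_hairpin(seq, 3, (3, 8))


def test_scanner_coordinates_round_trip_through_feature_extraction():
    """Hits on an extracted CR slice, lifted by its origin, land on the genome."""
    from mitocomp.genome import GeneFeature, GenomeRecord, extract_feature_sequence

    genome = GenomeRecord(id="toy", sequence="ACGC" * 10 + "TTTTTTT" + "ACGC" * 10)
    cr = GeneFeature("CR", 31, 57, "J", "CR")
    sub = extract_feature_sequence(genome, cr)
    hits = find_polyt(sub, min_run=7, origin=cr.start)
    (hit,) = [h for h in hits if h.strand == "J"]
    assert genome.sequence[hit.start - 1 : hit.end] == "T" * 7
    assert (hit.start, hit.end) == (41, 47)
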