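"""Six-frame translation and local alignment against an independent oracle."""

import random

import pytest
from Bio.Align import substitution_matrices

from nudipep.io import NucleotideContig, QueryProhormone
from nudipep.homology import (
    HomologyHit,
    ScoringConfig,
    completeness_check,
    extract_candidate_protein,
    local_align,
    reverse_complement,
    six_frame_translate,
    translated_search,
)
from nudipep.synthetic import _codons_by_aa

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def encode(protein: str) -> str:
    """Deterministic reverse translation (first codon per residue)."""
    codons = _codons_by_aa()
    return "".join(codons[aa][0] for aa in protein)


def sw_oracle(query: str, subject: str, open_cost: float = 12.0, extend_cost: float = 1.0) -> float:
    """Plain affine-gap Smith-Waterman DP, written independently of the engine.

    open_cost is charged for the first gapped column of a run, extend_cost for
    each further column; the empty alignment scores 0.
    """
    n, m = len(query), len(subject)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iq = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in subject
    Is = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = float(_BLOSUM62[query[i - 1], subject[j - 1]])
            M[i][j] = sub + max(0.0, M[i - 1][j - 1], Iq[i - 1][j - 1], Is[i - 1][j - 1])
            Iq[i][j] = max(M[i - 1][j] - open_cost, Iq[i - 1][j] - extend_cost)
            Is[i][j] = max(M[i][j - 1] - open_cost, Is[i][j - 1] - extend_cost)
            best = max(best, M[i][j])
    return best


class TestSixFrameTranslate:
    def test_forward_frame_standard_code(self):
        frames = six_frame_translate(NucleotideContig(id="c", sequence="ATGTTTATGCGTTTT"))
        assert frames[1] == "MFMRF"

    def test_stop_codons_rendered_as_asterisk(self):
        assert six_frame_translate(NucleotideContig(id="c", sequence="TAATAA"))[1] == "**"

    def test_reverse_frame_equals_forward_of_revcomp(self):
        seq = "ATGGCGTTTAAACCCGGGT"
        contig = NucleotideContig(id="c", sequence=seq)
        rc = NucleotideContig(id="rc", sequence=reverse_complement(seq))
        frames = six_frame_translate(contig)
        rc_frames = six_frame_translate(rc)
        for k in (1, 2, 3):
            assert frames[-k] == rc_frames[k]

    def test_n_codons_become_x_and_partial_codons_dropped(self):
        frames = six_frame_translate(NucleotideContig(id="c", sequence="ATGANTTTTG"))
        assert frames[1] == "MXF"  # trailing 'G' dropped

    def test_too_short_contig_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate(NucleotideContig(id="c", sequence="AT"))


class TestLocalAlign:
    def test_identical_ten_mers_are_full_identity(self):
        a = local_align("ACDEFGHIKL", "ACDEFGHIKL")
        assert a.percent_identity == 100.0
        assert a.query_span == (1, 10)
        assert a.subject_span == (1, 10)

    def test_embedded_motif_scores_sum_of_diagonal_entries(self):
        a = local_align("FMRF", "AAFMRFAA")
        expected = sum(float(_BLOSUM62[c, c]) for c in "FMRF")
        assert a.score == expected == 22.0
        assert a.subject_span == (3, 6)
        assert a.percent_identity == 100.0

    def test_unknown_residue_is_named(self):
        with pytest.raises(ValueError, match="'J'"):
            local_align("FMJF", "FMRF")

    @pytest.mark.parametrize("n_cases", [200])
    def test_score_equals_brute_force_oracle_on_random_pairs(self, n_cases):
        rng = random.Random(1234)
        for _ in range(n_cases):
            q = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 8)))
            s = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 8)))
            assert local_align(q, s).score == sw_oracle(q, s), (q, s)

    def test_short_subject_matches_exhaustive_optimum(self):
        rng = random.Random(99)
        for _ in range(50):
            q = "".join(rng.choice(AA20) for _ in range(rng.randint(1, 8)))
            s = "".join(rng.choice(AA20) for _ in range(3))
            assert local_align(q, s).score == sw_oracle(q, s)


class TestTranslatedSearch:
    QUERY = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"

    @pytest.mark.parametrize("offset", [0, 1, 2])
    @pytest.mark.parametrize("strand", [1, -1])
    def test_planted_orf_found_in_every_frame(self, offset, strand):
        forward = "T" * offset + encode(self.QUERY)
        seq = reverse_complement(forward) if strand == -1 else forward
        query = QueryProhormone(accession="q", sequence=self.QUERY)
        hits = translated_search(query, [NucleotideContig(id="c", sequence=seq)], min_score=40)
        top = hits[0]
        assert top.percent_identity == 100.0
        assert top.query_span == (1, len(self.QUERY))
        assert (top.frame > 0) == (strand == 1)

    def test_empty_contig_list_yields_no_hits(self):
        query = QueryProhormone(accession="q", sequence=self.QUERY)
        assert translated_search(query, []) == []

    def test_lowering_score_floor_never_removes_hits(self):
        rng = random.Random(7)
        contigs = [
            NucleotideContig(
                id=f"c{i}", sequence="".join(rng.choice("ACGT") for _ in range(240))
            )
            for i in range(4)
        ]
        contigs.append(NucleotideContig(id="planted", sequence=encode(self.QUERY)))
        query = QueryProhormone(accession="q", sequence=self.QUERY)
        strict = translated_search(query, contigs, min_score=60)
        loose = translated_search(query, contigs, min_score=20)
        strict_keys = {(h.contig_id, h.frame) for h in strict}
        loose_keys = {(h.contig_id, h.frame) for h in loose}
        assert strict_keys <= loose_keys
        assert len(loose) >= len(strict)

    def test_hits_sorted_by_descending_score(self):
        rng = random.Random(3)
        contigs = [
            NucleotideContig(id="exact", sequence=encode(self.QUERY)),
            NucleotideContig(
                id="noise", sequence="".join(rng.choice("ACGT") for _ in range(200))
            ),
        ]
        query = QueryProhormone(accession="q", sequence=self.QUERY)
        hits = translated_search(query, contigs, min_score=10)
        assert [h.score for h in hits] == sorted((h.score for h in hits), reverse=True)
        assert hits[0].contig_id == "exact"


class TestExtractCandidate:
    def hit_for(self, contig, frame, span):
        return HomologyHit(
            query_id="q", contig_id=contig.id, frame=frame,
            query_span=(1, span[1] - span[0] + 1), subject_span=span,
            score=50.0, percent_identity=100.0, expect=1e-5,
        )

    def test_stop_bounded_segment_extraction(self):
        contig = NucleotideContig(id="c", sequence=encode("AA*MFMRFG*AA"))
        hit = self.hit_for(contig, 1, (5, 8))  # inside MFMRFG
        assert extract_candidate_protein(hit, contig) == "MFMRFG"

    def test_stop_free_frame_returns_whole_translation(self):
        contig = NucleotideContig(id="c", sequence=encode("MFMRFGAA"))
        hit = self.hit_for(contig, 1, (2, 5))
        assert extract_candidate_protein(hit, contig) == "MFMRFGAA"

    def test_longest_of_overlapping_segments_wins(self):
        # span straddles the stop: two stop-free segments overlap it
        protein = "AAAA*MFMRFGHIKL"
        contig = NucleotideContig(id="c", sequence=encode(protein))
        hit = self.hit_for(contig, 1, (3, 8))
        # enumerate stop-free segments overlapping the span and take the longest
        segments = []
        start = None
        for i, aa in enumerate(protein + "*", start=1):
            if aa == "*":
                if start is not None:
                    segments.append((start, i - 1))
                start = None
            elif start is None:
                start = i
        overlapping = [s for s in segments if s[0] <= 8 and s[1] >= 3]
        expected = max(overlapping, key=lambda s: s[1] - s[0])
        assert extract_candidate_protein(hit, contig) == protein[expected[0] - 1 : expected[1]]
        assert "*" not in extract_candidate_protein(hit, contig)

    def test_span_outside_frame_rejected(self):
        contig = NucleotideContig(id="c", sequence=encode("MFMRF"))
        hit = self.hit_for(contig, 1, (4, 99))
        with pytest.raises(ValueError):
            extract_candidate_protein(hit, contig)


class TestCompleteness:
    @pytest.mark.parametrize(
        "cand_len,query_len,expected",
        [(95, 100, True), (94, 100, False), (100, 100, True)],
    )
    def test_ninety_five_percent_rule_boundary(self, cand_len, query_len, expected):
        query = QueryProhormone(accession="q", sequence="A" * query_len)
        assert completeness_check("A" * cand_len, query) is expected

    def test_threshold_validated(self):
        query = QueryProhormone(accession="q", sequence="AAAA")
        with pytest.raises(ValueError):
            completeness_check("AA", query, threshold=0.0)
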