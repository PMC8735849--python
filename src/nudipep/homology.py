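"""Translated homology search of prohormone queries against transcript contigs.

Each contig is translated in all six reading frames and every frame is
aligned to the protein query with an exhaustive Smith-Waterman local
alignment (BLOSUM62, affine gaps), the engine underlying a TBLASTN-style
search; heuristic seeding is deliberately absent because the inputs are
desk-scale.  An approximate Karlin-Altschul expectation value is attached for
ranking only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .io import NucleotideContig, QueryProhormone

__all__ = [
    "ScoringConfig",
    "HomologyHit",
    "AnnotatedProhormone",
    "AlignmentResult",
    "six_frame_translate",
    "local_align",
    "translated_search",
    "extract_candidate_protein",
    "completeness_check",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]


@lru_cache(maxsize=1)
def _codon_map() -> dict[str, str]:
    table = dict(_STANDARD_TABLE.forward_table)
    for stop in _STANDARD_TABLE.stop_codons:
        table[stop] = "*"
    return table


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def six_frame_translate(contig: NucleotideContig) -> dict[int, str]:
    """Translate a contig in all six frames (standard genetic code).

    Frames +1..+3 read the forward strand at offsets 0..2; -1..-3 read the
    reverse complement likewise.  Stop codons become '*'; any codon touching
    an N becomes 'X'; a trailing partial codon is dropped.
    """
    seq = contig.sequence
    if len(seq) < 3:
        raise ValueError(f"contig {contig.id!r} shorter than one codon ({len(seq)} nt)")
    codons = _codon_map()
    frames: dict[int, str] = {}
    for strand, s in ((1, seq), (-1, reverse_complement(seq))):
        for offset in range(3):
            aa = []
            for i in range(offset, len(s) - 2, 3):
                codon = s[i : i + 3]
                aa.append("X" if "N" in codon else codons[codon])
            frames[strand * (offset + 1)] = "".join(aa)
    return frames


@dataclass(frozen=True)
class ScoringConfig:
    """Alignment scoring: substitution matrix and affine gap penalties.

    Defaults follow TBLASTN (BLOSUM62, gap open 11, extend 1).  'X' is made
    neutral (scores 0 against everything) because it stands for untranslatable
    N-containing codons.  The Karlin-Altschul parameters are the gapped
    BLOSUM62 11/1 values and feed only the approximate expect value.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041


@lru_cache(maxsize=8)
def _load_matrix(name: str):
    matrix = substitution_matrices.load(name)
    if "X" in matrix.alphabet:
        for ch in matrix.alphabet:
            matrix["X", ch] = 0.0
            matrix[ch, "X"] = 0.0
    return matrix


@lru_cache(maxsize=8)
def _make_aligner(config: ScoringConfig) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _load_matrix(config.matrix_name)
    # Biopython charges open_gap_score for the first gapped column and
    # extend_gap_score thereafter; BLAST's open+k*extend maps as below.
    aligner.open_gap_score = -(config.gap_open + config.gap_extend)
    aligner.extend_gap_score = -config.gap_extend
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    score: float
    query_span: tuple[int, int] | None  # 1-based inclusive; None for empty alignment
    subject_span: tuple[int, int] | None
    percent_identity: float
    aligned_query: str = ""
    aligned_subject: str = ""


@dataclass(frozen=True)
class HomologyHit:
    query_id: str
    contig_id: str
    frame: int
    query_span: tuple[int, int]
    subject_span: tuple[int, int]  # residues on the translated frame
    score: float
    percent_identity: float
    expect: float


@dataclass
class AnnotatedProhormone:
    """A candidate precursor extracted from a contig hit."""

    species: str
    name: str
    sequence: str
    complete: bool
    signal_length: int | None = None
    source: HomologyHit | None = None


# Number of co-optimal alignments inspected for the deterministic tie-break.
_TIE_BREAK_LIMIT = 64


def local_align(query: str, subject: str, config: ScoringConfig | None = None) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment of two protein strings.

    Deterministic: among co-optimal alignments the one with the smallest
    query start, then smallest subject start, is returned.  An alignment with
    no positive-scoring pair is reported as score 0 with empty spans.
    """
    if not query or not subject:
        raise ValueError("local_align requires non-empty sequences")
    config = config or ScoringConfig()
    matrix = _load_matrix(config.matrix_name)
    for label, seq in (("query", query), ("subject", subject)):
        for ch in seq:
            if ch not in matrix.alphabet:
                raise ValueError(f"residue {ch!r} in {label} has no substitution-matrix entry")
    aligner = _make_aligner(config)
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return AlignmentResult(0.0, None, None, 0.0)

    def start_key(aln):
        return (aln.aligned[0][0][0], aln.aligned[1][0][0])

    chosen = min(
        itertools.islice(alignments, _TIE_BREAK_LIMIT),
        key=start_key,
    )
    qblocks, sblocks = chosen.aligned
    qspan = (int(qblocks[0][0]) + 1, int(qblocks[-1][1]))
    sspan = (int(sblocks[0][0]) + 1, int(sblocks[-1][1]))
    aq, asub = str(chosen[0]), str(chosen[1])
    columns = len(aq)
    identical = sum(1 for a, b in zip(aq, asub) if a == b and a != "-")
    pid = 100.0 * identical / columns if columns else 0.0
    return AlignmentResult(
        score=float(chosen.score),
        query_span=qspan,
        subject_span=sspan,
        percent_identity=pid,
        aligned_query=aq,
        aligned_subject=asub,
    )


def _expect(score: float, m: int, n: int, config: ScoringConfig) -> float:
    """Karlin-Altschul E = K m n exp(-lambda S); approximate, for ranking."""
    return config.karlin_k * m * n * math.exp(-config.karlin_lambda * score)


def translated_search(
    query: QueryProhormone,
    contigs: list[NucleotideContig],
    config: ScoringConfig | None = None,
    min_score: float = 40.0,
) -> list[HomologyHit]:
    """Align the query to every contig frame; keep hits at or above min_score.

    Hits are sorted by descending score (ties by contig id then frame) so the
    output is deterministic.
    """
    config = config or ScoringConfig()
    if not query.sequence:
        raise ValueError("empty query")
    db_size = 0
    frame_cache: list[tuple[NucleotideContig, dict[int, str]]] = []
    for contig in contigs:
        frames = six_frame_translate(contig)
        db_size += sum(len(f) for f in frames.values())
        frame_cache.append((contig, frames))
    hits: list[HomologyHit] = []
    for contig, frames in frame_cache:
        for frame, translation in frames.items():
            if not translation:
                continue
            aln = local_align(query.sequence, translation, config)
            if aln.score < min_score or aln.query_span is None:
                continue
            hits.append(
                HomologyHit(
                    query_id=query.accession,
                    contig_id=contig.id,
                    frame=frame,
                    query_span=aln.query_span,
                    subject_span=aln.subject_span,
                    score=aln.score,
                    percent_identity=aln.percent_identity,
                    expect=_expect(aln.score, len(query.sequence), max(db_size, 1), config),
                )
            )
    hits.sort(key=lambda h: (-h.score, h.contig_id, h.frame))
    return hits


def extract_candidate_protein(hit: HomologyHit, contig: NucleotideContig) -> str:
    """The longest stop-free translation segment overlapping the hit.

    Within the hit's frame, stop codons partition the translation into
    segments; the longest segment overlapping the subject span (extended to
    the flanking stops or the sequence ends) is returned.  A leading Met is
    not required because transcripts may be 5'-truncated.
    """
    if contig.id != hit.contig_id:
        raise ValueError(f"hit refers to contig {hit.contig_id!r}, got {contig.id!r}")
    translation = six_frame_translate(contig)[hit.frame]
    s, e = hit.subject_span
    if not (1 <= s <= e <= len(translation)):
        raise ValueError(
            f"subject span {hit.subject_span} outside frame {hit.frame} "
            f"translation of length {len(translation)}"
        )
    segments: list[tuple[int, int]] = []  # 1-based inclusive stop-free runs
    start = None
    for i, aa in enumerate(translation + "*", start=1):
        if aa == "*":
            if start is not None:
                segments.append((start, i - 1))
                start = None
        elif start is None:
            start = i
    overlapping = [seg for seg in segments if seg[0] <= e and seg[1] >= s]
    if not overlapping:
        raise ValueError("subject span covers only stop codons")
    a, b = max(overlapping, key=lambda seg: (seg[1] - seg[0], -seg[0]))
    return translation[a - 1 : b]


def completeness_check(candidate: str, query: QueryProhormone, threshold: float = 0.95) -> bool:
    """True iff the candidate reaches the threshold fraction of query length.

    The boundary is inclusive (a 95-residue candidate against a 100-residue
    query passes at the default threshold); a small epsilon guards against
    float representation of the threshold.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    return len(candidate) >= threshold * len(query.sequence) - 1e-9
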