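"""Precursor processing: signal trimming, cleavage prediction, PTM variants.

Prohormone convertases cleave C-terminal to basic sites; the engine here is a
deterministic rule-based model (dibasic KR/RR/KK/RK plus spaced monobasic R)
with a pluggable injection table so site calls from an external predictor can
be supplied verbatim.  Variant enumeration covers the common secretory-pathway
PTMs: C-terminal amidation from a Gly donor, N-terminal pyroglutamation of
Gln/Glu, and optional N-terminal acetylation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .masses import (
    ModificationDelta,
    PredictedPeptide,
    default_registry,
)

__all__ = [
    "CleavageModel",
    "SegmentRecord",
    "predict_signal_peptide",
    "predict_cleavage_sites",
    "segment_records",
    "derive_peptides",
    "process_precursor",
]

BASIC = frozenset("KR")
HYDROPHOBIC = frozenset("AILMFWVC")

# von Heijne-style (-3,-1) cleavage context used by the signal stand-in.
_SIGNAL_MINUS1 = frozenset("AG")
_SIGNAL_MINUS3 = frozenset("AGSCT")
_SIGNAL_SEARCH_WINDOW = 30
_SIGNAL_MIN_CORE = 8
_SIGNAL_CLEAVAGE_REACH = 10


@dataclass(frozen=True)
class CleavageModel:
    """Rule-based stand-in for a trained convertase-site model."""

    dibasic_motifs: frozenset[str] = frozenset({"KR", "RR", "KK", "RK"})
    monobasic_enabled: bool = True
    monobasic_residues: frozenset[str] = frozenset({"R"})
    monobasic_min_spacing: int = 3

    def __post_init__(self) -> None:
        for motif in self.dibasic_motifs:
            if len(motif) != 2 or any(r not in BASIC for r in motif):
                raise ValueError(f"dibasic motif {motif!r} must be a pair over K/R")
        if self.monobasic_min_spacing < 0:
            raise ValueError("monobasic_min_spacing must be >= 0")


def predict_signal_peptide(
    precursor: str,
    external: dict[str, int] | None = None,
    prohormone_id: str | None = None,
) -> int | None:
    """Signal-peptide length, or None if no signal is detected.

    An externally supplied prediction (e.g. from a dedicated predictor) keyed
    by prohormone id takes precedence.  The built-in heuristic looks for a
    hydrophobic core of at least 8 consecutive residues from {A,I,L,M,F,W,V,C}
    within the first 30 positions, then places the cleavage site at the first
    downstream position (within 10 residues of the core end) whose residue is
    small (-1 in {A,G}) with a compatible -3 residue ({A,G,S,C,T}); if no such
    context exists the signal ends with the hydrophobic core.
    """
    if len(precursor) < 20:
        raise ValueError("precursor shorter than 20 residues")
    if external is not None and prohormone_id is not None and prohormone_id in external:
        return external[prohormone_id]
    window = precursor[:_SIGNAL_SEARCH_WINDOW]
    core_end = None
    run_start = None
    for i, aa in enumerate(window + "$", start=1):  # sentinel terminates runs
        if aa in HYDROPHOBIC:
            if run_start is None:
                run_start = i
        else:
            if run_start is not None and i - run_start >= _SIGNAL_MIN_CORE:
                core_end = i - 1
                break
            run_start = None
    if core_end is None:
        return None
    for p in range(core_end + 1, min(core_end + _SIGNAL_CLEAVAGE_REACH, len(precursor) - 1) + 1):
        if precursor[p - 1] in _SIGNAL_MINUS1 and p >= 3 and precursor[p - 3] in _SIGNAL_MINUS3:
            return p
    return core_end


def predict_cleavage_sites(
    precursor: str,
    model: CleavageModel | None = None,
    signal_length: int | None = None,
    site_table: list[int] | None = None,
) -> list[int]:
    """Cut positions (1-based, cleavage after the position), sorted ascending.

    A run of consecutive basic residues yields a single cut after its last
    residue when any adjacent pair in the run matches a dibasic motif
    (rightmost rule, so overlapping motifs like KKR never produce zero-length
    peptides).  An isolated monobasic residue cleaves only when no other basic
    residue lies within the spacing window.  No cuts fall inside the signal
    region.  An injected site table bypasses the rules entirely.
    """
    if not precursor:
        raise ValueError("empty precursor")
    model = model or CleavageModel()
    start = (signal_length or 0) + 1
    if site_table is not None:
        return sorted({c for c in site_table if start <= c <= len(precursor)})
    basic_positions = [i for i, aa in enumerate(precursor, start=1) if aa in BASIC]
    cuts: set[int] = set()
    # maximal basic runs
    runs: list[tuple[int, int]] = []
    for pos in basic_positions:
        if runs and pos == runs[-1][1] + 1:
            runs[-1] = (runs[-1][0], pos)
        else:
            runs.append((pos, pos))
    for a, b in runs:
        if b - a + 1 >= 2:
            pairs = [precursor[i - 1 : i + 1] for i in range(a, b)]
            if any(p in model.dibasic_motifs for p in pairs):
                cuts.add(b)
        elif model.monobasic_enabled and precursor[a - 1] in model.monobasic_residues:
            isolated = all(
                other == a or abs(other - a) > model.monobasic_min_spacing
                for other in basic_positions
            )
            if isolated:
                cuts.add(a)
    return sorted(c for c in cuts if c >= start)


@dataclass(frozen=True)
class SegmentRecord:
    """One inter-cleavage segment with its stripped flanking residues.

    ``leading`` and ``trailing`` are the basic residues removed from the
    segment ends; ``donates_gly`` marks a core whose trailing Gly is consumed
    by amidation.  Concatenating leading + core (+G) + trailing over all
    segments reconstructs the post-signal precursor.
    """

    start: int  # 1-based position of the segment on the precursor
    end: int
    leading: str
    core: str
    trailing: str
    donates_gly: bool = False

    @property
    def core_start(self) -> int:
        return self.start + len(self.leading)

    @property
    def core_end(self) -> int:
        return self.core_start + len(self.core) - 1

    def reconstruct(self) -> str:
        return self.leading + self.core + ("G" if self.donates_gly else "") + self.trailing


_MAX_FLANK_STRIP = 2


def segment_records(
    precursor: str,
    cuts: list[int],
    signal_length: int | None = None,
) -> list[SegmentRecord]:
    """Split the post-signal precursor at the cut sites and strip basic flanks."""
    start = (signal_length or 0) + 1
    bounds = [c for c in cuts if c >= start]
    edges = [start - 1] + bounds + ([len(precursor)] if (not bounds or bounds[-1] != len(precursor)) else [])
    records: list[SegmentRecord] = []
    for left, right in zip(edges, edges[1:]):
        seg = precursor[left:right]
        if not seg:
            continue
        lead = 0
        while lead < min(_MAX_FLANK_STRIP, len(seg)) and seg[lead] in BASIC:
            lead += 1
        trail = 0
        while trail < min(_MAX_FLANK_STRIP, len(seg) - lead) and seg[len(seg) - 1 - trail] in BASIC:
            trail += 1
        core = seg[lead : len(seg) - trail]
        donates = core.endswith("G") and len(core) >= 2
        records.append(
            SegmentRecord(
                start=left + 1,
                end=right,
                leading=seg[:lead],
                core=core[:-1] if donates else core,
                trailing=seg[len(seg) - trail :],
                donates_gly=donates,
            )
        )
    return records


MIN_PEPTIDE_LENGTH = 2
MAX_VARIANTS_PER_SEGMENT = 8


def derive_peptides(
    precursor: str,
    cuts: list[int],
    model: CleavageModel | None = None,
    registry: dict[str, ModificationDelta] | None = None,
    family: str = "",
    prohormone_id: str = "",
    signal_length: int | None = None,
    emit_unamidated_gly: bool = False,
    acetylation_enabled: bool = False,
) -> list[PredictedPeptide]:
    """All predicted modification variants of the cleavage products.

    A core whose segment ends in Gly before a cut (or the sequence end) yields
    the amidated variant, the Gly being consumed; optionally the Gly-retaining
    free acid as well.  N-terminal Gln/Glu cores yield both the unmodified and
    pyroglutamated forms.  Acetylation variants are emitted only when enabled
    (combinatorial growth is otherwise unwarranted).  Cores shorter than 2
    residues are dropped.
    """
    registry = registry if registry is not None else default_registry()
    for required in ("amidation", "pyroglutamation-from-Gln", "pyroglutamation-from-Glu"):
        if required not in registry:
            raise ValueError(f"modification registry missing required delta {required!r}")
    peptides: list[PredictedPeptide] = []
    for seg in segment_records(precursor, cuts, signal_length):
        variants: list[tuple[str, frozenset[str]]] = []
        if seg.donates_gly:
            variants.append((seg.core, frozenset({"amidation"})))
            if emit_unamidated_gly:
                variants.append((seg.core + "G", frozenset()))
        else:
            variants.append((seg.core, frozenset()))
        if seg.core.startswith("Q"):
            variants.extend(
                (s, m | {"pyroglutamation-from-Gln"}) for s, m in list(variants) if s.startswith("Q")
            )
        elif seg.core.startswith("E"):
            variants.extend(
                (s, m | {"pyroglutamation-from-Glu"}) for s, m in list(variants) if s.startswith("E")
            )
        if acetylation_enabled:
            variants.extend(
                (s, m | {"acetylation"})
                for s, m in list(variants)
                if not any(mod.startswith("pyroglutamation") for mod in m)
            )
        if len(variants) > MAX_VARIANTS_PER_SEGMENT:
            warnings.warn(
                f"segment at {seg.start}-{seg.end} yields {len(variants)} variants; "
                f"capped at {MAX_VARIANTS_PER_SEGMENT}",
                stacklevel=2,
            )
            variants = variants[:MAX_VARIANTS_PER_SEGMENT]
        for seq, mods in variants:
            if len(seq) < MIN_PEPTIDE_LENGTH:
                continue
            peptides.append(
                PredictedPeptide.from_sequence(
                    seq,
                    mods,
                    prohormone_id=prohormone_id,
                    family=family,
                    start=seg.core_start,
                    end=seg.core_start + len(seq) - 1,
                    registry=registry,
                )
            )
    return peptides


def process_precursor(
    precursor: str,
    model: CleavageModel | None = None,
    registry: dict[str, ModificationDelta] | None = None,
    family: str = "",
    prohormone_id: str = "",
    signal_external: dict[str, int] | None = None,
    site_table: list[int] | None = None,
    **derive_kwargs,
) -> tuple[int | None, list[int], list[PredictedPeptide]]:
    """Convenience: signal call, cleavage sites, then peptide variants."""
    model = model or CleavageModel()
    signal = (
        predict_signal_peptide(precursor, signal_external, prohormone_id)
        if len(precursor) >= 20
        else None
    )
    cuts = predict_cleavage_sites(precursor, model, signal, site_table)
    peptides = derive_peptides(
        precursor,
        cuts,
        model,
        registry,
        family=family,
        prohormone_id=prohormone_id,
        signal_length=signal,
        **derive_kwargs,
    )
    return signal, cuts, peptides
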