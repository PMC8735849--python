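"""Per-neuron prohormone-family profiles and cross-neuron comparison.

A profile counts the distinct peptides (sequence + modification set, not
peaks) assigned to each prohormone family in one neuron's spectrum; the
presence matrix summarizes which families were detected in which neuron and
supports the shared/unique family breakdown.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .masses import PeakAssignment

__all__ = [
    "NeuronProfile",
    "FamilyPresenceMatrix",
    "family_profile",
    "presence_matrix",
    "motif_scan",
]


@dataclass
class NeuronProfile:
    sample_id: str
    species: str = ""
    family_counts: dict[str, int] = field(default_factory=dict)

    @property
    def families_present(self) -> set[str]:
        return {f for f, n in self.family_counts.items() if n >= 1}

    @property
    def n_distinct_peptides(self) -> int:
        return sum(self.family_counts.values())


def family_profile(
    assignments: list[PeakAssignment],
    sample_id: str | None = None,
    species: str = "",
) -> NeuronProfile:
    """Count distinct assigned peptides per family for one sample.

    All assignments must share one sample id.  A peptide assigned under two
    different families (cross-family isobaric ambiguity) triggers a warning
    rather than silent double counting.
    """
    ids = {a.sample_id for a in assignments}
    if len(ids) > 1:
        raise ValueError(f"assignments mix sample ids: {sorted(ids)}")
    if sample_id is None:
        sample_id = next(iter(ids)) if ids else ""
    distinct: dict[str, set[tuple[str, frozenset[str]]]] = {}
    seen_keys: dict[tuple[str, frozenset[str]], str] = {}
    for a in assignments:
        key = a.peptide.key
        if key in seen_keys and seen_keys[key] != a.family:
            warnings.warn(
                f"peptide {a.peptide.sequence!r} assigned under families "
                f"{seen_keys[key]!r} and {a.family!r}",
                stacklevel=2,
            )
        seen_keys.setdefault(key, a.family)
        distinct.setdefault(a.family, set()).add(key)
    counts = {fam: len(keys) for fam, keys in sorted(distinct.items())}
    return NeuronProfile(sample_id=sample_id, species=species, family_counts=counts)


@dataclass
class FamilyPresenceMatrix:
    """Boolean neurons x families matrix with shared/unique summaries."""

    table: pd.DataFrame  # index: row labels, columns: families, bool cells

    @property
    def families(self) -> list[str]:
        return list(self.table.columns)

    def families_in_all(self) -> set[str]:
        return {f for f in self.table.columns if bool(self.table[f].all())}

    def unique_families(self) -> dict[str, str]:
        """family -> the single row it occurs in, for families seen once."""
        out = {}
        for f in self.table.columns:
            rows = self.table.index[self.table[f]].tolist()
            if len(rows) == 1:
                out[f] = rows[0]
        return out

    def families_by_subset(self) -> dict[tuple[str, ...], list[str]]:
        """Map each set of rows to the families present in exactly those rows."""
        out: dict[tuple[str, ...], list[str]] = {}
        for f in self.table.columns:
            rows = tuple(sorted(self.table.index[self.table[f]].tolist()))
            out.setdefault(rows, []).append(f)
        return out

    def summary(self) -> dict:
        return {
            "families_in_all": sorted(self.families_in_all()),
            "unique_families": dict(sorted(self.unique_families().items())),
            "families_by_subset": {
                " + ".join(rows): sorted(fams)
                for rows, fams in sorted(self.families_by_subset().items())
            },
        }


def presence_matrix(profiles: list[NeuronProfile]) -> FamilyPresenceMatrix:
    """Presence/absence of each family across neurons (row order = input order)."""
    if not profiles:
        raise ValueError("presence_matrix needs at least one profile")
    labels = []
    for p in profiles:
        if p.species and p.species != p.sample_id:
            label = f"{p.species} {p.sample_id}"
        else:
            label = p.species or p.sample_id
        labels.append(label)
    families = sorted({f for p in profiles for f in p.families_present})
    data = {
        f: [f in p.families_present for p in profiles] for f in families
    }
    table = pd.DataFrame(data, index=labels, columns=families, dtype=bool)
    return FamilyPresenceMatrix(table=table)


def motif_scan(
    sequence: str,
    pattern: str,
    c_terminal: bool = False,
    require_amidation: bool = False,
    modifications: frozenset[str] | set[str] = frozenset(),
    leu_ile_equivalent: bool = True,
) -> list[int]:
    """1-based start positions where the motif matches.

    The pattern is fixed residue letters with 'X' as a single-residue
    wildcard; ``c_terminal`` anchors the match to the sequence end and
    ``require_amidation`` additionally demands the amidation modification in
    the peptide's modification set.  Because Leu and Ile are isobaric and
    indistinguishable by mass fingerprinting, an L in the pattern matches I
    (and vice versa) by default.
    """
    if not pattern:
        raise ValueError("empty motif pattern")
    if require_amidation and "amidation" not in modifications:
        return []
    k = len(pattern)
    if k > len(sequence):
        return []

    def matches(p: str, c: str) -> bool:
        if p == "X" or p == c:
            return True
        return leu_ile_equivalent and {p, c} == {"I", "L"}

    starts = [len(sequence) - k] if c_terminal else range(len(sequence) - k + 1)
    hits = []
    for s in starts:
        if all(matches(p, sequence[s + i]) for i, p in enumerate(pattern)):
            hits.append(s + 1)
    return hits
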