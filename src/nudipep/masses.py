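"""Monoisotopic peptide masses and peak matching (peptide mass fingerprinting).

Theoretical [M+H]+ values are additive: the sum of residue masses plus one
water for the termini, plus any modification deltas, plus one proton for the
singly charged MALDI ion.  All arithmetic is double precision; rounding happens
only when values are written to reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RESIDUE_MASS",
    "WATER_MASS",
    "PROTON_MASS",
    "ModificationDelta",
    "default_registry",
    "MatchParameters",
    "PredictedPeptide",
    "PeakAssignment",
    "MatchResult",
    "PeptideLibrary",
    "residue_mass",
    "peptide_neutral_mass",
    "peptide_mh",
    "ppm_error",
    "build_library",
    "match_peaks",
]

# Standard monoisotopic residue (amino-acid minus water) masses, Da, fixed to
# 5 decimals so that computed [M+H]+ values are reproducible bit-for-bit.
RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MASS = 18.01056
PROTON_MASS = 1.00728

# Modification site constraints.
SITE_C_TERMINAL_GLY = "c-terminal-gly"  # requires a Gly donor following the core
SITE_N_TERMINAL_GLN = "n-terminal-gln"
SITE_N_TERMINAL_GLU = "n-terminal-glu"
SITE_N_TERMINAL_ANY = "n-terminal-any"


@dataclass(frozen=True)
class ModificationDelta:
    """A post-translational modification as a monoisotopic mass shift."""

    name: str
    delta: float
    site: str


def default_registry() -> dict[str, ModificationDelta]:
    """The common neuropeptide PTMs: amidation, pyroglutamation, acetylation."""
    mods = [
        ModificationDelta("amidation", -0.98402, SITE_C_TERMINAL_GLY),
        ModificationDelta("pyroglutamation-from-Gln", -17.02655, SITE_N_TERMINAL_GLN),
        ModificationDelta("pyroglutamation-from-Glu", -18.01056, SITE_N_TERMINAL_GLU),
        ModificationDelta("acetylation", +42.01057, SITE_N_TERMINAL_ANY),
    ]
    return {m.name: m for m in mods}


class UnknownResidueError(KeyError):
    pass


class ModificationError(ValueError):
    pass


def residue_mass(residue: str) -> float:
    """Monoisotopic mass of one of the 20 canonical residues."""
    try:
        return RESIDUE_MASS[residue]
    except KeyError:
        raise UnknownResidueError(
            f"unknown residue {residue!r}: not one of the 20 canonical letters"
        ) from None


def _check_site(sequence: str, mod: ModificationDelta) -> None:
    if mod.site == SITE_N_TERMINAL_GLN and not sequence.startswith("Q"):
        raise ModificationError(
            f"{mod.name} requires an N-terminal Gln; sequence starts with {sequence[0]!r}"
        )
    if mod.site == SITE_N_TERMINAL_GLU and not sequence.startswith("E"):
        raise ModificationError(
            f"{mod.name} requires an N-terminal Glu; sequence starts with {sequence[0]!r}"
        )
    # Amidation site validity (the Gly donor) depends on precursor context and
    # is enforced where peptides are derived from the precursor.


def peptide_neutral_mass(
    sequence: str,
    modifications: frozenset[str] | set[str] = frozenset(),
    registry: dict[str, ModificationDelta] | None = None,
) -> float:
    """Neutral monoisotopic mass of a (possibly modified) peptide."""
    if not sequence:
        raise ValueError("empty peptide sequence")
    registry = registry if registry is not None else default_registry()
    total = sum(residue_mass(r) for r in sequence) + WATER_MASS
    for name in modifications:
        try:
            mod = registry[name]
        except KeyError:
            raise ModificationError(f"modification {name!r} not in registry") from None
        _check_site(sequence, mod)
        total += mod.delta
    return total


def peptide_mh(
    sequence: str,
    modifications: frozenset[str] | set[str] = frozenset(),
    registry: dict[str, ModificationDelta] | None = None,
) -> float:
    """Singly protonated ion mass [M+H]+ of a modified peptide, Da."""
    return peptide_neutral_mass(sequence, modifications, registry) + PROTON_MASS


def ppm_error(observed: float, theoretical: float) -> float:
    """Signed relative mass error in parts per million.

    Positive when the observed mass is heavier than the theoretical one;
    reports round this to 1 decimal.
    """
    if theoretical <= 0:
        raise ValueError("theoretical mass must be positive")
    return (observed - theoretical) / theoretical * 1e6


@dataclass(frozen=True)
class MatchParameters:
    """Settings for peptide mass fingerprinting."""

    tolerance_ppm: float = 200.0
    proton_mass: float = PROTON_MASS
    water_mass: float = WATER_MASS
    assignment_policy: str = "all-within-tolerance"  # or "best-only"

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance_ppm must be positive")
        if self.assignment_policy not in ("all-within-tolerance", "best-only"):
            raise ValueError(f"unknown assignment policy {self.assignment_policy!r}")


@dataclass(frozen=True)
class PredictedPeptide:
    """A cleavage product with its modification set and theoretical masses.

    ``start``/``end`` are 1-based inclusive positions of the core sequence on
    the precursor (the amidation-donating Gly at ``end + 1`` is not part of
    the core).
    """

    prohormone_id: str
    family: str
    start: int
    end: int
    sequence: str
    modifications: frozenset[str]
    neutral_mass: float
    mh: float

    @classmethod
    def from_sequence(
        cls,
        sequence: str,
        modifications: frozenset[str] | set[str] = frozenset(),
        *,
        prohormone_id: str = "",
        family: str = "",
        start: int = 1,
        end: int | None = None,
        registry: dict[str, ModificationDelta] | None = None,
        mh: float | None = None,
    ) -> "PredictedPeptide":
        """Build a peptide, computing masses unless an explicit mh is given."""
        mods = frozenset(modifications)
        if mh is None:
            neutral = peptide_neutral_mass(sequence, mods, registry)
            mh = neutral + PROTON_MASS
        else:
            neutral = mh - PROTON_MASS
        return cls(
            prohormone_id=prohormone_id,
            family=family,
            start=start,
            end=end if end is not None else start + len(sequence) - 1,
            sequence=sequence,
            modifications=mods,
            neutral_mass=neutral,
            mh=mh,
        )

    @property
    def key(self) -> tuple[str, frozenset[str]]:
        return (self.sequence, self.modifications)


@dataclass(frozen=True)
class PeakAssignment:
    """An observed peak matched to a library peptide within tolerance."""

    sample_id: str
    mz: float
    peptide: PredictedPeptide
    ppm_error: float
    ambiguous: bool = False

    @property
    def family(self) -> str:
        return self.peptide.family


class PeptideLibrary:
    """A mass-sorted, bisection-searchable peptide library."""

    def __init__(self, peptides: list[PredictedPeptide]):
        seen: dict[tuple[str, frozenset[str]], PredictedPeptide] = {}
        for p in peptides:
            seen.setdefault(p.key, p)
        ordered = sorted(seen.values(), key=lambda p: (p.mh, p.sequence))
        self.peptides: list[PredictedPeptide] = ordered
        self._mh = np.array([p.mh for p in ordered], dtype=float)

    def __len__(self) -> int:
        return len(self.peptides)

    def __iter__(self):
        return iter(self.peptides)

    @property
    def mh_values(self) -> np.ndarray:
        return self._mh

    def query(self, mz: float, tolerance_ppm: float) -> list[PredictedPeptide]:
        """All entries whose theoretical mh lies within the ppm window of mz."""
        lo = mz / (1.0 + tolerance_ppm * 1e-6)
        hi = mz / (1.0 - tolerance_ppm * 1e-6)
        i = int(np.searchsorted(self._mh, lo, side="left"))
        j = int(np.searchsorted(self._mh, hi, side="right"))
        return [
            p
            for p in self.peptides[i:j]
            if abs(ppm_error(mz, p.mh)) <= tolerance_ppm
        ]


def build_library(peptides: list[PredictedPeptide]) -> PeptideLibrary:
    """Deduplicate (sequence, modifications) pairs and sort ascending by mh."""
    return PeptideLibrary(peptides)


@dataclass
class MatchResult:
    """Assignments plus the peaks that matched nothing."""

    assignments: list[PeakAssignment]
    unassigned: list = field(default_factory=list)


def match_peaks(peaks, library: PeptideLibrary, params: MatchParameters | None = None) -> MatchResult:
    """Match observed [M+H]+ peaks to the library by ppm tolerance.

    Under ``all-within-tolerance`` every library entry within the window is
    reported (peaks with several candidates are flagged ambiguous); under
    ``best-only`` the minimum-|ppm| entry wins, ties broken by lower mh then
    lexicographically smaller sequence.
    """
    params = params or MatchParameters()
    assignments: list[PeakAssignment] = []
    unassigned = []
    for peak in peaks.peaks:
        hits = library.query(peak.mz, params.tolerance_ppm)
        if not hits:
            unassigned.append(peak)
            continue
        if params.assignment_policy == "best-only":
            hits = [min(hits, key=lambda p: (abs(ppm_error(peak.mz, p.mh)), p.mh, p.sequence))]
        ambiguous = len(hits) > 1
        for p in hits:
            assignments.append(
                PeakAssignment(
                    sample_id=peaks.sample_id,
                    mz=peak.mz,
                    peptide=p,
                    ppm_error=ppm_error(peak.mz, p.mh),
                    ambiguous=ambiguous,
                )
            )
    return MatchResult(assignments=assignments, unassigned=unassigned)
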