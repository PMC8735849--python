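"""Synthetic precursors, transcripts and MALDI peak lists with ground truth.

The generator emulates the statistical structure the pipeline assumes: a
prohormone is a signal peptide followed by peptide cassettes flanked by
dibasic KR sites (with optional Gly amidation donors); a transcript is the
reverse-translated precursor embedded in random UTRs, optionally
strand-flipped and point-mutated; a spectrum is one peak per surviving
peptide at its theoretical [M+H]+ perturbed by Gaussian ppm noise, plus
uniform contaminant peaks kept away from library masses so recovery tests
have unambiguous truth.  Every random draw flows from one seed through named
per-component streams, so outputs are bit-reproducible.
"""

from __future__ import annotations

import json
import zlib
from bisect import bisect_left
from dataclasses import dataclass, field, asdict

import numpy as np
from Bio.Data import CodonTable

from .io import NucleotideContig, Peak, PeakList
from .masses import PeakAssignment, PredictedPeptide, peptide_mh

__all__ = [
    "SyntheticSpec",
    "TrueProhormone",
    "ContigRecord",
    "PeakRecord",
    "GroundTruthManifest",
    "RecoveryScore",
    "SyntheticDataset",
    "make_prohormone",
    "encode_transcript",
    "simulate_peaklist",
    "score_recovery",
    "generate_dataset",
]

_CORE_ALPHABET = "ADFHILMNPSTVWY"  # no basics, no Gly/Gln/Glu, no Cys
_SPACER_ALPHABET = "SD"
_SIGNAL_HYDROPHOBIC = "LIVFMA"
_MUTATION_ALPHABET = "ADEFHILMNPQSTVWY"


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_prohormones: int = 3
    peptides_per_prohormone: tuple[int, int] = (2, 5)
    signal_length_range: tuple[int, int] = (18, 30)
    utr_length_range: tuple[int, int] = (30, 120)
    substitution_rate: float = 0.0
    noise_ppm_sigma: float = 20.0
    contaminant_count: int = 5
    dropout_probability: float = 0.2
    tolerance_ppm: float = 200.0
    adversarial_decoy_ppm: float | None = None

    def __post_init__(self) -> None:
        if not 0 <= self.dropout_probability <= 1:
            raise ValueError("dropout_probability must be in [0, 1]")
        if not 0 <= self.substitution_rate <= 1:
            raise ValueError("substitution_rate must be in [0, 1]")
        if self.noise_ppm_sigma < 0:
            raise ValueError("noise_ppm_sigma must be >= 0")


def stream(spec: SyntheticSpec, name: str) -> np.random.Generator:
    """A named RNG stream fanned out from the spec seed.

    Streams are keyed by a hash of the name, so adding a new generator never
    perturbs the draws of existing ones.
    """
    key = zlib.crc32(name.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(key,)))


@dataclass(frozen=True)
class TrueProhormone:
    prohormone_id: str
    family: str
    precursor: str
    signal_length: int
    cut_positions: tuple[int, ...]
    true_peptides: tuple[PredictedPeptide, ...]


@dataclass(frozen=True)
class ContigRecord:
    contig_id: str
    prohormone_id: str
    frame: int  # BLAST convention on the emitted contig
    protein: str  # the (possibly mutated) encoded precursor
    n_substitutions: int
    substitution_positions: tuple[int, ...]


@dataclass(frozen=True)
class PeakRecord:
    mz: float
    origin: str  # "<prohormone_id>:<sequence>:<mods>" | "contaminant" | "decoy:..."
    ppm_offset: float


def _peptide_origin(p: PredictedPeptide) -> str:
    return f"{p.prohormone_id}:{p.sequence}:{','.join(sorted(p.modifications))}"


@dataclass
class GroundTruthManifest:
    """Everything needed to recompute every expected pipeline output."""

    spec: SyntheticSpec
    prohormones: list[TrueProhormone] = field(default_factory=list)
    contigs: list[ContigRecord] = field(default_factory=list)
    peaks: list[PeakRecord] = field(default_factory=list)

    def all_true_peptides(self) -> list[PredictedPeptide]:
        return [p for pro in self.prohormones for p in pro.true_peptides]

    def surviving_peptides(self) -> list[PredictedPeptide]:
        origins = {r.origin for r in self.peaks}
        return [p for p in self.all_true_peptides() if _peptide_origin(p) in origins]

    def family_presence(self) -> set[str]:
        """Families with at least one surviving (detectable) peptide."""
        return {p.family for p in self.surviving_peptides()}

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, frozenset):
                return sorted(o)
            raise TypeError(type(o))

        return json.dumps(asdict(self), default=default, indent=1)


def make_prohormone(
    spec: SyntheticSpec,
    rng: np.random.Generator,
    index: int = 0,
    existing_masses: list[float] | None = None,
) -> TrueProhormone:
    """One synthetic precursor: signal + [spacer KR core(+G) KR] cassettes.

    Cores are drawn without basic residues so the rule-based cleavage engine
    recovers exactly the planted peptides; the signal is built to end with an
    S-S-A cleavage context that the built-in signal heuristic resolves to the
    planted length.
    """
    existing = list(existing_masses or [])
    pid = f"SYN{index + 1}"
    family = f"FAM{index + 1}"
    sig_len = int(rng.integers(spec.signal_length_range[0], spec.signal_length_range[1] + 1))
    hydro = "".join(rng.choice(list(_SIGNAL_HYDROPHOBIC), size=sig_len - 5))
    signal = "M" + str(rng.choice(list("TN"))) + hydro + "SSA"
    assert len(signal) == sig_len
    k = int(rng.integers(spec.peptides_per_prohormone[0], spec.peptides_per_prohormone[1] + 1))
    parts = [signal]
    pos = sig_len
    cuts: list[int] = []
    peptides: list[PredictedPeptide] = []
    for _ in range(k):
        spacer = str(rng.choice(list(_SPACER_ALPHABET)))
        while True:
            core_len = int(rng.integers(5, 11))
            core = "".join(rng.choice(list(_CORE_ALPHABET), size=core_len))
            amidated = bool(rng.random() < 0.5)
            mods = frozenset({"amidation"}) if amidated else frozenset()
            mh = peptide_mh(core, mods)
            # >= 1 Da apart: even a 5-sigma noisy peak cannot reach another
            # library mass within the default 200 ppm tolerance
            if mh >= 540.0 and all(abs(mh - m) > 1.0 for m in existing):
                break
        existing.append(mh)
        cassette = spacer + "KR" + core + ("G" if amidated else "") + "KR"
        # positions: spacer | K R | core | (G) | K R
        cut1 = pos + len(spacer) + 2
        core_start = cut1 + 1
        core_end = core_start + core_len - 1
        cut2 = core_end + (1 if amidated else 0) + 2
        cuts.extend([cut1, cut2])
        peptides.append(
            PredictedPeptide.from_sequence(
                core, mods, prohormone_id=pid, family=family, start=core_start, end=core_end
            )
        )
        parts.append(cassette)
        pos = cut2
    precursor = "".join(parts)
    return TrueProhormone(
        prohormone_id=pid,
        family=family,
        precursor=precursor,
        signal_length=sig_len,
        cut_positions=tuple(cuts),
        true_peptides=tuple(peptides),
    )


_CODON_TABLE = CodonTable.unambiguous_dna_by_id[1]


def _codons_by_aa() -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for codon, aa in sorted(_CODON_TABLE.forward_table.items()):
        out.setdefault(aa, []).append(codon)
    out["*"] = sorted(_CODON_TABLE.stop_codons)
    return out


_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def encode_transcript(
    prohormone: TrueProhormone,
    spec: SyntheticSpec,
    rng: np.random.Generator,
) -> tuple[NucleotideContig, ContigRecord]:
    """Reverse-translate a precursor into a contig with UTRs.

    Codons are chosen uniformly among synonyms.  Point substitutions (at the
    spec rate, interior residues only) are applied at the protein level and
    recorded.  The 5' UTR ends with an in-frame stop so the open reading
    frame of the encoded precursor is exactly stop-bounded; the contig is
    strand-flipped half the time.
    """
    codons = _codons_by_aa()
    protein = list(prohormone.precursor)
    sub_positions: list[int] = []
    if spec.substitution_rate > 0:
        for i in range(3, len(protein) - 3):  # keep termini intact
            if rng.random() < spec.substitution_rate:
                choices = [a for a in _MUTATION_ALPHABET if a != protein[i]]
                protein[i] = str(rng.choice(choices))
                sub_positions.append(i + 1)
    protein_str = "".join(protein)
    cds = "".join(str(rng.choice(codons[aa])) for aa in protein_str)
    cds += str(rng.choice(codons["*"]))
    utr5_len = int(rng.integers(spec.utr_length_range[0], spec.utr_length_range[1] + 1))
    utr3_len = int(rng.integers(spec.utr_length_range[0], spec.utr_length_range[1] + 1))
    utr5 = "".join(rng.choice(list("ACGT"), size=utr5_len))
    utr3 = "".join(rng.choice(list("ACGT"), size=utr3_len))
    utr5 = utr5[:-3] + "TAA" if utr5_len >= 3 else "TAA"
    forward = utr5 + cds + utr3
    frame = (len(utr5) % 3) + 1
    flipped = bool(rng.random() < 0.5)
    sequence = forward.translate(_COMPLEMENT)[::-1] if flipped else forward
    contig = NucleotideContig(
        id=f"contig_{prohormone.prohormone_id}",
        sequence=sequence,
        description=f"synthetic transcript of {prohormone.prohormone_id}",
    )
    record = ContigRecord(
        contig_id=contig.id,
        prohormone_id=prohormone.prohormone_id,
        frame=-frame if flipped else frame,
        protein=protein_str,
        n_substitutions=len(sub_positions),
        substitution_positions=tuple(sub_positions),
    )
    return contig, record


def simulate_peaklist(
    true_peptides: list[PredictedPeptide],
    spec: SyntheticSpec,
    rng: np.random.Generator,
    library_masses: list[float] | None = None,
    sample_id: str = "synthetic",
    species: str = "synthetic",
) -> tuple[PeakList, list[PeakRecord]]:
    """One peak per surviving peptide plus contaminants.

    Peptides drop out independently at the spec rate; each survivor gets one
    peak at mh * (1 + eps*1e-6) with eps ~ Normal(0, sigma).  Contaminants
    are uniform on the surveyed 530-5000 Da range and re-drawn while within
    the ppm tolerance of any library mass.  In adversarial mode one decoy
    peak per survivor is placed at a fixed ppm offset to exercise ambiguity
    flagging.
    """
    masses = library_masses if library_masses is not None else [p.mh for p in true_peptides]
    records: list[PeakRecord] = []
    for p in true_peptides:
        if rng.random() < spec.dropout_probability:
            continue
        eps = float(rng.normal(0.0, spec.noise_ppm_sigma)) if spec.noise_ppm_sigma > 0 else 0.0
        mz = p.mh * (1.0 + eps * 1e-6)
        records.append(PeakRecord(mz=mz, origin=_peptide_origin(p), ppm_offset=eps))
        if spec.adversarial_decoy_ppm is not None:
            off = spec.adversarial_decoy_ppm
            records.append(
                PeakRecord(
                    mz=p.mh * (1.0 + off * 1e-6),
                    origin=f"decoy:{_peptide_origin(p)}",
                    ppm_offset=off,
                )
            )
    for _ in range(spec.contaminant_count):
        while True:
            mz = float(rng.uniform(530.0, 5000.0))
            near = any(abs(mz - m) / m * 1e6 <= spec.tolerance_ppm for m in masses)
            if not near:
                break
        records.append(PeakRecord(mz=mz, origin="contaminant", ppm_offset=0.0))
    peaks = PeakList(
        sample_id=sample_id,
        species=species,
        peaks=[Peak(mz=r.mz) for r in records],
    )
    return peaks, records


@dataclass
class RecoveryScore:
    precision: float | None
    recall: float | None
    per_family: dict[str, dict[str, float | None]] = field(default_factory=dict)


def score_recovery(
    assignments: list[PeakAssignment],
    manifest: GroundTruthManifest,
) -> RecoveryScore:
    """Precision/recall of assignments against the generator's ground truth.

    Precision is the fraction of assignments whose peak originates from the
    assigned peptide; recall is the fraction of surviving true peptides
    correctly assigned.  Both are None (reported as absent) when undefined.
    """
    mzs = sorted((r.mz, r) for r in manifest.peaks)
    keys = [m for m, _ in mzs]

    def lookup(mz: float) -> PeakRecord:
        i = bisect_left(keys, mz)
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(keys) and abs(keys[j] - mz) < 1e-4:
                return mzs[j][1]
        raise ValueError(f"assignment m/z {mz} not found in manifest (sample mismatch?)")

    surviving = manifest.surviving_peptides()
    by_family_truth: dict[str, set[str]] = {}
    for p in surviving:
        by_family_truth.setdefault(p.family, set()).add(_peptide_origin(p))
    correct_origins: dict[str, set[str]] = {}
    n_correct = 0
    fam_assign: dict[str, int] = {}
    fam_correct: dict[str, int] = {}
    for a in assignments:
        rec = lookup(a.mz)
        fam_assign[a.family] = fam_assign.get(a.family, 0) + 1
        if rec.origin == _peptide_origin(a.peptide):
            n_correct += 1
            fam_correct[a.family] = fam_correct.get(a.family, 0) + 1
            correct_origins.setdefault(a.family, set()).add(rec.origin)
    precision = n_correct / len(assignments) if assignments else None
    n_surviving = len(surviving)
    n_recovered = sum(len(v) for v in correct_origins.values())
    recall = n_recovered / n_surviving if n_surviving else None
    per_family: dict[str, dict[str, float | None]] = {}
    for fam in sorted(set(fam_assign) | set(by_family_truth)):
        fam_p = fam_correct.get(fam, 0) / fam_assign[fam] if fam_assign.get(fam) else None
        truth = by_family_truth.get(fam, set())
        fam_r = len(correct_origins.get(fam, set()) & truth) / len(truth) if truth else None
        per_family[fam] = {"precision": fam_p, "recall": fam_r}
    return RecoveryScore(precision=precision, recall=recall, per_family=per_family)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    prohormones: list[TrueProhormone]
    contigs: list[NucleotideContig]
    peaklist: PeakList
    manifest: GroundTruthManifest


def generate_dataset(spec: SyntheticSpec) -> SyntheticDataset:
    """Full dataset: precursors, encoding contigs, peak list, manifest."""
    rng_pro = stream(spec, "prohormone")
    rng_tx = stream(spec, "transcript")
    rng_peaks = stream(spec, "peaks")
    prohormones: list[TrueProhormone] = []
    masses: list[float] = []
    for i in range(spec.n_prohormones):
        pro = make_prohormone(spec, rng_pro, index=i, existing_masses=masses)
        masses.extend(p.mh for p in pro.true_peptides)
        prohormones.append(pro)
    contigs = []
    contig_records = []
    for pro in prohormones:
        contig, rec = encode_transcript(pro, spec, rng_tx)
        contigs.append(contig)
        contig_records.append(rec)
    true_peptides = [p for pro in prohormones for p in pro.true_peptides]
    peaklist, peak_records = simulate_peaklist(true_peptides, spec, rng_peaks)
    manifest = GroundTruthManifest(
        spec=spec, prohormones=prohormones, contigs=contig_records, peaks=peak_records
    )
    return SyntheticDataset(
        spec=spec,
        prohormones=prohormones,
        contigs=contigs,
        peaklist=peaklist,
        manifest=manifest,
    )
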