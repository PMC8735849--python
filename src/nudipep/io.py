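"""Reading and writing the pipeline's file formats.

FASTA for sequences (via Biopython), plain TSV for peak lists, peptide
libraries and assignment reports.  Peak lists are centroided [M+H]+ values,
one per row; raw spectra and mzML are out of scope.  All text is UTF-8 with
"." as the decimal point.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from .masses import PeakAssignment, PredictedPeptide

NUCLEOTIDE_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY")

# The instrument's surveyed m/z range; peaks outside it are kept but flagged.
SURVEYED_RANGE = (530.0, 5000.0)


class ValidationError(ValueError):
    """Malformed input naming the offending record/line and position."""


@dataclass(frozen=True)
class NucleotideContig:
    """A transcript contig (assembled cDNA) to be searched for prohormone ORFs."""

    id: str
    sequence: str
    description: str = ""


@dataclass(frozen=True)
class QueryProhormone:
    """A known prohormone protein used as a homology-search query."""

    accession: str
    sequence: str
    organism: str = ""
    name: str = ""


@dataclass(frozen=True)
class Peak:
    mz: float
    intensity: float | None = None


@dataclass
class PeakList:
    """Observed [M+H]+ values for one sample (one neuron), sorted ascending."""

    sample_id: str
    species: str = ""
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        for p in self.peaks:
            if p.mz <= 0:
                raise ValidationError(f"non-positive m/z {p.mz} in sample {self.sample_id!r}")
        self.peaks = sorted(self.peaks, key=lambda p: p.mz)
        seen: set[float] = set()
        for p in self.peaks:
            if p.mz in seen:
                warnings.warn(
                    f"duplicate m/z {p.mz} in sample {self.sample_id!r}", stacklevel=2
                )
            seen.add(p.mz)
            if not SURVEYED_RANGE[0] <= p.mz <= SURVEYED_RANGE[1]:
                warnings.warn(
                    f"m/z {p.mz} outside surveyed range {SURVEYED_RANGE} "
                    f"in sample {self.sample_id!r}",
                    stacklevel=2,
                )

    def __len__(self) -> int:
        return len(self.peaks)


def _validate_sequence(seq: str, alphabet: set[str], record_id: str, kind: str) -> str:
    seq = seq.upper()
    for pos, ch in enumerate(seq, start=1):
        if ch not in alphabet:
            raise ValidationError(
                f"illegal {kind} character {ch!r} at position {pos} in record {record_id!r}"
            )
    if not seq:
        raise ValidationError(f"empty sequence in record {record_id!r}")
    return seq


def read_fasta(path, alphabet: str):
    """Parse a FASTA file into contigs or query prohormones.

    ``alphabet`` is ``"nucleotide"`` (A/C/G/T/N) or ``"protein"`` (the 20
    canonical residues).  Sequences are uppercased; anything else is rejected
    with the record and offset named.  An empty file yields an empty list.
    """
    if alphabet not in ("nucleotide", "protein"):
        raise ValueError(f"alphabet must be 'nucleotide' or 'protein', got {alphabet!r}")
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if alphabet == "nucleotide":
            seq = _validate_sequence(str(rec.seq), NUCLEOTIDE_ALPHABET, rec.id, "nucleotide")
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(NucleotideContig(id=rec.id, sequence=seq, description=desc))
        else:
            seq = _validate_sequence(str(rec.seq), PROTEIN_ALPHABET, rec.id, "protein")
            desc = rec.description[len(rec.id):].strip() if rec.description else ""
            records.append(QueryProhormone(accession=rec.id, sequence=seq, name=desc))
    return records


def write_fasta(records, path) -> None:
    """Write contigs or prohormones back out as FASTA (unwrapped lines)."""
    seqrecords = []
    for r in records:
        if isinstance(r, NucleotideContig):
            seqrecords.append(SeqRecord(Seq(r.sequence), id=r.id, description=r.description))
        else:
            seqrecords.append(SeqRecord(Seq(r.sequence), id=r.accession, description=r.name))
    with open(path, "w", encoding="utf-8") as fh:
        for rec in seqrecords:
            header = f">{rec.id} {rec.description}".rstrip()
            fh.write(f"{header}\n{rec.seq}\n")


def read_peaklist(path, sample_id: str | None = None, species: str = "") -> PeakList:
    """Read a peak-list TSV (columns: mz[, intensity]; '#' comments allowed)."""
    path = Path(path)
    if sample_id is None:
        sample_id = path.stem
    peaks: list[Peak] = []
    header: list[str] | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip().lower() for f in fields]
                if "mz" not in header:
                    raise ValidationError(
                        f"{path}: line {lineno}: peak list needs an 'mz' column"
                    )
                continue
            row = dict(zip(header, fields))
            try:
                mz = float(row["mz"])
            except (KeyError, ValueError):
                raise ValidationError(
                    f"{path}: line {lineno}: non-numeric m/z {row.get('mz')!r}"
                ) from None
            if mz <= 0:
                raise ValidationError(f"{path}: line {lineno}: non-positive m/z {mz}")
            intensity = None
            if "intensity" in row and row["intensity"] not in ("", "NA"):
                try:
                    intensity = float(row["intensity"])
                except ValueError:
                    raise ValidationError(
                        f"{path}: line {lineno}: non-numeric intensity {row['intensity']!r}"
                    ) from None
            peaks.append(Peak(mz=mz, intensity=intensity))
    return PeakList(sample_id=sample_id, species=species, peaks=peaks)


def write_peaklist(peaklist: PeakList, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mz\tintensity\n")
        for p in peaklist.peaks:
            inten = "" if p.intensity is None else f"{p.intensity:.6f}"
            fh.write(f"{p.mz:.6f}\t{inten}\n")


_MOD_SEP = ";"

LIBRARY_COLUMNS = [
    "prohormone_id",
    "family",
    "start",
    "end",
    "sequence",
    "modifications",
    "neutral_mass",
    "mh",
]


def format_modifications(mods: frozenset[str]) -> str:
    return _MOD_SEP.join(sorted(mods))


def parse_modifications(text) -> frozenset[str]:
    if text is None or (isinstance(text, float) and pd.isna(text)) or text == "":
        return frozenset()
    return frozenset(str(text).split(_MOD_SEP))


def write_library(peptides, path) -> None:
    """Write a peptide library TSV (one row per modification variant)."""
    rows = [
        {
            "prohormone_id": p.prohormone_id,
            "family": p.family,
            "start": p.start,
            "end": p.end,
            "sequence": p.sequence,
            "modifications": format_modifications(p.modifications),
            "neutral_mass": f"{p.neutral_mass:.6f}",
            "mh": f"{p.mh:.6f}",
        }
        for p in peptides
    ]
    pd.DataFrame(rows, columns=LIBRARY_COLUMNS).to_csv(path, sep="\t", index=False)


def read_library(path) -> list[PredictedPeptide]:
    df = pd.read_csv(path, sep="\t", dtype={"modifications": str})
    missing = set(LIBRARY_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: library TSV missing columns {sorted(missing)}")
    peptides = []
    for _, row in df.iterrows():
        peptides.append(
            PredictedPeptide(
                prohormone_id=str(row["prohormone_id"]),
                family=str(row["family"]),
                start=int(row["start"]),
                end=int(row["end"]),
                sequence=str(row["sequence"]),
                modifications=parse_modifications(row["modifications"]),
                neutral_mass=float(row["neutral_mass"]),
                mh=float(row["mh"]),
            )
        )
    return peptides


ASSIGNMENT_COLUMNS = [
    "sample_id",
    "mz",
    "peptide_sequence",
    "modifications",
    "family",
    "theoretical_mh",
    "ppm_error",
]


def write_assignments(assignments: list[PeakAssignment], path) -> None:
    """Write an assignment report TSV; ppm errors rounded to 1 decimal."""
    rows = [
        {
            "sample_id": a.sample_id,
            "mz": f"{a.mz:.6f}",
            "peptide_sequence": a.peptide.sequence,
            "modifications": format_modifications(a.peptide.modifications),
            "family": a.family,
            "theoretical_mh": f"{a.peptide.mh:.6f}",
            "ppm_error": f"{a.ppm_error:.1f}",
        }
        for a in assignments
    ]
    pd.DataFrame(rows, columns=ASSIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_assignments(path) -> pd.DataFrame:
    """Read an assignment report back as a DataFrame (round-trip of the TSV)."""
    df = pd.read_csv(path, sep="\t", dtype={"modifications": str})
    missing = set(ASSIGNMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: assignment TSV missing columns {sorted(missing)}")
    df["modifications"] = df["modifications"].fillna("")
    return df
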