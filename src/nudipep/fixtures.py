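"""Packaged published fixtures: per-species peptide tables and peak lists.

The packaged table lists, for each of the three species' characterized
neurons, the identified peptides with their modification sets, the observed
mean [M+H]+ and the theoretical [M+H]+ as printed in the original report.
The printed theoretical column is kept verbatim — including rows known to
disagree with additive recomputation — so the mass calculator can be checked
against it honestly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .io import Peak, PeakList
from .masses import PredictedPeptide, peptide_mh
from . import io as nio

H_CRASSICORNIS = "H. crassicornis"
M_LEONINA = "M. leonina"
P_CALIFORNICA = "P. californica"
SPECIES = (H_CRASSICORNIS, M_LEONINA, P_CALIFORNICA)

# Rows whose printed theoretical mass is 1.000 Da above the additive value
# (an arithmetic slip in the original table); they are documented
# expected-fails for mass recomputation and are matched via the printed mass.
DISCREPANT_SEQUENCES = frozenset({"SGYLAFPRM"})


def load_fixture_table() -> pd.DataFrame:
    ref = resources.files("nudipep.data") / "slb_vwc_peptides.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"modifications": str})
    df["modifications"] = df["modifications"].fillna("")
    return df


def _species_rows(species: str) -> pd.DataFrame:
    df = load_fixture_table()
    if species not in SPECIES:
        raise ValueError(f"unknown species {species!r}; expected one of {SPECIES}")
    return df[df["species"] == species].reset_index(drop=True)


def fixture_library(species: str, use_printed: bool = True) -> list[PredictedPeptide]:
    """The species' peptide library from the published table.

    With ``use_printed`` (default) the search mass is the printed theoretical
    [M+H]+ where the table prints one — that is the library the published
    matching used; otherwise every mass is recomputed from the sequence and
    modification set.
    """
    peptides = []
    for _, row in _species_rows(species).iterrows():
        mods = nio.parse_modifications(row["modifications"])
        printed = row.get("printed_mh")
        mh = None
        if use_printed and pd.notna(printed):
            mh = float(printed)
        peptides.append(
            PredictedPeptide.from_sequence(
                str(row["sequence"]),
                mods,
                prohormone_id=f"{species}:{row['family']}",
                family=str(row["family"]),
                mh=mh,
            )
        )
    return peptides


def fixture_peaklist(species: str, sample_id: str | None = None) -> PeakList:
    """The species' observed mean [M+H]+ values as a peak list.

    Peptides previously characterized in the neuron but without a printed
    observed mean (the P. californica FMRFa/QNFLa entries) are represented at
    their computed theoretical [M+H]+, recording the published finding that
    they are present in the cell.
    """
    if sample_id is None:
        sample_id = species
    peaks = []
    for _, row in _species_rows(species).iterrows():
        mean = row.get("mean_mh")
        if pd.notna(mean):
            peaks.append(Peak(mz=float(mean)))
        else:
            mods = nio.parse_modifications(row["modifications"])
            peaks.append(Peak(mz=peptide_mh(str(row["sequence"]), mods)))
    return PeakList(sample_id=sample_id, species=species, peaks=peaks)


def printed_mass_rows() -> pd.DataFrame:
    """All rows carrying both an observed mean and a printed theoretical mass."""
    df = load_fixture_table()
    return df[df["mean_mh"].notna() & df["printed_mh"].notna()].reset_index(drop=True)
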