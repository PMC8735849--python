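"""Generator determinism and ground-truth recovery through the pipeline."""

import dataclasses

import pytest

from nudipep.cleavage import process_precursor
from nudipep.homology import six_frame_translate, translated_search
from nudipep.io import QueryProhormone
from nudipep.masses import MatchParameters, build_library, match_peaks
from nudipep.profiles import family_profile
from nudipep.synthetic import (
    SyntheticSpec,
    encode_transcript,
    generate_dataset,
    make_prohormone,
    score_recovery,
    simulate_peaklist,
    stream,
)


def library_for(dataset):
    peptides = []
    for pro in dataset.prohormones:
        _, _, peps = process_precursor(
            pro.precursor, family=pro.family, prohormone_id=pro.prohormone_id
        )
        peptides.extend(peps)
    return build_library(peptides)


class TestMakeProhormone:
    def test_planted_cores_recovered_by_cleavage_rules(self):
        spec = SyntheticSpec(seed=7, peptides_per_prohormone=(2, 2))
        pro = make_prohormone(spec, stream(spec, "prohormone"))
        signal, cuts, peps = process_precursor(
            pro.precursor, family=pro.family, prohormone_id=pro.prohormone_id
        )
        assert signal == pro.signal_length
        assert list(cuts) == list(pro.cut_positions)
        assert sorted(p.key for p in peps) == sorted(p.key for p in pro.true_peptides)
        assert len(pro.true_peptides) == 2

    def test_zero_cassettes_gives_signal_only_protein(self):
        spec = SyntheticSpec(seed=1, peptides_per_prohormone=(0, 0))
        pro = make_prohormone(spec, stream(spec, "prohormone"))
        assert pro.true_peptides == ()
        assert len(pro.precursor) == pro.signal_length

    def test_same_seed_identical_output(self):
        spec = SyntheticSpec(seed=13)
        a = make_prohormone(spec, stream(spec, "prohormone"))
        b = make_prohormone(spec, stream(spec, "prohormone"))
        assert a == b


class TestEncodeTranscript:
    def test_faithful_encoding_translates_back(self):
        spec = SyntheticSpec(seed=3, substitution_rate=0.0)
        pro = make_prohormone(spec, stream(spec, "prohormone"))
        contig, rec = encode_transcript(pro, spec, stream(spec, "transcript"))
        translation = six_frame_translate(contig)[rec.frame]
        assert pro.precursor in translation
        assert rec.protein == pro.precursor

    def test_strand_flipped_contig_recovered_in_negative_frame(self):
        spec = SyntheticSpec(seed=0)
        rng = stream(spec, "transcript")
        pro = make_prohormone(spec, stream(spec, "prohormone"))
        flipped = None
        for _ in range(10):  # strand choice is random; find a flipped one
            contig, rec = encode_transcript(pro, spec, rng)
            if rec.frame < 0:
                flipped = (contig, rec)
                break
        assert flipped is not None
        contig, rec = flipped
        query = QueryProhormone(accession="q", sequence=pro.precursor)
        top = translated_search(query, [contig], min_score=50)[0]
        assert top.frame == rec.frame
        assert top.percent_identity == 100.0

    def test_substituted_identity_matches_manifest(self):
        spec = SyntheticSpec(seed=21, substitution_rate=0.1)
        pro = make_prohormone(spec, stream(spec, "prohormone"))
        contig, rec = encode_transcript(pro, spec, stream(spec, "transcript"))
        assert rec.n_substitutions > 0
        query = QueryProhormone(accession="q", sequence=pro.precursor)
        top = translated_search(query, [contig], min_score=50)[0]
        expected = 100.0 * (len(pro.precursor) - rec.n_substitutions) / len(pro.precursor)
        assert top.percent_identity == pytest.approx(expected, abs=1e-9)


class TestSimulatePeaklist:
    def test_noiseless_limit_matches_exactly(self):
        spec = SyntheticSpec(
            seed=5, noise_ppm_sigma=0.0, dropout_probability=0.0, contaminant_count=0
        )
        dataset = generate_dataset(spec)
        result = match_peaks(dataset.peaklist, library_for(dataset))
        assert len(result.unassigned) == 0
        assert all(a.ppm_error == pytest.approx(0.0, abs=1e-9) for a in result.assignments)
        score = score_recovery(result.assignments, dataset.manifest)
        assert score.precision == 1.0 and score.recall == 1.0

    def test_full_dropout_leaves_only_contaminants(self):
        spec = SyntheticSpec(seed=5, dropout_probability=1.0, contaminant_count=4)
        dataset = generate_dataset(spec)
        assert len(dataset.peaklist) == 4
        result = match_peaks(dataset.peaklist, library_for(dataset))
        assert result.assignments == []
        score = score_recovery(result.assignments, dataset.manifest)
        assert score.precision is None and score.recall is None

    def test_contaminants_kept_away_from_library_masses(self):
        spec = SyntheticSpec(seed=9, contaminant_count=30, dropout_probability=0.0)
        dataset = generate_dataset(spec)
        masses = [p.mh for p in dataset.manifest.all_true_peptides()]
        contaminants = [r for r in dataset.manifest.peaks if r.origin == "contaminant"]
        assert len(contaminants) == 30
        for rec in contaminants:
            assert all(abs(rec.mz - m) / m * 1e6 > spec.tolerance_ppm for m in masses)

    def test_noisy_survivors_all_assigned_correctly(self):
        # P(|eps| > 200 ppm) at sigma=20 is ~1e-23: every survivor must match
        for seed in range(100):
            spec = SyntheticSpec(seed=seed, noise_ppm_sigma=20.0)
            dataset = generate_dataset(spec)
            result = match_peaks(dataset.peaklist, library_for(dataset))
            score = score_recovery(result.assignments, dataset.manifest)
            survivors = dataset.manifest.surviving_peptides()
            if survivors:
                assert score.recall == 1.0, f"seed {seed}"
                assert score.precision == 1.0, f"seed {seed}"

    def test_adversarial_decoys_flagged_ambiguous_free(self):
        # decoys at 150 ppm sit inside the 200 ppm window of the true mass
        spec = SyntheticSpec(
            seed=2, noise_ppm_sigma=0.0, dropout_probability=0.0,
            contaminant_count=0, adversarial_decoy_ppm=150.0,
        )
        dataset = generate_dataset(spec)
        result = match_peaks(dataset.peaklist, library_for(dataset))
        assert all(abs(a.ppm_error) <= 200 for a in result.assignments)
        decoy_assignments = [a for a in result.assignments if abs(a.ppm_error) > 100]
        assert decoy_assignments, "decoy peaks should still fall within tolerance"


class TestDeterminism:
    def test_dataset_bit_reproducible(self):
        a = generate_dataset(SyntheticSpec(seed=77))
        b = generate_dataset(SyntheticSpec(seed=77))
        assert a.prohormones == b.prohormones
        assert [c.sequence for c in a.contigs] == [c.sequence for c in b.contigs]
        assert [p.mz for p in a.peaklist.peaks] == [p.mz for p in b.peaklist.peaks]

    def test_named_streams_are_independent(self):
        spec = SyntheticSpec(seed=4)
        a = stream(spec, "prohormone").integers(0, 2**31, size=4).tolist()
        b = stream(spec, "transcript").integers(0, 2**31, size=4).tolist()
        assert a != b
        assert a == stream(spec, "prohormone").integers(0, 2**31, size=4).tolist()


class TestEndToEnd:
    def test_pipeline_reproduces_manifest_presence(self):
        spec = SyntheticSpec(seed=123)
        dataset = generate_dataset(spec)
        # annotate from the contigs, not from the true precursors
        peptides = []
        for pro in dataset.prohormones:
            query = QueryProhormone(accession=pro.prohormone_id, sequence=pro.precursor)
            top = translated_search(query, dataset.contigs, min_score=50)[0]
            contig = next(c for c in dataset.contigs if c.id == top.contig_id)
            from nudipep.homology import extract_candidate_protein

            candidate = extract_candidate_protein(top, contig)
            _, _, peps = process_precursor(
                candidate, family=pro.family, prohormone_id=pro.prohormone_id
            )
            peptides.extend(peps)
        result = match_peaks(dataset.peaklist, build_library(peptides))
        profile = family_profile(result.assignments)
        assert profile.families_present == dataset.manifest.family_presence()
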