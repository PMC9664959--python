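"""Reference mapping, residue calling, family classification, star MSA."""

import math

import numpy as np
import pytest

from pypfam.refmap import (
    call_residues,
    classify_family,
    conservation_profile,
    map_to_reference,
    star_msa,
    write_calls,
)
from pypfam.synthdata import SequenceRecord, SynthConfig, generate_family


class TestMapToReference:
    def test_identity_mapping(self, reference):
        rm = map_to_reference(reference, reference)
        assert rm.reliable
        assert all(
            rm.mapping[p] == reference.residues[p - 1]
            for p in range(1, len(reference.residues) + 1)
        )
        assert rm.insertions == {}

    def test_deletion_shifts_mapping(self, reference):
        mut = SequenceRecord(
            id="del10", residues=reference.residues[:9] + reference.residues[10:]
        )
        rm = map_to_reference(mut, reference)
        assert rm.mapping[10] == "-"
        for p in range(11, 126):
            assert rm.mapping[p] == reference.residues[p - 1]

    def test_insertion_absorbed(self, reference):
        mut = SequenceRecord(
            id="ins20",
            residues=reference.residues[:20] + "AAA" + reference.residues[20:],
        )
        rm = map_to_reference(mut, reference)
        assert all(
            rm.mapping[p] == reference.residues[p - 1] for p in range(1, 126)
        )
        assert rm.insertions == {20: "AAA"}

    def test_unrelated_sequence_flagged_unreliable(self, reference):
        rng = np.random.default_rng(0)
        junk = SequenceRecord(
            id="junk",
            residues="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=125)),
        )
        assert not map_to_reference(junk, reference).reliable


class TestCallResidues:
    def test_reference_call_is_functional_with_no_labels(self, reference):
        rm = map_to_reference(reference, reference)
        call = call_residues(rm, reference)
        assert call.residues_at[42] == "Y"
        assert call.residues_at[46] == "E"
        assert call.residues_at[69] == "C"
        assert call.substitution_labels == []
        assert call.functional

    def test_y42f_labeled_without_affecting_functionality(self, reference):
        res = list(reference.residues)
        res[41] = "F"
        mut = SequenceRecord(id="y42f", residues="".join(res))
        call = call_residues(map_to_reference(mut, reference), reference)
        assert "Y42F" in call.substitution_labels
        assert call.functional

    def test_gap_at_69_reported_and_nonfunctional(self, reference):
        mut = SequenceRecord(
            id="del69", residues=reference.residues[:68] + reference.residues[69:]
        )
        call = call_residues(map_to_reference(mut, reference), reference)
        assert call.residues_at[69] == "-"
        assert "C69-" in call.substitution_labels
        assert not call.functional

    def test_position_outside_reference_rejected(self, reference):
        rm = map_to_reference(reference, reference)
        with pytest.raises(ValueError, match="outside reference"):
            call_residues(rm, reference, positions=[200])

    def test_round_trip_reproduces_reference_residues(self, reference):
        """call(map(reference)) must reproduce the reference exactly at every
        probed position."""
        rm = map_to_reference(reference, reference)
        call = call_residues(rm, reference, positions=list(range(1, 126)))
        assert all(
            call.residues_at[p] == reference.residues[p - 1] for p in range(1, 126)
        )


class TestClassifyFamily:
    def test_all_functional_no_labels(self, reference):
        rm = map_to_reference(reference, reference)
        calls = [call_residues(rm, reference) for _ in range(5)]
        s = classify_family(calls)
        assert s.member_fraction == 1.0
        assert s.triad_conserved_fraction == 1.0
        assert not s.functional_42_46_cooccurrence

    def test_member_fraction_arithmetic(self, reference):
        good = call_residues(map_to_reference(reference, reference), reference)
        res = list(reference.residues)
        res[68] = "S"
        bad_rec = SequenceRecord(id="c69s", residues="".join(res))
        bad = call_residues(map_to_reference(bad_rec, reference), reference)
        s = classify_family([good] * 7 + [bad] * 3)
        assert s.member_fraction == pytest.approx(0.7)
        assert s.label_counts["C69S"] == 3

    def test_planted_substitution_rates_recovered(self, reference):
        cfg = SynthConfig(seed=21)
        fam = generate_family(cfg, "A", 500)
        calls = [
            call_residues(map_to_reference(r, reference_of(cfg), ), reference_of(cfg))
            for r in fam
        ]
        s = classify_family(calls)
        for label, p in (("Y42F", 0.10), ("E46Q", 0.05)):
            se = math.sqrt(p * (1 - p) / 500)
            assert abs(s.label_fractions.get(label, 0.0) - p) < 3 * se

    def test_classification_perfect_against_planted_truth(self):
        """Precision = recall = 1.0 on sequences that are not borderline-
        diverged (global identity >= 0.5 to the reference; below that the
        position map itself is no longer meaningful)."""
        from pypfam.align import global_align

        cfg = SynthConfig(seed=22)
        fam = generate_family(cfg, "A", 200)
        ref = reference_of(cfg)
        scoped = [
            r for r in fam
            if global_align(r.residues, ref.residues).identity >= 0.5
        ]
        assert len(scoped) > 150
        predicted = {
            r.id
            for r in scoped
            if call_residues(map_to_reference(r, ref), ref).functional
        }
        truth = {r.id for r in scoped if r.residues[68] == "C"}
        assert predicted == truth  # precision = recall = 1.0


def reference_of(cfg):
    from pypfam.synthdata import reference_record

    return reference_record(cfg)


class TestStarMSA:
    def test_identical_sequences_give_reference_width(self, reference):
        seqs = [
            SequenceRecord(id=f"s{i}", residues=reference.residues) for i in range(3)
        ]
        msa = star_msa(seqs, reference)
        assert msa.width == len(reference.residues)
        assert msa.ids[0] == reference.id

    def test_single_insertion_makes_one_insert_column(self, reference):
        mut = SequenceRecord(
            id="ins", residues=reference.residues[:30] + "W" + reference.residues[30:]
        )
        msa = star_msa([mut], reference)
        assert msa.width == len(reference.residues) + 1
        ref_row = msa.rows[0]
        ins_col = msa.ref_columns[30] + 1
        assert ref_row[ins_col] == "-"

    def test_nested_indels_match_hand_merge(self, reference):
        # s1 inserts 2 after position 20; s2 inserts 3 at the same slot;
        # s3 deletes position 50. Hand merge: one 3-wide insert block after
        # 20 (left aligned), no other extra columns.
        r = reference.residues
        s1 = SequenceRecord(id="s1", residues=r[:20] + "AA" + r[20:])
        s2 = SequenceRecord(id="s2", residues=r[:20] + "AAA" + r[20:])
        s3 = SequenceRecord(id="s3", residues=r[:49] + r[50:])
        msa = star_msa([s1, s2, s3], reference)
        assert msa.width == 125 + 3
        block = slice(msa.ref_columns[20] + 1, msa.ref_columns[21])
        assert msa.rows[1][block] == "AA-"
        assert msa.rows[2][block] == "AAA"
        assert msa.rows[3][block] == "---"
        assert msa.rows[3][msa.ref_columns[50]] == "-"

    def test_indel_free_rows_equal_raw_sequences(self, config, reference):
        fam = generate_family(config, "A", 10)
        msa = star_msa(fam, reference)
        for rec in fam:
            assert msa.row(rec.id) == rec.residues

    def test_unreliable_sequences_excluded_with_warning(self, reference):
        rng = np.random.default_rng(1)
        junk = SequenceRecord(
            id="junk",
            residues="".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=125)),
        )
        with pytest.warns(UserWarning, match="excluding 'junk'"):
            msa = star_msa([junk], reference)
        assert msa.ids == [reference.id]


class TestConservationProfile:
    def test_frequencies_sum_to_one(self, config, reference):
        fam = generate_family(config, "A", 20)
        msa = star_msa(fam, reference)
        prof = conservation_profile(msa, {r.id: "A" for r in fam})
        assert np.allclose(prof["A"].sum(axis=1), 1.0, atol=1e-12)

    def test_half_half_column(self, reference):
        r = reference.residues
        a = SequenceRecord(id="a", residues=r)
        res = list(r)
        res[68] = "S"
        b = SequenceRecord(id="b", residues="".join(res))
        msa = star_msa([a, b], reference)
        prof = conservation_profile(msa, {"a": "g", "b": "g"})
        assert prof["g"].loc[69, "C"] == pytest.approx(0.5)
        assert prof["g"].loc[69, "S"] == pytest.approx(0.5)

    def test_clade_c_met100_near_fixation(self, reference):
        cfg = SynthConfig(seed=23)
        fam = generate_family(cfg, "C", 60)
        ref = reference_of(cfg)
        msa = star_msa(fam, ref)
        prof = conservation_profile(msa, {r.id: "C" for r in fam})
        assert prof["C"].loc[100, "M"] == 1.0  # motif position, enforced
        # clade C does not constrain 92/96: conservation decays there
        assert prof["C"].loc[92, "F"] < 1.0

    def test_empty_group_rejected(self, config, reference):
        fam = generate_family(config, "A", 5)
        msa = star_msa(fam, reference)
        with pytest.raises(ValueError):
            conservation_profile(msa, {"not_present": "g"})


def test_calls_tsv_written(tmp_path, reference):
    rm = map_to_reference(reference, reference)
    call = call_residues(rm, reference)
    path = tmp_path / "calls.tsv"
    write_calls([call], path)
    lines = path.read_text().splitlines()
    assert lines[0].startswith("id\tresidue@42")
    assert lines[1].split("\t")[-1] == "True"
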