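"""Profile HMM: construction rules, scoring oracles, cutoffs, iteration."""

import numpy as np
import pytest

from conftest import background_probability, enumerate_hmm_paths
from pypfam.align import AA_INDEX
from pypfam.phmm import (
    HmmHit,
    build_hmm,
    forward,
    iterate_build,
    read_hmm,
    search,
    set_cutoffs,
    viterbi,
    write_hmm,
)
from pypfam.refmap import ResidueCall, StarMSA
from pypfam.synthdata import SynthConfig, generate_family, reference_record


def _msa(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    width = len(rows[0])
    return StarMSA(ids=ids, rows=rows, ref_columns={i + 1: i for i in range(width)})


def _random_model(rng, max_match=3):
    L = int(rng.integers(1, max_match + 1))
    nseq = int(rng.integers(2, 5))
    rows = ["".join(rng.choice(list("ACDEFG"), size=L)) for _ in range(nseq)]
    return build_hmm(_msa(rows), pseudocount_weight=float(rng.uniform(0.2, 2.0)))


class TestBuildHmm:
    def test_identical_ungapped_rows_give_indicator_emissions(self):
        h = build_hmm(_msa(["ACD"] * 4), pseudocount_weight=0.0)
        h.validate()
        assert h.n_match == 3
        assert np.allclose(h.emissions_match.max(axis=1), 1.0)
        assert h.t_mm[1] == 1.0  # interior M->M has probability 1

    def test_match_column_occupancy_rule(self):
        # column 1: 3 residues + 1 gap (0.75 >= 0.5 -> match);
        # column 2: 1 residue (0.25 < 0.5 -> insert)
        rows = ["CA", "C-", "C-", "--"]
        h = build_hmm(_msa(rows))
        assert h.n_match == 1

    def test_pseudocount_formula(self):
        h = build_hmm(
            _msa(["C", "C"]),
            pseudocount_weight=1.0,
            background=np.full(20, 0.05),
        )
        assert h.emissions_match[0, AA_INDEX["C"]] == pytest.approx((2 + 0.05) / 3)

    def test_all_gap_msa_rejected(self):
        with pytest.raises(ValueError, match="occupancy"):
            build_hmm(_msa(["--", "--", "--", "--"]))

    def test_normalization_invariants_on_random_builds(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            _random_model(rng).validate()


class TestScoring:
    def test_single_state_model_forward_equals_viterbi(self):
        h = build_hmm(_msa(["C", "C", "C"]), pseudocount_weight=0.0)
        v, path = viterbi(h, "C")
        f = forward(h, "C")
        assert v == pytest.approx(f)
        assert path == [("M", 1)]

    def test_two_state_model_matches_enumerated_paths(self):
        h = build_hmm(_msa(["AC", "AC", "AD"]), pseudocount_weight=0.5)
        seq = "AC"
        x = [AA_INDEX[c] for c in seq]
        total, best = enumerate_hmm_paths(h, x)
        pbg = background_probability(x)
        assert 2 ** forward(h, seq) * pbg == pytest.approx(total, abs=1e-12)
        v, _ = viterbi(h, seq)
        assert 2 ** v * pbg == pytest.approx(best, abs=1e-12)

    def test_consensus_scores_positive(self):
        h = build_hmm(_msa(["ACDEF"] * 6), pseudocount_weight=0.1)
        v, _ = viterbi(h, "ACDEF")
        assert v > 0

    def test_forward_at_least_viterbi_on_random_pairs(self):
        rng = np.random.default_rng(29)
        for _ in range(200):
            h = _random_model(rng)
            seq = "".join(rng.choice(list("ACDEFGHIK"), size=rng.integers(1, 6)))
            f = forward(h, seq)
            v, _ = viterbi(h, seq)
            assert f >= v - 1e-9

    def test_empty_sequence_rejected(self):
        h = build_hmm(_msa(["C", "C"]))
        with pytest.raises(ValueError):
            forward(h, "")
        with pytest.raises(ValueError):
            viterbi(h, "")


class TestSearch:
    def test_no_cutoff_scores_everything(self, config, reference):
        fam = generate_family(config, "A", 10)
        h = build_hmm(_msa([r.residues for r in fam], [r.id for r in fam]))
        hits = search(h, fam)
        assert len(hits) == 10
        scores = [x.bit_score for x in hits]
        assert scores == sorted(scores, reverse=True)

    def test_planted_family_separated_from_decoys(self, config):
        fam = generate_family(config, "A", 30)
        decoys = generate_family(config, "decoy1", 60)
        h = build_hmm(_msa([r.residues for r in fam], [r.id for r in fam]))
        hits = {x.sequence_id: x.bit_score for x in search(h, fam + decoys)}
        worst_fam = min(hits[r.id] for r in fam)
        best_dec = max(hits[r.id] for r in decoys)
        assert worst_fam > best_dec

    def test_empty_db(self):
        h = build_hmm(_msa(["C", "C"]))
        assert search(h, []) == []


def _call(seq_id, functional):
    return ResidueCall(
        sequence_id=seq_id, residues_at={}, substitution_labels=[],
        functional=functional,
    )


class TestSetCutoffs:
    def _hmm(self):
        return build_hmm(_msa(["C", "C"]))

    def test_rule_application(self):
        h = self._hmm()
        hits = [HmmHit("f1", 50.0, frozenset()), HmmHit("f2", 60.0, frozenset()),
                HmmHit("n1", 20.0, frozenset())]
        calls = {"f1": _call("f1", True), "f2": _call("f2", True),
                 "n1": _call("n1", False)}
        cut = set_cutoffs(h, hits, calls)
        assert cut == {"GA": 35.0, "TC": 50.0, "NC": 20.0}
        h.validate()

    def test_no_nonfunctional_defaults_noise_to_zero(self):
        h = self._hmm()
        hits = [HmmHit("f1", 50.0, frozenset())]
        cut = set_cutoffs(h, hits, {"f1": _call("f1", True)})
        assert cut == {"GA": 25.0, "TC": 50.0, "NC": 0.0}

    def test_equal_functional_scores(self):
        h = self._hmm()
        hits = [HmmHit("a", 40.0, frozenset()), HmmHit("b", 40.0, frozenset())]
        calls = {"a": _call("a", True), "b": _call("b", True)}
        cut = set_cutoffs(h, hits, calls)
        assert cut["TC"] == 40.0 and cut["NC"] == 0.0

    def test_no_functional_sequence_is_an_error(self):
        h = self._hmm()
        with pytest.raises(ValueError, match="functional"):
            set_cutoffs(h, [HmmHit("x", 10.0, frozenset())], {"x": _call("x", False)})

    def test_ordering_invariant_on_random_inputs(self):
        rng = np.random.default_rng(31)
        h = self._hmm()
        for _ in range(50):
            n = int(rng.integers(2, 20))
            hits = [HmmHit(f"s{i}", float(rng.normal(0, 50)), frozenset()) for i in range(n)]
            calls = {f"s{i}": _call(f"s{i}", bool(rng.random() < 0.6)) for i in range(n)}
            if not any(c.functional for c in calls.values()):
                calls["s0"] = _call("s0", True)
            cut = set_cutoffs(h, hits, calls)
            assert cut["NC"] <= cut["GA"] <= cut["TC"] or cut["GA"] == cut["TC"]


class TestIterateBuild:
    def test_seeds_only_database_is_a_fixed_point(self):
        cfg = SynthConfig(seed=7, substitution_rates={})  # all seeds functional
        fam = generate_family(cfg, "A", 8)
        ref = reference_record(cfg)
        res = iterate_build(fam, fam, ref, max_rounds=4)
        assert res.converged
        assert res.rounds[-1] == {r.id for r in fam}

    def test_single_round_when_capped(self, config, reference):
        fam = generate_family(config, "A", 8)
        res = iterate_build(fam, fam, reference, max_rounds=1)
        assert len(res.rounds) == 1

    def test_iteration_recall_never_decreases(self, reference):
        cfg = SynthConfig(seed=41, substitution_rates={})
        fam = generate_family(cfg, "A", 40)
        decoys = generate_family(cfg, "decoy1", 40)
        ref = reference_record(cfg)
        res = iterate_build(fam[:6], fam + decoys, ref, max_rounds=4)
        fam_ids = {r.id for r in fam}
        recalls = [len(s & fam_ids) for s in res.rounds]
        assert all(b >= a for a, b in zip(recalls, recalls[1:]))


class TestSerialization:
    def test_write_read_write_is_byte_stable(self, tmp_path, config):
        fam = generate_family(config, "B", 12)
        h = build_hmm(_msa([r.residues for r in fam], [r.id for r in fam]))
        h.cutoffs = {"GA": 12.5, "TC": 20.0, "NC": 5.0}
        p1, p2 = tmp_path / "a.hmm", tmp_path / "b.hmm"
        write_hmm(h, p1)
        h2 = read_hmm(p1)
        write_hmm(h2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert h2.n_match == h.n_match
        assert h2.cutoffs == h.cutoffs

    def test_scores_survive_serialization(self, tmp_path, config):
        fam = generate_family(config, "B", 12)
        h = build_hmm(_msa([r.residues for r in fam], [r.id for r in fam]))
        write_hmm(h, tmp_path / "m.hmm")
        h2 = read_hmm(tmp_path / "m.hmm")
        seq = fam[0].residues
        assert forward(h2, seq) == pytest.approx(forward(h, seq), abs=0.05)
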