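import random

import pytest

from rxnaug.evaluation import (
    BeamSet,
    evaluate,
    invalid_rate,
    match_prediction,
    per_class_report,
    read_nbest,
    topk_accuracy,
)
from rxnaug.smiles_engine import parse, random_smiles, write
from rxnaug.toy_data import ToyDatasetConfig, gen_dataset


def beam(*cands, width=10, sid=0):
    return BeamSet(source_id=sid, candidates=list(cands), beam_width=width)


class TestMatchPrediction:
    def test_alternative_writing_matches(self):
        assert match_prediction("OCC", "CCO")

    def test_component_order_invariant(self):
        assert match_prediction("CC.O", "O.CC")

    def test_invalid_prediction_is_mismatch(self):
        assert not match_prediction("C1CC", "CCO")
        assert not match_prediction("", "CCO")

    def test_invalid_reference_raises(self):
        with pytest.raises(ValueError):
            match_prediction("CCO", "C1CC")

    def test_different_molecule_no_match(self):
        assert not match_prediction("CCN", "CCO")

    def test_component_multiset_counts(self):
        assert match_prediction("C.C.O", "O.C.C")
        assert not match_prediction("C.O", "C.C.O")


class TestTopkAccuracy:
    def test_all_rank_one_correct(self):
        beams = [beam("CCO"), beam("OCC")]
        assert topk_accuracy(beams, ["CCO", "CCO"], 1) == 1.0

    def test_worked_example_ranks(self):
        # first match at ranks 1, 2, 3, never
        beams = [
            beam("CCO", "C", "C"),
            beam("C", "CCO", "C"),
            beam("C", "C", "CCO"),
            beam("C", "C", "C"),
        ]
        refs = ["CCO"] * 4
        assert topk_accuracy(beams, refs, 1) == 0.25
        assert topk_accuracy(beams, refs, 3) == 0.75
        assert topk_accuracy(beams, refs, 5) == 0.75

    def test_monotone_in_k(self):
        rng = random.Random(0)
        records = gen_dataset(ToyDatasetConfig(n_reactions=30, seed=2))
        refs, beams = [], []
        for i, rec in enumerate(records):
            ref = ".".join(rec.reactants)
            refs.append(ref)
            cands = [random_smiles(parse(ref)[0], rng.randrange(10**6))
                     if rng.random() < 0.5 else "C" for _ in range(10)]
            beams.append(BeamSet(source_id=i, candidates=cands, beam_width=10))
        accs = [topk_accuracy(beams, refs, k) for k in (1, 3, 5, 10)]
        assert accs == sorted(accs)

    def test_misaligned_raises(self):
        with pytest.raises(ValueError):
            topk_accuracy([beam("C")], ["C", "C"], 1)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            topk_accuracy([], [], 1)

    def test_k_exceeding_beam_raises(self):
        with pytest.raises(ValueError):
            topk_accuracy([beam("C", width=3)], ["C"], 5)


class TestInvalidRate:
    def test_all_valid(self):
        beams = [beam("CCO", "OCC"), beam("C", "N")]
        for k in (1, 2):
            assert invalid_rate(beams, k) == 0.0

    def test_one_in_four_at_rank_one(self):
        beams = [beam("CCO"), beam("C1CC"), beam("C"), beam("O")]
        assert invalid_rate(beams, 1) == 0.25

    def test_pooled_denominator(self):
        beams = [beam("C", "C1CC"), beam("C", "C(C")]
        # 4 pooled candidates at k=2, 2 invalid
        assert invalid_rate(beams, 2) == 0.5

    def test_per_source_variant(self):
        beams = [beam("C", "C1CC"), beam("C", "C")]
        assert invalid_rate(beams, 2, per_source=True) == 0.5

    def test_strict_valence_flag(self):
        beams = [beam("C(C)(C)(C)(C)C")]
        assert invalid_rate(beams, 1) == 0.0
        assert invalid_rate(beams, 1, strict_valence=True) == 1.0

    def test_duplicates_scored_as_is(self):
        beams = [beam("C1CC", "C1CC", "C")]
        assert invalid_rate(beams, 3) == pytest.approx(2 / 3)


class TestPerClass:
    def test_single_class_equals_global(self):
        beams = [beam("CCO"), beam("C")]
        refs = ["CCO", "CCO"]
        rep = per_class_report(beams, refs, ["Rx_1", "Rx_1"])
        assert set(rep) == {"Rx_1"}
        assert rep["Rx_1"]["top_1_accuracy"] == topk_accuracy(beams, refs, 1)

    def test_weighted_mean_equals_global(self):
        rng = random.Random(3)
        records = gen_dataset(ToyDatasetConfig(n_reactions=80, seed=3))
        beams, refs, classes = [], [], []
        for i, rec in enumerate(records):
            ref = ".".join(rec.reactants)
            refs.append(ref)
            classes.append(rec.rx_class)
            good = rng.random() < 0.6
            cand = (random_smiles(parse(ref)[0], rng.randrange(10**6))
                    if good else "N")
            beams.append(BeamSet(source_id=i, candidates=[cand], beam_width=1))
        rep = per_class_report(beams, refs, classes)
        total = sum(row["n"] for row in rep.values())
        weighted = sum(row["n"] * row["top_1_accuracy"] for row in rep.values()) / total
        assert weighted == pytest.approx(topk_accuracy(beams, refs, 1))

    def test_empty_class_absent(self):
        rep = per_class_report([beam("C")], ["C"], ["Rx_2"])
        assert "Rx_1" not in rep


class TestEvaluateAndIO:
    def test_report_shape(self):
        beams = [beam("CCO", "C", "N"), beam("N", "OCC", "C")]
        rep = evaluate(beams, ["CCO", "CCO"], classes=["Rx_1", "Rx_2"],
                       ks=(1, 3, 5, 10))
        assert set(rep.top_k_accuracy) == {1, 3, 5, 10}
        assert rep.top_k_accuracy[1] == 0.5
        assert rep.top_k_accuracy[3] == 1.0
        assert rep.n_evaluated == 2
        assert set(rep.per_class) == {"Rx_1", "Rx_2"}
        assert "top-k" in rep.to_table()
        assert "top_k_accuracy" in rep.to_json()

    def test_read_nbest_layout(self, tmp_path):
        p = tmp_path / "preds.txt"
        p.write_text("C C O\nO C C\nN\nC\n")
        beams = read_nbest(p, beam_width=2)
        assert len(beams) == 2
        assert beams[0].candidates == ["CCO", "OCC"]
        assert beams[1].candidates == ["N", "C"]

    def test_read_nbest_bad_multiple(self, tmp_path):
        p = tmp_path / "preds.txt"
        p.write_text("C\nC\nC\n")
        with pytest.raises(ValueError):
            read_nbest(p, beam_width=2)

    def test_oracle_random_rewritings_perfect(self):
        # end-to-end canonicalization correctness: beams built from write()
        # under random atom orders must score top-1 = 1.0, invalid = 0
        rng = random.Random(9)
        records = gen_dataset(ToyDatasetConfig(n_reactions=40, seed=6))
        beams, refs = [], []
        for i, rec in enumerate(records):
            ref = ".".join(rec.reactants)
            refs.append(ref)
            cands = [".".join(random_smiles(c, rng.randrange(10**6))
                              for c in parse(ref)) for _ in range(3)]
            beams.append(BeamSet(source_id=i, candidates=cands, beam_width=3))
        rep = evaluate(beams, refs, ks=(1, 3))
        assert rep.top_k_accuracy[1] == 1.0
        assert rep.invalid_rate[1] == 0.0
        assert rep.invalid_rate[3] == 0.0
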