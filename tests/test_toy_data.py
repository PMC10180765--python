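import random
from collections import Counter

import numpy as np
import pytest

from rxnaug.evaluation import topk_accuracy
from rxnaug.normalization import char_normalize, denormalize
from rxnaug.reaction_io import TaskSpec, make_src_tgt
from rxnaug.smiles_engine import canonical, is_valid, parse, write
from rxnaug.toy_data import (
    TEMPLATES,
    TemplateMatchError,
    ToyDatasetConfig,
    apply_template,
    gen_dataset,
    gen_molecule,
    retrieval_predict,
    retrieval_predict_batch,
    token_edit_distance,
)
from rxnaug.toy_data import _batch_distances, _encode


class TestGenMolecule:
    def test_single_atom(self):
        mol = gen_molecule(1, 0)
        assert mol.n_atoms == 1

    def test_requested_size(self):
        for size in (2, 5, 9):
            assert gen_molecule(size, 1).n_atoms == size

    def test_strict_valence_valid_draws(self):
        rng = random.Random(2)
        for _ in range(400):
            mol = gen_molecule(rng.randint(1, 10), rng)
            s = write(mol, 0)
            ok, diag = is_valid(s, strict_valence=True)
            assert ok, (s, diag)

    def test_no_aromatics_no_stereo(self):
        rng = random.Random(3)
        for _ in range(50):
            mol = gen_molecule(rng.randint(2, 8), rng)
            assert not any(a.aromatic or a.chirality for a in mol.atoms)

    def test_acyclic_or_monocyclic(self):
        rng = random.Random(4)
        for _ in range(100):
            mol = gen_molecule(rng.randint(3, 9), rng)
            assert len(mol.bonds) - mol.n_atoms + 1 in (0, 1)

    def test_deterministic(self):
        assert write(gen_molecule(7, 42), 0) == write(gen_molecule(7, 42), 0)

    def test_bad_size(self):
        with pytest.raises(ValueError):
            gen_molecule(0, 0)


class TestTemplates:
    def test_esterification_worked_example(self):
        rec = apply_template(TEMPLATES["Rx_2"], ["CCO", "CC(=O)Cl"])
        assert canonical(rec.products[0]) == canonical("CC(=O)OCC")
        assert rec.products[1] == "Cl"
        assert rec.rx_class == "Rx_2"

    def test_substitution(self):
        rec = apply_template(TEMPLATES["Rx_1"], ["CCBr", "CN"])
        assert canonical(rec.products[0]) == canonical("CCNC")
        assert rec.products[1] == "Br"

    def test_deprotection(self):
        rec = apply_template(TEMPLATES["Rx_6"], ["CCOC"])
        assert canonical(rec.products[0]) == canonical("CCO")
        assert rec.products[1] == "C"

    def test_no_match_raises(self):
        with pytest.raises(TemplateMatchError):
            apply_template(TEMPLATES["Rx_2"], ["CC", "CC"])

    def test_byproducts_droppable(self):
        rec = apply_template(TEMPLATES["Rx_2"], ["CCO", "CC(=O)Cl"],
                             keep_byproducts=False)
        assert len(rec.products) == 1

    def test_rewrites_always_strict_valid(self):
        rng = random.Random(7)
        templates = list(TEMPLATES.values())
        for i in range(300):
            t = templates[i % len(templates)]
            reactants = t.builder(rng, (2, 7))
            rec = apply_template(t, reactants)
            for s in rec.products:
                ok, diag = is_valid(s, strict_valence=True)
                assert ok, (t.name, reactants, s, diag)


class TestGenDataset:
    def test_count_and_validity(self):
        records = gen_dataset(ToyDatasetConfig(n_reactions=10, seed=0))
        assert len(records) == 10
        for rec in records:
            rec.validate()
            assert len(rec.products) == 1

    def test_multinomial_class_counts(self):
        n = 1000
        weights = {"Rx_1": 0.6, "Rx_2": 0.3, "Rx_6": 0.1}
        records = gen_dataset(ToyDatasetConfig(
            n_reactions=n, seed=1, class_weights=weights))
        counts = Counter(r.rx_class for r in records)
        for c, w in weights.items():
            sigma = (n * w * (1 - w)) ** 0.5
            assert abs(counts[c] - n * w) <= 3 * sigma, (c, counts[c])

    def test_deterministic(self):
        cfg = ToyDatasetConfig(n_reactions=30, seed=9)
        a = [r.to_line(True) for r in gen_dataset(cfg)]
        b = [r.to_line(True) for r in gen_dataset(cfg)]
        assert a == b

    def test_missing_template_rejected(self):
        with pytest.raises(ValueError, match="template"):
            gen_dataset(ToyDatasetConfig(
                n_reactions=5, class_weights={"Rx_9": 1.0}))

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError):
            ToyDatasetConfig(class_weights={"Rx_1": 0.5})

    def test_pipeline_round_trip(self, tmp_path):
        from rxnaug.reaction_io import read_rsmi, write_rsmi

        records = gen_dataset(ToyDatasetConfig(n_reactions=20, seed=13))
        p = tmp_path / "d.rsmi"
        write_rsmi(records, p, with_class=True)
        back = read_rsmi(p, with_class=True)
        src, tgt = make_src_tgt(back, TaskSpec(task="retro_with_class"))
        for s, t in zip(src, tgt):
            assert denormalize(char_normalize(s)) == s
            assert denormalize(char_normalize(t)) == t


class TestRetrieval:
    train_src = ["CCO", "CCCC", "CNC", "C1CC1"]
    train_tgt = ["O", "N", "S", "P"]

    def test_exact_query_rank_one(self):
        b = retrieval_predict(self.train_src, self.train_tgt, "CNC", 2)
        assert b.candidates[0] == "S"

    def test_fewer_training_pairs_than_beam(self):
        b = retrieval_predict(self.train_src, self.train_tgt, "C", 10)
        assert len(b.candidates) == 4

    def test_matches_bruteforce_ordering(self):
        rng = random.Random(1)
        records = gen_dataset(ToyDatasetConfig(n_reactions=60, seed=3))
        src, tgt = make_src_tgt(records, TaskSpec(task="retro"))
        queries = src[:8]
        beams = retrieval_predict_batch(src, tgt, queries, 5)
        for q, b in zip(queries, beams):
            qt = char_normalize(q).tokens
            dists = [token_edit_distance(qt, char_normalize(s).tokens)
                     for s in src]
            order = sorted(range(len(src)), key=lambda i: (dists[i], i))[:5]
            assert b.candidates == [tgt[i] for i in order]

    def test_vectorized_distance_equals_reference(self):
        rng = random.Random(5)
        strings = [write(gen_molecule(rng.randint(1, 8), rng), 0)
                   for _ in range(30)]
        ids = _encode(strings)
        for qi in (0, 7, 29):
            dists = _batch_distances(ids[:20], ids[qi])
            expect = [token_edit_distance(
                char_normalize(strings[qi]).tokens,
                char_normalize(s).tokens) for s in strings[:20]]
            assert dists.tolist() == expect

    def test_bad_beam_width(self):
        with pytest.raises(ValueError):
            retrieval_predict(self.train_src, self.train_tgt, "C", 0)

    def test_empty_training(self):
        with pytest.raises(ValueError):
            retrieval_predict([], [], "C", 1)


def test_augmentation_helps_randomized_queries():
    """Directional property: retrieval trained on 10-level augmented data is
    at least as accurate on randomized-SMILES queries as on 1-level data."""
    from rxnaug.augmentation import AugmentationConfig, augment_dataset
    from rxnaug.reaction_io import split_train_test
    from rxnaug.smiles_engine import random_smiles

    def run(seed, level):
        ds = gen_dataset(ToyDatasetConfig(n_reactions=300, seed=seed,
                                          mol_size_range=(2, 4)))
        train, test = split_train_test(ds, 0.1, seed)
        aug = augment_dataset(train, AugmentationConfig(
            level_n=level, seed=seed, source_side="products"))
        src, tgt = make_src_tgt(aug, TaskSpec(task="retro"))
        qsrc, qtgt = make_src_tgt(test, TaskSpec(task="retro"))
        rng = random.Random(seed + 999)
        queries = [".".join(random_smiles(c, rng) for c in parse(s))
                   for s in qsrc]
        beams = retrieval_predict_batch(src, tgt, queries, 5)
        return topk_accuracy(beams, qtgt, 1)

    seeds = range(3)
    acc1 = np.mean([run(s, 1) for s in seeds])
    acc10 = np.mean([run(s, 10) for s in seeds])
    assert acc10 >= acc1
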