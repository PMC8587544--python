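import math

import numpy as np
import pytest
from rdkit import Chem

from vscreen.chem_data import record_to_mol
from vscreen.deep_models import (
    ClassifierConfig,
    ConfusionCounts,
    TrainingError,
    auc_score,
    batch_size_sweep,
    classify,
    confusion,
    load_classifier,
    metrics,
    predict,
    save_classifier,
    train_dense_classifier,
    train_nfp_classifier,
    write_sweep_tsv,
)
from vscreen.fingerprints import BitFingerprint, encode_graph
from vscreen.synthetic import make_fingerprint_dataset, make_motif_library

FAST = ClassifierConfig(
    hidden_widths=(64,), epochs=60, early_stop_patience=10, batch_size=50, seed=0
)


def split_pairs(pairs, n_train):
    return pairs[:n_train], pairs[n_train:]


@pytest.fixture(scope="module")
def dense_classifier(fingerprint_dataset):
    train, test = split_pairs(fingerprint_dataset.pairs, 700)
    return train_dense_classifier(train, test, FAST), test


@pytest.fixture(scope="module")
def graph_pairs(motif_library):
    pairs = []
    for rec in motif_library:
        mol = record_to_mol(rec, with_conformers=False)
        pairs.append((encode_graph(mol), int(rec.label == "active")))
    rng = np.random.default_rng(0)
    idx = rng.permutation(len(pairs))
    return [pairs[i] for i in idx]


class TestTrainDenseClassifier:
    def test_separable_data_high_auc(self, dense_classifier):
        clf, test = dense_classifier
        p = predict(clf, [fp for fp, _ in test])
        assert auc_score([y for _, y in test], p) >= 0.99

    def test_null_labels_near_chance(self, fingerprint_dataset):
        aucs = []
        for seed in range(3):
            rng = np.random.default_rng(seed + 100)
            null = [(fp, int(rng.random() < 0.5)) for fp, _ in fingerprint_dataset.pairs[:600]]
            train, test = split_pairs(null, 400)
            cfg = ClassifierConfig(
                hidden_widths=(32,), epochs=25, early_stop_patience=5,
                batch_size=100, seed=seed,
            )
            clf = train_dense_classifier(train, test, cfg)
            p = predict(clf, [fp for fp, _ in test])
            aucs.append(auc_score([y for _, y in test], p))
        assert all(0.35 <= a <= 0.65 for a in aucs)

    def test_paper_default_batch_size_accepted(self, fingerprint_dataset):
        train, test = split_pairs(fingerprint_dataset.pairs[:400], 300)
        cfg = ClassifierConfig(
            hidden_widths=(32,), epochs=5, early_stop_patience=5, batch_size=300
        )
        clf = train_dense_classifier(train, test, cfg)
        assert clf.config.batch_size == 300
        assert clf.history["batch_size"] == 300

    def test_single_class_raises(self, fingerprint_dataset):
        ones = [(fp, 1) for fp, _ in fingerprint_dataset.pairs[:50]]
        with pytest.raises(TrainingError):
            train_dense_classifier(ones, ones, FAST)

    def test_deterministic_for_fixed_seed(self, fingerprint_dataset):
        train, test = split_pairs(fingerprint_dataset.pairs[:300], 200)
        cfg = ClassifierConfig(hidden_widths=(16,), epochs=5, batch_size=50, seed=7)
        a = train_dense_classifier(train, test, cfg)
        b = train_dense_classifier(train, test, cfg)
        pa = predict(a, [fp for fp, _ in test])
        pb = predict(b, [fp for fp, _ in test])
        assert np.array_equal(pa, pb)


class TestTrainNfpClassifier:
    def test_motif_recovery_high_auc(self, graph_pairs):
        train, test = split_pairs(graph_pairs, 280)
        cfg = ClassifierConfig(
            hidden_widths=(64,), epochs=100, early_stop_patience=15,
            batch_size=50, seed=0,
        )
        clf = train_nfp_classifier(train, test, cfg)
        p = predict(clf, [g for g, _ in test])
        # oracle: motif presence/absence is a perfect classifier by construction
        assert auc_score([y for _, y in test], p) >= 0.95

    def test_atom_permutation_invariance(self, graph_pairs):
        train, test = split_pairs(graph_pairs, 280)
        clf = train_nfp_classifier(train, test, FAST)
        smiles = "CCOc1ccccc1S(N)(=O)=O"
        mol = Chem.MolFromSmiles(smiles)
        perm = list(reversed(range(mol.GetNumAtoms())))
        permuted = Chem.RenumberAtoms(mol, perm)
        p1 = predict(clf, [encode_graph(mol)])[0]
        p2 = predict(clf, [encode_graph(permuted)])[0]
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_paper_default_batch_size_accepted(self, graph_pairs):
        train, test = split_pairs(graph_pairs, 360)
        cfg = ClassifierConfig(
            hidden_widths=(32,), epochs=5, early_stop_patience=5, batch_size=350
        )
        clf = train_nfp_classifier(train, test, cfg)
        assert clf.config.batch_size == 350


class TestPredict:
    def test_empty_input(self, dense_classifier):
        clf, _ = dense_classifier
        assert predict(clf, []).shape == (0,)

    def test_repeated_item_identical(self, dense_classifier):
        clf, test = dense_classifier
        fp = test[0][0]
        p = predict(clf, [fp, fp, fp])
        assert p[0] == p[1] == p[2]

    def test_probabilities_in_unit_interval(self, dense_classifier):
        clf, test = dense_classifier
        p = predict(clf, [fp for fp, _ in test])
        assert np.all((0.0 <= p) & (p <= 1.0))

    def test_classify_matches_thresholding(self, dense_classifier):
        clf, test = dense_classifier
        items = [fp for fp, _ in test[:50]]
        p = predict(clf, items)
        assert np.array_equal(classify(clf, items), (p >= 0.5).astype(int))

    def test_architecture_mismatch(self, dense_classifier):
        clf, _ = dense_classifier
        with pytest.raises((TypeError, ValueError)):
            predict(clf, [encode_graph("CCO")])


class TestConfusion:
    def test_all_correct(self):
        c = confusion([1] * 5 + [0] * 5, [1] * 5 + [0] * 5)
        assert (c.TP, c.TN, c.FP, c.FN) == (5, 5, 0, 0)

    def test_all_flipped(self):
        c = confusion([1] * 5 + [0] * 5, [0] * 5 + [1] * 5)
        assert (c.TP, c.TN) == (0, 0)
        assert (c.FN, c.FP) == (5, 5)

    def test_matches_hand_enumeration(self):
        labels = [1, 0, 1, 1, 0, 0, 1]
        preds = [1, 1, 0, 1, 0, 1, 1]
        c = confusion(labels, preds)
        tp = fn = tn = fp = 0
        for y, p in zip(labels, preds):
            if y == 1 and p == 1:
                tp += 1
            elif y == 1:
                fn += 1
            elif p == 0:
                tn += 1
            else:
                fp += 1
        assert (c.TP, c.FN, c.TN, c.FP) == (tp, fn, tn, fp)
        assert c.total == len(labels)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        rep = metrics(
            ConfusionCounts(TP=5, FN=0, TN=5, FP=0),
            scores=[0.9] * 5 + [0.1] * 5,
            labels=[1] * 5 + [0] * 5,
        )
        assert (rep.SE, rep.SP, rep.Qplus, rep.Qminus, rep.MCC, rep.AUC) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_worked_example(self):
        # oracle: direct evaluation of the defining ratio formulas
        rep = metrics(ConfusionCounts(TP=50, FN=5, TN=40, FP=10))
        assert rep.SE == pytest.approx(50 / 55)
        assert rep.SP == pytest.approx(40 / 50)
        assert rep.Qplus == pytest.approx(50 / 60)
        assert rep.Qminus == pytest.approx(40 / 45)
        assert rep.MCC == pytest.approx(
            (50 * 40 - 5 * 10) / math.sqrt(55 * 60 * 45 * 50)
        )

    def test_degenerate_denominators_flagged(self):
        rep = metrics(ConfusionCounts(TP=10, FN=0, TN=0, FP=5))
        assert rep.SP == 0.0
        assert math.isnan(rep.Qminus)  # TN + FN = 0
        assert math.isnan(metrics(ConfusionCounts(TP=0, FN=0, TN=3, FP=2)).SE)

    def test_mcc_label_flip_antisymmetry(self, rng):
        for _ in range(50):
            tp, fn, tn, fp = (int(x) for x in rng.integers(0, 40, size=4))
            m1 = metrics(ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp)).MCC
            m2 = metrics(ConfusionCounts(TP=fn, FN=tp, TN=fp, FP=tn)).MCC
            if math.isnan(m1):
                assert math.isnan(m2)
            else:
                assert m1 == pytest.approx(-m2)
                assert -1.0 <= m1 <= 1.0

    def test_se_sp_recover_counts(self, rng):
        for _ in range(20):
            tp, fn, tn, fp = (int(x) for x in rng.integers(1, 50, size=4))
            rep = metrics(ConfusionCounts(TP=tp, FN=fn, TN=tn, FP=fp))
            assert rep.SE * (tp + fn) == pytest.approx(tp)
            assert rep.SP * (tn + fp) == pytest.approx(tn)


class TestAucScore:
    def test_matches_pair_counting_exhaustive(self):
        # all ≤8-item label arrangements with distinct scores
        import itertools

        for n in range(2, 9):
            scores = [float(n - i) for i in range(n)]
            for flags in itertools.product([0, 1], repeat=n):
                if sum(flags) in (0, n):
                    continue
                got = auc_score(list(flags), scores)
                pos = [s for s, f in zip(scores, flags) if f]
                neg = [s for s, f in zip(scores, flags) if not f]
                wins = sum(
                    1.0 if p > q else 0.5 if p == q else 0.0
                    for p in pos for q in neg
                )
                assert got == pytest.approx(wins / (len(pos) * len(neg)))


class TestBatchSizeSweep:
    def test_single_size(self, fingerprint_dataset):
        train, test = split_pairs(fingerprint_dataset.pairs[:400], 300)
        cfg = ClassifierConfig(hidden_widths=(32,), epochs=5, batch_size=50)
        rows, best = batch_size_sweep(train, test, [50], base_config=cfg)
        assert len(rows) == 1 and best == 0
        assert rows[0].model == "Model_D1"

    def test_two_sizes_both_separate(self, fingerprint_dataset):
        train, test = split_pairs(fingerprint_dataset.pairs, 700)
        cfg = ClassifierConfig(hidden_widths=(64,), epochs=150, early_stop_patience=25)
        rows, best = batch_size_sweep(train, test, [50, 100], base_config=cfg)
        assert all(row.report.AUC >= 0.99 for row in rows)
        assert rows[best].report.AUC == max(r.report.AUC for r in rows)

    def test_seven_row_table_and_tsv(self, fingerprint_dataset, tmp_path):
        train, test = split_pairs(fingerprint_dataset.pairs[:420], 350)
        cfg = ClassifierConfig(hidden_widths=(16,), epochs=2, batch_size=50)
        sizes = list(range(50, 351, 50))
        rows, _ = batch_size_sweep(train, test, sizes, base_config=cfg)
        assert [r.batch_size for r in rows] == sizes
        assert [r.model for r in rows] == [f"Model_D{i}" for i in range(1, 8)]
        out = tmp_path / "sweep.tsv"
        write_sweep_tsv(out, rows)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == [
            "model", "batch_size", "SE", "SP", "Q+", "Q-", "MCC", "AUC",
        ]
        assert len(lines) == 8

    def test_empty_sizes(self, fingerprint_dataset):
        train, test = split_pairs(fingerprint_dataset.pairs[:100], 80)
        with pytest.raises(ValueError):
            batch_size_sweep(train, test, [])


class TestCheckpointing:
    def test_dense_round_trip(self, dense_classifier, tmp_path):
        clf, test = dense_classifier
        path = tmp_path / "model.json"
        save_classifier(clf, path)
        back = load_classifier(path)
        items = [fp for fp, _ in test[:20]]
        assert np.allclose(predict(back, items), predict(clf, items))
        assert back.config == clf.config

    def test_nfp_round_trip(self, graph_pairs, tmp_path):
        train, test = split_pairs(graph_pairs[:200], 150)
        clf = train_nfp_classifier(train, test, FAST)
        path = tmp_path / "model.json"
        save_classifier(clf, path)
        back = load_classifier(path)
        items = [g for g, _ in test[:10]]
        assert np.allclose(predict(back, items), predict(clf, items))
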