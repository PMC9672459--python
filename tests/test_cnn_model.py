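import numpy as np
import pytest

from phageprom import CNNConfig, DataError, build_model, sigmoid
from phageprom.cnn_model import Conv1D, Dense, Dropout, Flatten, MaxPool1D, PromoterCNN


def motif_vs_scrambled(n_per_class=60, seed=0):
    """Fully scrambled negatives: a cleanly separable toy problem."""
    rng = np.random.default_rng(seed)
    X, y = [], []
    motif = list("TATAATGCGCGC")
    for i in range(n_per_class):
        seq = rng.choice(list("ACGT"), size=99)
        seq[40:52] = motif
        X.append(seq.copy())
        y.append(1)
        rng.shuffle(seq)
        X.append(seq)
        y.append(0)
    onehot = {"A": 0, "C": 1, "G": 2, "T": 3}
    M = np.zeros((len(X), 99, 4))
    for i, seq in enumerate(X):
        for j, b in enumerate(seq):
            M[i, j, onehot[b]] = 1
    return M, np.array(y)


class TestSigmoid:
    def test_zero_maps_to_half(self):
        assert sigmoid(0.0) == pytest.approx(0.5)

    @pytest.mark.parametrize("p", [-3.0, -1.0, 2.0, 10.0])
    def test_symmetry_identity(self, p):
        assert sigmoid(p) + sigmoid(-p) == pytest.approx(1.0)

    def test_value_at_two(self):
        assert sigmoid(2.0) == pytest.approx(0.880797, abs=1e-6)

    def test_stable_for_extreme_logits(self):
        assert sigmoid(1000.0) == pytest.approx(1.0)
        assert sigmoid(-1000.0) == pytest.approx(0.0)


class TestBuildModel:
    def test_first_conv_parameter_count(self):
        m = build_model(CNNConfig(), (99, 4))
        # filters x (kernel x channels) + bias
        assert m.layers[0].n_params == 16 * (5 * 4) + 16 == 336

    def test_layer_sequence_matches_architecture(self):
        m = build_model(CNNConfig(), (99, 4))
        kinds = [type(l).__name__ for l in m.layers]
        assert kinds == [
            "Conv1D", "MaxPool1D", "Dropout",
            "Conv1D", "MaxPool1D", "Dropout",
            "Flatten", "Dense", "Dropout", "Dense",
        ]
        assert sum(k == "Conv1D" for k in kinds) == 2
        assert sum(k == "Dropout" for k in kinds) == 3

    def test_dense_head_configuration(self):
        m = build_model(CNNConfig(), (99, 4))
        dense = [l for l in m.layers if isinstance(l, Dense)]
        assert dense[0].W.shape[1] == 64 and dense[0].activation == "relu"
        assert dense[1].W.shape[1] == 1 and dense[1].activation == "sigmoid"

    def test_rejects_non_99_row_input(self):
        with pytest.raises(DataError, match="99"):
            build_model(CNNConfig(), (64, 4))

    def test_invalid_config_lists_fields(self):
        with pytest.raises(DataError, match="dropout"):
            CNNConfig(dropout=1.5)

    def test_channel_count_follows_encoding(self):
        m = build_model(CNNConfig(), (99, 3))
        assert m.layers[0].W.shape == (5 * 3, 16)


class TestTraining:
    def test_overfits_separable_toy(self):
        X, y = motif_vs_scrambled(n_per_class=100)
        cfg = CNNConfig(epochs=30, seed=1)
        m = PromoterCNN(cfg, (99, 4)).fit(X, y)
        train_acc = np.mean(m.predict(X) == y)
        assert train_acc >= 0.99

    def test_log_has_one_entry_per_epoch(self):
        X, y = motif_vs_scrambled(n_per_class=20)
        cfg = CNNConfig(epochs=7, seed=2)
        m = PromoterCNN(cfg, (99, 4)).fit(X, y)
        assert len(m.training_log) == 7
        assert [e["epoch"] for e in m.training_log] == list(range(1, 8))

    def test_seeded_training_reproducible(self):
        X, y = motif_vs_scrambled(n_per_class=20)
        losses = []
        for _ in range(2):
            m = PromoterCNN(CNNConfig(epochs=5, seed=3), (99, 4)).fit(X, y)
            losses.append(m.training_log[-1]["loss"])
        assert losses[0] == pytest.approx(losses[1], abs=1e-6)

    def test_loss_mostly_decreasing_on_separable_toy(self):
        X, y = motif_vs_scrambled(n_per_class=50)
        cfg = CNNConfig(epochs=40, dropout=0.0, seed=4)
        m = PromoterCNN(cfg, (99, 4)).fit(X, y)
        losses = [e["loss"] for e in m.training_log]
        upticks = sum(b > a for a, b in zip(losses, losses[1:]))
        assert upticks <= 0.05 * len(losses) + 1
        assert losses[-1] < losses[0]

    def test_single_class_rejected(self):
        X, _ = motif_vs_scrambled(n_per_class=5)
        with pytest.raises(DataError, match="single class"):
            PromoterCNN(CNNConfig(epochs=1, seed=0), (99, 4)).fit(
                X, np.ones(len(X))
            )

    def test_label_length_mismatch(self):
        X, y = motif_vs_scrambled(n_per_class=5)
        with pytest.raises(DataError):
            PromoterCNN(CNNConfig(epochs=1, seed=0), (99, 4)).fit(X, y[:-1])


@pytest.fixture(scope="module")
def trained():
    X, y = motif_vs_scrambled(n_per_class=30)
    return PromoterCNN(CNNConfig(epochs=10, seed=5), (99, 4)).fit(X, y), X, y


class TestPredict:

    def test_probabilities_in_unit_interval(self, trained, rng):
        m, X, _ = trained
        p = m.predict_proba(X)
        assert p.shape == (len(X),)
        assert np.all((p >= 0) & (p <= 1))

    def test_order_preserved(self, trained):
        m, X, _ = trained
        p_all = m.predict_proba(X)
        p_rev = m.predict_proba(X[::-1])
        np.testing.assert_allclose(p_all[::-1], p_rev, atol=1e-12)

    def test_shape_mismatch_rejected(self, trained, rng):
        m, _, _ = trained
        with pytest.raises(DataError, match="incompatible"):
            m.predict_proba(rng.random((3, 99, 3)))


class TestPersistence:
    def test_save_load_round_trip(self, tmp_path):
        X, y = motif_vs_scrambled(n_per_class=10)
        m = PromoterCNN(CNNConfig(epochs=2, seed=6), (99, 4)).fit(X, y)
        path = tmp_path / "model.ppm"
        m.save(path)
        m2 = PromoterCNN.load(path)
        np.testing.assert_array_equal(m.predict_proba(X), m2.predict_proba(X))
        assert m2.config == m.config
        assert m2.training_log == m.training_log

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "bad.ppm"
        path.write_bytes(b"not a model")
        with pytest.raises(DataError, match="corrupt"):
            PromoterCNN.load(path)

    def test_schema_version_checked(self, tmp_path):
        import json
        import zipfile

        X, y = motif_vs_scrambled(n_per_class=5)
        m = PromoterCNN(CNNConfig(epochs=1, seed=7), (99, 4)).fit(X, y)
        good = tmp_path / "good.ppm"
        m.save(good)
        bad = tmp_path / "bad.ppm"
        with zipfile.ZipFile(good) as zin, zipfile.ZipFile(bad, "w") as zout:
            meta = json.loads(zin.read("config.json"))
            meta["schema_version"] = 999
            zout.writestr("config.json", json.dumps(meta))
            zout.writestr("weights.npz", zin.read("weights.npz"))
        with pytest.raises(DataError, match="schema version"):
            PromoterCNN.load(bad)
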