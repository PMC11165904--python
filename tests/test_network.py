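import numpy as np
import pytest

from parmds import NeuralMDS, batch_pair_loss, init_network
from parmds.datasets import gaussian_clusters, open_box
from parmds.distances import pairwise_distances, stress

from conftest import brute_force_distances


class TestInitNetwork:
    def test_seed_determinism(self):
        a = init_network(7, 3, 2, seed=42)
        b = init_network(7, 3, 2, seed=42)
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)

    def test_different_seeds_differ(self):
        a = init_network(7, 3, 2, seed=1)
        b = init_network(7, 3, 2, seed=2)
        assert not np.array_equal(a[0], b[0])

    def test_nonpositive_dims_rejected(self):
        with pytest.raises(ValueError):
            init_network(0, 1, 1, seed=0)

    def test_auto_hidden_on_rank_one_data(self):
        t = np.linspace(0, 1, 30)[:, None]
        X = t @ np.array([[2.0, -1.0, 0.5]])
        model = NeuralMDS(n_components=1, hidden="auto", epochs=1,
                          batch_size=8).fit(X)
        assert model.hidden_dim_ == 1


class TestBatchPairLoss:
    def test_two_point_batch(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])   # distance 5
        Y = np.array([[0.0], [3.0]])             # distance 3
        assert batch_pair_loss(X, Y) == pytest.approx(4.0)

    def test_collapsed_output_gives_sum_of_squared_input_distances(self, rng):
        X = rng.standard_normal((6, 4))
        Y = np.ones((6, 2))
        D = brute_force_distances(X)
        iu = np.triu_indices(6, 1)
        assert batch_pair_loss(X, Y) == pytest.approx(np.sum(D[iu] ** 2))

    @pytest.mark.parametrize("metric", ["euclidean", "cosine"])
    def test_matches_double_loop_oracle(self, metric, rng):
        X = rng.standard_normal((16, 5))
        Y = rng.standard_normal((16, 2))
        DX = brute_force_distances(X, metric)
        DY = brute_force_distances(Y)
        expected = sum(
            (DX[i, j] - DY[i, j]) ** 2 for i in range(16) for j in range(i + 1, 16)
        )
        assert batch_pair_loss(X, Y, metric) == pytest.approx(expected)

    def test_single_point_batch_rejected(self):
        with pytest.raises(ValueError):
            batch_pair_loss(np.ones((1, 3)), np.ones((1, 2)))


class TestFit:
    def test_loss_decreases_on_open_box(self):
        ds = open_box(500, seed=0)
        model = NeuralMDS(epochs=100, random_state=0).fit(ds.X)
        assert model.loss_trace_[-1] <= model.loss_trace_[0]

    def test_smoothed_trace_non_increasing(self):
        ds = open_box(500, seed=1)
        model = NeuralMDS(epochs=200, random_state=1).fit(ds.X)
        windows = model.loss_trace_.reshape(-1, 10).mean(axis=1)
        assert np.all(np.diff(windows) <= 0.05 * windows[0])

    def test_two_points_embed_exactly(self):
        X = np.array([[0.0, 0.0], [3.0, 4.0]])
        model = NeuralMDS(n_components=1, epochs=1000, batch_size=2,
                          random_state=0).fit(X)
        D = pairwise_distances(X)
        s = stress(D, pairwise_distances(model.embedding_))
        assert s / np.sum(D**2) < 1e-3

    def test_seeded_determinism(self):
        ds = gaussian_clusters(100, 5, 2, seed=3)
        a = NeuralMDS(epochs=20, random_state=7).fit(ds.X).embedding_
        b = NeuralMDS(epochs=20, random_state=7).fit(ds.X).embedding_
        assert np.array_equal(a, b)

    def test_rejects_single_point_and_bad_config(self):
        with pytest.raises(ValueError):
            NeuralMDS().fit(np.ones((1, 3)))
        with pytest.raises(ValueError):
            NeuralMDS(batch_size=1).fit(np.ones((4, 3)))
        with pytest.raises(ValueError):
            NeuralMDS(metric="mahalanobis").fit(np.ones((4, 3)))


class TestTransform:
    @pytest.fixture(scope="class")
    def fitted(self):
        ds = gaussian_clusters(120, 8, 3, seed=5)
        model = NeuralMDS(epochs=50, random_state=5).fit(ds.X)
        return ds, model

    def test_training_matrix_reproduces_stored_embedding(self, fitted):
        ds, model = fitted
        assert np.array_equal(model.transform(ds.X), model.embedding_)

    def test_single_row_equals_batched_row(self, fitted):
        ds, model = fitted
        full = model.transform(ds.X)
        one = model.transform(ds.X[10:11])
        # BLAS takes different code paths for 1-row and batched products,
        # so agreement is to float round-off, not bit-for-bit
        assert np.allclose(one[0], full[10], rtol=1e-12, atol=1e-14)

    def test_column_mismatch_rejected(self, fitted):
        _, model = fitted
        with pytest.raises(ValueError, match="features"):
            model.transform(np.ones((3, 99)))

    def test_standardize_path_is_stored_and_replayed(self):
        ds = gaussian_clusters(80, 6, 2, seed=9)
        model = NeuralMDS(epochs=30, standardize=True, random_state=9).fit(ds.X)
        manual = (ds.X - model.mean_) / model.scale_
        H = np.tanh(manual @ model.W1_ + model.b1_)
        assert np.allclose(H @ model.W2_ + model.b2_, model.transform(ds.X))


class TestPersistence:
    def test_round_trip_transform_bit_for_bit(self, tmp_path):
        ds = gaussian_clusters(60, 5, 2, seed=11)
        model = NeuralMDS(epochs=10, random_state=11).fit(ds.X)
        path = tmp_path / "model.json"
        model.save(path)
        loaded = NeuralMDS.load(path)
        assert np.array_equal(loaded.transform(ds.X), model.transform(ds.X))

    def test_newer_major_version_refused(self, tmp_path):
        import json

        ds = gaussian_clusters(20, 3, 2, seed=1)
        model = NeuralMDS(epochs=2, random_state=1).fit(ds.X)
        path = tmp_path / "model.json"
        model.save(path)
        blob = json.loads(path.read_text())
        blob["format_version"] = 99
        path.write_text(json.dumps(blob))
        with pytest.raises(ValueError, match="newer"):
            NeuralMDS.load(path)
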