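"""SOM training, BMU assignment, centrotypes, quality, neuron clustering."""

import numpy as np
import pytest

from pathsom.som import (
    SOMModel,
    assign_bmu,
    assign_bmus,
    centrotypes,
    cluster_neurons,
    hex_positions,
    neuron_quality,
    train_som,
)


def _manual_model(codebook, rows=2, cols=2):
    return SOMModel(rows=rows, cols=cols, codebook=np.asarray(codebook, float), seed=0)


class TestHexLattice:
    def test_positions_and_neighbor_counts(self):
        pos = hex_positions(3, 3)
        assert pos.shape == (9, 3 - 1)
        # odd row shifted by +0.5, rows sqrt(3)/2 apart
        assert pos[3, 0] == pytest.approx(0.5)
        assert pos[3, 1] == pytest.approx(np.sqrt(3) / 2)
        model = _manual_model(np.zeros((9, 2)), rows=3, cols=3)
        # centre neuron of a 3x3 hex sheet touches all 6 hex neighbours
        assert len(model.neighbors(4)) == 6
        # corner neuron touches 2 or 3 depending on the row offset
        assert len(model.neighbors(0)) in (2, 3)


class TestTraining:
    def test_deterministic_given_seed(self, small_dataset):
        data = small_dataset.replicas[0].features.values
        m1 = train_som(data, rows=4, cols=4, seed=9, n_epochs=40)
        m2 = train_som(data, rows=4, cols=4, seed=9, n_epochs=40)
        np.testing.assert_array_equal(m1.codebook, m2.codebook)
        m3 = train_som(data, rows=4, cols=4, seed=10, n_epochs=40)
        assert not np.array_equal(m1.codebook, m3.codebook)

    def test_far_separated_points_each_capture_a_neuron(self):
        # as many far-apart points as neurons: long training drives the
        # quantization error toward zero with every point on its own BMU
        pts = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0], [10.0, 10.0]]) + 1.0
        # a seed whose random init orders without topological folding
        model = train_som(pts, rows=2, cols=2, seed=0, n_epochs=800, radius_end=0.1)
        bmus, dists = assign_bmus(model, pts)
        assert len(set(bmus)) == 4
        assert model.quantization_error < 0.1  # ~1% of the point separation

    def test_two_blobs_recovered_near_blob_means(self):
        rng = np.random.default_rng(5)
        blob_a = rng.normal([1.0, 1.0, 1.0], 0.05, (200, 3))
        blob_b = rng.normal([5.0, 5.0, 5.0], 0.05, (200, 3))
        data = np.vstack([blob_a, blob_b])
        model = train_som(data, rows=2, cols=2, seed=2, n_epochs=300, radius_end=0.1)
        se = 0.05 / np.sqrt(200)
        for mean in (blob_a.mean(0), blob_b.mean(0)):
            nearest = np.min(np.linalg.norm(model.codebook - mean, axis=1))
            assert nearest < max(3 * se, 0.02)

    def test_quantization_error_not_worse_than_init(self, small_dataset):
        data = small_dataset.replicas[0].features.values
        for seed in range(5):
            model = train_som(data, rows=3, cols=3, seed=seed, n_epochs=60)
            init_rng = np.random.default_rng(seed)
            init = init_rng.uniform(data.min(0), data.max(0), (9, data.shape[1]))
            init_model = SOMModel(rows=3, cols=3, codebook=init, seed=seed)
            _, d0 = assign_bmus(init_model, data)
            assert model.quantization_error <= d0.mean()

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            train_som(np.empty((0, 3)), rows=2, cols=2, seed=0)
        with pytest.raises(ValueError):
            train_som(np.full((10, 3), np.nan), rows=2, cols=2, seed=0)
        with pytest.raises(ValueError):
            train_som(np.ones((10, 3)), rows=1, cols=4, seed=0)

    def test_underpopulated_map_warns(self):
        with pytest.warns(UserWarning, match="underpopulated"):
            train_som(np.random.default_rng(0).uniform(1, 2, (5, 3)),
                      rows=3, cols=3, seed=0, n_epochs=5)


class TestAssignBmu:
    def test_codebook_vector_maps_to_its_neuron(self, trained_model):
        j = 17
        bmu, dist = assign_bmu(trained_model, trained_model.codebook[j])
        assert (bmu, dist) == (j, 0.0)

    def test_matches_bruteforce_argmin(self, trained_model):
        rng = np.random.default_rng(3)
        lo, hi = trained_model.codebook.min(), trained_model.codebook.max()
        for _ in range(300):
            x = rng.uniform(lo, hi, trained_model.n_features)
            d = [np.sqrt(((w - x) ** 2).sum()) for w in trained_model.codebook]
            assert assign_bmu(trained_model, x)[0] == int(np.argmin(d))

    def test_tie_breaks_to_lowest_id(self):
        codebook = np.array([[0.0, 0.0], [2.0, 0.0], [0.0, 2.0], [2.0, 2.0]])
        model = _manual_model(codebook)
        # equidistant from neurons 1 and 2
        bmu, _ = assign_bmu(model, [1.0, 1.0])
        assert bmu == 0  # also equidistant from 0 and 3: lowest id wins

    def test_dimension_mismatch(self, trained_model):
        with pytest.raises(ValueError):
            assign_bmu(trained_model, np.ones(trained_model.n_features + 1))


class TestCentrotypes:
    def test_single_frame_neuron_is_its_own_centrotype(self):
        codebook = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [5.0, 5.0]])
        model = _manual_model(codebook)
        frames = np.array([[0.1, 0.0], [5.2, 0.0]])
        cts = centrotypes(model, frames)
        assert cts == {0: 0, 1: 1}

    def test_picks_closest_of_several(self):
        codebook = np.array([[0.0, 0.0], [5.0, 0.0], [0.0, 5.0], [5.0, 5.0]])
        model = _manual_model(codebook)
        frames = np.array([[0.2, 0.0], [0.1, 0.0], [0.4, 0.0]])
        assert centrotypes(model, frames)[0] == 1

    def test_matches_bruteforce_scan(self, trained_model, small_dataset):
        data = np.vstack([r.features.values for r in small_dataset.replicas])
        cts = centrotypes(trained_model, data)
        bmus, _ = assign_bmus(trained_model, data)
        for neuron, frame in cts.items():
            members = np.where(bmus == neuron)[0]
            d = [np.linalg.norm(data[f] - trained_model.codebook[neuron]) for f in members]
            assert frame == members[int(np.argmin(d))]


class TestNeuronQuality:
    def test_identical_frames_give_degenerate_distributions(self, trained_model):
        data = np.tile(trained_model.codebook[10], (6, 1))
        q = neuron_quality(trained_model, data)
        assert np.all(q["intra"] == 0.0)
        assert len(q["inter"]) == 0  # one neuron occupied: no neighbour pairs

    def test_two_neuron_offset_construction(self):
        codebook = np.zeros((4, 3))
        codebook[1] = 0.5  # neuron 1 offset by c=0.5 in every component
        codebook[2] = 10.0
        codebook[3] = 20.0
        model = _manual_model(codebook)
        frames = np.vstack([codebook[0], codebook[0], codebook[1], codebook[1]])
        q = neuron_quality(model, frames)
        assert np.allclose(q["intra"], 0.0)
        assert np.allclose(q["inter"], 0.5)  # dRMSD of a constant offset

    def test_intra_below_inter_on_pathway_data(self, trained_model, small_dataset):
        data = np.vstack([r.features.values for r in small_dataset.replicas])
        q = neuron_quality(trained_model, data, seed=0)
        assert q["median_intra"] < q["median_inter"]


class TestClusterNeurons:
    def test_two_blobs_split_exactly(self):
        rng = np.random.default_rng(4)
        codebook = np.vstack([
            rng.normal(0.0, 0.01, (8, 3)),
            rng.normal(5.0, 0.01, (8, 3)),
        ])
        model = SOMModel(rows=4, cols=4, codebook=codebook, seed=0)
        nc = cluster_neurons(model, n=2)
        assert len(set(nc.labels[:8])) == 1 and len(set(nc.labels[8:])) == 1
        assert nc.labels[0] != nc.labels[8]
        assert np.all(nc.silhouette > 0)

    def test_n_minus_one_pairs_closest_codebook_vectors(self, trained_model):
        nc = cluster_neurons(trained_model, n=trained_model.n_neurons - 1)
        sizes = np.bincount(nc.labels)[1:]
        assert sorted(sizes)[-1] == 2 and np.sum(sizes == 2) == 1
        pair = np.where(nc.labels == np.argmax(np.bincount(nc.labels)))[0]
        # brute-force closest pair in codebook space
        cb = trained_model.codebook
        best, best_d = None, np.inf
        for i in range(len(cb)):
            for j in range(i + 1, len(cb)):
                d = np.linalg.norm(cb[i] - cb[j])
                if d < best_d:
                    best, best_d = (i, j), d
        assert tuple(pair) == best

    def test_eight_by_eight_cut_at_eight(self, trained_model):
        nc = cluster_neurons(trained_model, n=8)
        assert nc.n_clusters == 8
        assert np.all(np.bincount(nc.labels)[1:] > 0)

    def test_auto_prefers_high_silhouette(self):
        rng = np.random.default_rng(8)
        centers = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0], [6, 6, 6]], float)
        codebook = np.vstack([rng.normal(c, 0.05, (4, 3)) for c in centers])
        model = SOMModel(rows=4, cols=4, codebook=codebook, seed=0)
        nc = cluster_neurons(model, n="auto")
        assert nc.n_clusters == 4
        assert nc.average_silhouette > 0.9

    def test_invalid_n(self, trained_model):
        with pytest.raises(ValueError):
            cluster_neurons(trained_model, n=1)
        with pytest.raises(ValueError):
            cluster_neurons(trained_model, n=trained_model.n_neurons)


class TestPersistence:
    def test_round_trip_is_lossless(self, trained_model, tmp_path):
        path = tmp_path / "som.model"
        trained_model.save(path)
        loaded = SOMModel.load(path)
        np.testing.assert_array_equal(loaded.codebook, trained_model.codebook)
        assert loaded.rows == trained_model.rows
        assert loaded.seed == trained_model.seed
        assert loaded.quantization_error == trained_model.quantization_error
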