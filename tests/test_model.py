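import numpy as np
import pytest

import fogcue.model as fm
from fogcue import FogClassifier, SimConfig, batch_windows, generate_recording
from fogcue.model import chronological_split, load_model, tune_past_samples


class TestArchitecture:
    def test_canonical_shape_arithmetic(self):
        clf = FogClassifier(ps=39).build(20)
        assert clf.n_features_in_ == 800
        assert clf.flatten_size_ == 1280

    @pytest.mark.parametrize("ps,filters", [(15, 32), (39, 16), (100, 8)])
    def test_flatten_count_law(self, ps, filters):
        clf = FogClassifier(ps=ps, conv_filters=filters).build(20)
        assert clf.flatten_size_ == filters * (ps + 1)

    def test_untrained_scores_are_valid_probabilities(self):
        clf = FogClassifier(ps=5, random_state=3).build(20)
        x = np.random.default_rng(0).normal(size=(10, 120)).astype(np.float32)
        s = clf.predict_score(x)
        assert s.dtype == np.float32
        assert np.isfinite(s).all() and (s >= 0).all() and (s <= 1).all()

    def test_zeroed_output_layer_scores_half(self):
        clf = FogClassifier(ps=2).build(20)
        clf.net_.params["dense_W"][:] = 0
        clf.net_.params["dense_b"][:] = 0
        s = clf.predict_score(np.zeros(60, dtype=np.float32))
        assert s == np.float32(0.5)

    def test_window_length_mismatch_rejected(self):
        clf = FogClassifier(ps=5).build(20)
        with pytest.raises(ValueError):
            clf.predict_score(np.zeros(100, dtype=np.float32))


@pytest.fixture(scope="module")
def training_data():
    cfg = SimConfig(duration_s=150, fog_prevalence=0.08, n_fog_episodes=10, seed=13)
    rec = generate_recording(cfg)
    return batch_windows(rec, 39)


class TestTraining:
    def test_loss_decreases_over_first_epochs(self, training_data):
        X, y = training_data
        tr, _ = chronological_split(X.shape[0])
        clf = FogClassifier(ps=39, epochs=3, random_state=1)
        clf.fit(X[tr], y[tr])
        assert clf.history_[0] > clf.history_[1] > clf.history_[2]

    def test_fit_is_deterministic_given_seed(self, training_data):
        X, y = training_data
        a = FogClassifier(ps=39, epochs=1, random_state=5).fit(X[:2000], y[:2000])
        b = FogClassifier(ps=39, epochs=1, random_state=5).fit(X[:2000], y[:2000])
        for k in a.net_.params:
            assert np.array_equal(a.net_.params[k], b.net_.params[k])

    def test_single_class_split_rejected(self):
        X = np.zeros((50, 60), dtype=np.float32)
        with pytest.raises(ValueError, match="single class"):
            FogClassifier(ps=2).fit(X, np.zeros(50))

    def test_repeated_prediction_is_bitwise_stable(self, trained_model, small_recording):
        X, _ = batch_windows(small_recording, trained_model.ps)
        assert np.array_equal(trained_model.predict_score(X[:50]), trained_model.predict_score(X[:50]))

    def test_predict_thresholds_strictly(self, trained_model, small_recording):
        X, _ = batch_windows(small_recording, trained_model.ps)
        s = trained_model.predict_score(X[:200])
        assert np.array_equal(trained_model.predict(X[:200]), (s > trained_model.threshold).astype(np.uint8))

    def test_sklearn_params_roundtrip(self):
        clf = FogClassifier(ps=7, epochs=2)
        params = clf.get_params()
        assert params["ps"] == 7
        clone = FogClassifier(**params)
        assert clone.get_params() == params


class TestPersistence:
    def test_save_load_roundtrip_bitwise(self, trained_model, tmp_path):
        path = tmp_path / "model.fog"
        trained_model.save(path)
        loaded = load_model(path)
        rng = np.random.default_rng(2)
        x = rng.normal(size=(100, trained_model.n_features_in_)).astype(np.float32)
        assert np.array_equal(trained_model.predict_score(x), loaded.predict_score(x))

    def test_corrupt_file_rejected(self, tmp_path):
        path = tmp_path / "bad.fog"
        path.write_bytes(b"this is not a model container")
        with pytest.raises(ValueError, match="container"):
            load_model(path)

    def test_ps_mismatch_rejected(self, trained_model, tmp_path):
        path = tmp_path / "model.fog"
        trained_model.save(path)
        with pytest.raises(ValueError, match="ps"):
            load_model(path, expected_ps=99)


class TestTunePastSamples:
    def test_returns_grid_member_and_full_table(self, small_recording):
        best, table = tune_past_samples(
            small_recording, ps_grid=(5, 10), epochs=1, random_state=0
        )
        assert best in (5, 10)
        assert list(table["ps"]) == [5, 10]

    def test_singleton_grid(self, small_recording):
        best, table = tune_past_samples(small_recording, ps_grid=(8,), epochs=1)
        assert best == 8 and len(table) == 1

    def test_ties_break_toward_smaller_ps(self, small_recording, monkeypatch):
        monkeypatch.setattr(fm, "_f1", lambda pred, target: 0.5)
        best, _ = tune_past_samples(small_recording, ps_grid=(20, 5, 10), epochs=1)
        assert best == 5

    def test_empty_grid_rejected(self, small_recording):
        with pytest.raises(ValueError):
            tune_past_samples(small_recording, ps_grid=())
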