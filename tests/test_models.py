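"""c-EEGNet (shapes, gradients, training) and TRCA (oracle equivalence)."""

import numpy as np
import pytest

from cvepauth.models import (
    CEEGNet,
    CEEGNetConfig,
    TrainConfig,
    authenticate_ceegnet,
    authenticate_trca,
    load_model,
    save_model,
    train_ceegnet,
    trca_calibrate_threshold,
    trca_fit,
    trca_scores,
)
from cvepauth.sampling import POSITIONS, TrainingPacket

TINY = CEEGNetConfig(n1=4, n2=2, n3=2, n4=8, n5=2, time_kernel=8, time_kernel2=4,
                     dropout=0.0, n_channels=3, n_times=24)


def _toy_packet(rng, n=48, C=3, T=64, sep=3.0, noise=0.3):
    """Separable-by-construction packet: two distinct 4-position templates."""
    t = np.arange(T) / T
    a = np.stack([np.sin(2 * np.pi * (3 + k) * t) for k in range(4)])  # (4, T)
    b = np.stack([np.cos(2 * np.pi * (2 + k) * t) for k in range(4)])
    chans = rng.uniform(0.5, 1.5, size=(2, C))

    def make(template, cw, count):
        base = template[None, :, None, :] * cw[None, None, :, None]
        return sep * np.repeat(base, count, axis=0) + noise * rng.normal(
            size=(count, 4, C, T))

    X = np.concatenate([make(a, chans[0], n), make(b, chans[1], n)]).astype(np.float32)
    y = np.array([1] * n + [0] * n)
    return TrainingPacket(claimed_subject="A", X=X, y=y, n_avg=1, rng_seed=0)


SMALL = CEEGNetConfig(n1=8, n2=2, n3=2, n4=16, n5=4, time_kernel=16,
                      time_kernel2=8, n_channels=3, n_times=64)


class TestArchitecture:
    def test_default_shape_contract(self):
        cfg = CEEGNetConfig()
        assert cfg.pooled1 == 65
        assert cfg.n_features == 256
        assert cfg.pooled2 == 8
        assert cfg.flat_len == 512

    @pytest.mark.parametrize("n_channels", [9, 3])
    def test_forward_returns_probabilities(self, n_channels, rng):
        m = CEEGNet(CEEGNetConfig(n_channels=n_channels), rng_seed=0)
        X = rng.normal(size=(5, 4, n_channels, 262)).astype(np.float32)
        p = m.forward(X)
        assert p.shape == (5, 2)
        assert np.allclose(p.sum(axis=1), 1, atol=1e-6)

    def test_kernel_longer_than_input_rejected(self):
        with pytest.raises(ValueError):
            CEEGNetConfig(time_kernel=300)

    def test_shape_mismatch_rejected(self, rng):
        m = CEEGNet(TINY, rng_seed=0)
        with pytest.raises(ValueError):
            m.forward(rng.normal(size=(2, 4, 5, 24)))

    def test_branch_merge_mode_builds(self, rng):
        cfg = CEEGNetConfig(n1=4, n2=2, n3=2, n4=8, n5=2, time_kernel=8,
                            time_kernel2=4, n_channels=3, n_times=24,
                            merge_mode="branch")
        m = CEEGNet(cfg, rng_seed=0)
        p = m.forward(rng.normal(size=(3, 4, 3, 24)).astype(np.float32))
        assert np.allclose(p.sum(axis=1), 1, atol=1e-6)


@pytest.mark.parametrize("merge_mode", ["full", "branch"])
def test_gradients_match_finite_differences(merge_mode, rng):
    cfg = CEEGNetConfig(n1=4, n2=2, n3=2, n4=8, n5=2, time_kernel=8,
                        time_kernel2=4, dropout=0.0, n_channels=3, n_times=24,
                        merge_mode=merge_mode)
    m = CEEGNet(cfg, rng_seed=3)
    X = rng.standard_normal((6, 4, 3, 24)).astype(np.float32)
    y = np.array([0, 1, 0, 1, 1, 0])
    _, grads = m.loss_and_grads(X, y, np.random.default_rng(1))
    params = m._opt_params()
    for name in sorted(grads):
        p = params[name]
        g = np.asarray(grads[name]).reshape(p.shape).reshape(-1)
        flat = p.reshape(-1)
        for i in rng.choice(flat.size, size=min(3, flat.size), replace=False):
            eps, orig = 1e-2, flat[i]
            flat[i] = orig + eps
            l1, _ = m.loss_and_grads(X, y, np.random.default_rng(1))
            flat[i] = orig - eps
            l2, _ = m.loss_and_grads(X, y, np.random.default_rng(1))
            flat[i] = orig
            num = (l1 - l2) / (2 * eps)
            assert abs(num - g[i]) <= 5e-2 * max(abs(num), abs(g[i]), 1e-2), name


class TestTraining:
    def test_separable_packet_reaches_high_validation_accuracy(self, rng):
        pk = _toy_packet(rng)
        m = CEEGNet(SMALL, rng_seed=1)
        train_ceegnet(m, pk, TrainConfig(max_epochs=20, patience=5, rng_seed=1))
        assert m.metadata["val_acc"] >= 0.99

    def test_shuffled_labels_give_chance_validation(self, rng):
        pk = _toy_packet(rng, n=64)
        y = pk.y.copy()
        np.random.default_rng(0).shuffle(y)
        m = CEEGNet(SMALL, rng_seed=1)
        m.fit(pk.X, y, TrainConfig(max_epochs=8, patience=8, rng_seed=1))
        assert abs(m.metadata["val_acc"] - 0.5) <= 0.2

    def test_training_is_deterministic(self, rng):
        pk = _toy_packet(rng, n=24)
        runs = []
        for _ in range(2):
            m = CEEGNet(SMALL, rng_seed=5)
            m.fit(pk.X, pk.y, TrainConfig(max_epochs=3, patience=3, rng_seed=5))
            runs.append(m.metadata["history"]["train_loss"])
        assert runs[0] == runs[1]

    def test_authenticate_rules(self, rng):
        pk = _toy_packet(rng, n=24)
        m = CEEGNet(SMALL, rng_seed=2)
        train_ceegnet(m, pk, TrainConfig(max_epochs=5, patience=5, rng_seed=2))
        sample = pk.X[0]
        out = authenticate_ceegnet(m, sample)
        assert out["decision"] == ("accept" if out["score"] >= 0.5 else "reject")
        assert authenticate_ceegnet(m, sample, rule="threshold", theta=1.01)["decision"] == "reject"
        assert authenticate_ceegnet(m, sample, rule="threshold", theta=0.0)["decision"] == "accept"


def _common_component_trials(rng, K=12, C=2, T=120, direction=(0.8, 0.6), noise=0.6):
    common = rng.normal(size=(K, T)) * 0 + np.sin(2 * np.pi * 7 * np.arange(T) / T)
    d = np.asarray(direction, dtype=float)
    X = d[None, :, None] * common[:, None, :] + noise * rng.normal(size=(K, C, T))
    return X


def _brute_force_trca_2ch(trials, n_angles=7200):
    """Grid search over unit vectors maximizing the TRCA Rayleigh quotient."""
    K, C, T = trials.shape
    Xc = trials - trials.mean(axis=-1, keepdims=True)
    total = Xc.sum(axis=0)
    Q = sum(x @ x.T for x in Xc)
    S = total @ total.T - Q
    best, best_w = -np.inf, None
    for ang in np.linspace(0, np.pi, n_angles, endpoint=False):
        w = np.array([np.cos(ang), np.sin(ang)])
        val = (w @ S @ w) / (w @ Q @ w)
        if val > best:
            best, best_w = val, w
    return best_w


class TestTRCA:
    def test_filter_matches_brute_force_within_1_degree(self, rng):
        trials = _common_component_trials(rng)
        w_bf = _brute_force_trca_2ch(trials)
        epochs = {p: trials for p in POSITIONS}
        model = trca_fit(epochs)
        w = model.filters["left"]
        cos = abs(float(w @ w_bf))
        assert np.degrees(np.arccos(np.clip(cos, 0, 1))) < 1.0

    def test_pure_noise_leading_eigenvalue_small(self, rng):
        trials = rng.normal(size=(10, 3, 200))
        model = trca_fit({p: trials for p in POSITIONS})
        # generalized eigenvalue ~ K-1 times smaller than the perfect-
        # coherence value (K-1); noise keeps it near zero
        assert model.eigenvalues["left"] < 1.0

    def test_filtered_correlation_beats_raw_channels(self, rng):
        trials = _common_component_trials(rng, noise=1.0)
        model = trca_fit({p: trials for p in POSITIONS})
        w = model.filters["left"]

        def mean_pairwise_corr(comps):
            K = len(comps)
            cs = [np.corrcoef(comps[i], comps[j])[0, 1]
                  for i in range(K) for j in range(i + 1, K)]
            return np.mean(cs)

        filtered = mean_pairwise_corr([w @ x for x in trials])
        raw = max(mean_pairwise_corr([x[c] for x in trials])
                  for c in range(trials.shape[1]))
        assert filtered > raw

    def test_training_mean_scores_one(self, rng):
        trials = _common_component_trials(rng)
        model = trca_fit({p: trials for p in POSITIONS})
        sample = np.stack([trials.mean(axis=0)] * 4)
        assert trca_scores(model, sample)[0] == pytest.approx(1.0, abs=1e-9)

    def test_noise_scores_centred_on_zero(self, rng):
        trials = _common_component_trials(rng)
        model = trca_fit({p: trials for p in POSITIONS})
        X = rng.normal(size=(1000, 4, 2, 120))
        s = trca_scores(model, X)
        assert abs(s.mean()) < 3 * s.std() / np.sqrt(len(s))

    def test_threshold_above_one_rejects_everything(self, rng):
        trials = _common_component_trials(rng)
        model = trca_fit({p: trials for p in POSITIONS})
        model.theta = 1.1
        sample = np.stack([trials.mean(axis=0)] * 4)
        assert authenticate_trca(model, sample)["decision"] == "reject"

    def test_calibration_sets_theta_between_classes(self, rng):
        trials = _common_component_trials(rng)
        model = trca_fit({p: trials for p in POSITIONS})
        Xg = np.stack([np.stack([trials.mean(axis=0)] * 4)] * 20)
        Xg = Xg + 0.05 * rng.normal(size=Xg.shape)
        Xi = rng.normal(size=(20, 4, 2, 120))
        X = np.concatenate([Xg, Xi])
        y = np.array([1] * 20 + [0] * 20)
        theta = trca_calibrate_threshold(model, X, y)
        sg, si = trca_scores(model, Xg), trca_scores(model, Xi)
        assert si.max() < theta <= sg.min() + 1e-9


class TestSerialization:
    def test_ceegnet_roundtrip_bit_exact(self, tmp_path, rng):
        m = CEEGNet(TINY, rng_seed=4)
        X = rng.normal(size=(3, 4, 3, 24)).astype(np.float32)
        before = m.predict_proba(X)
        save_model(m, tmp_path / "m.h5")
        loaded = load_model(tmp_path / "m.h5")
        after = loaded.predict_proba(X)
        assert np.array_equal(before, after)

    def test_trca_roundtrip(self, tmp_path, rng):
        trials = _common_component_trials(rng)
        model = trca_fit({p: trials for p in POSITIONS})
        model.theta = 0.4
        save_model(model, tmp_path / "t.h5")
        loaded = load_model(tmp_path / "t.h5")
        assert loaded.theta == 0.4
        for p in POSITIONS:
            assert np.array_equal(loaded.filters[p], model.filters[p])
            assert np.array_equal(loaded.templates[p], model.templates[p])

    def test_corrupted_file_clean_error(self, tmp_path):
        path = tmp_path / "bad.h5"
        path.write_bytes(b"this is not a model container")
        with pytest.raises(ValueError, match="container"):
            load_model(path)

    def test_shared_container_schema(self, tmp_path, rng):
        import json

        import h5py

        m = CEEGNet(TINY, rng_seed=0)
        trials = _common_component_trials(rng)
        t = trca_fit({p: trials for p in POSITIONS})
        save_model(m, tmp_path / "a.h5")
        save_model(t, tmp_path / "b.h5")
        for fname, kind in (("a.h5", "ceegnet"), ("b.h5", "trca")):
            with h5py.File(tmp_path / fname) as f:
                header = json.loads(f.attrs["header"])
                assert header["model_type"] == kind
                assert "params" in f
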