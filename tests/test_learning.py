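import numpy as np
import pandas as pd
import pytest

from boxcc import (BccRegressor, DatasetArchive, DescriptorRecord, ModelConfig,
                   TrainedModel, evaluate_predictions, predict_bcc,
                   rotate_voxels, train_model)
from boxcc.learning import desk_scale_config


def _records(n, rng, grid=8, aa="ALA", labels=None):
    out = []
    for i in range(n):
        lab = labels[i] if labels is not None else float(rng.uniform(0, 1))
        out.append(DescriptorRecord(
            channels=rng.normal(size=(5, grid, grid, grid)).astype(np.float32),
            amino_acid=aa, structure_id=f"s{i % 4}", resolution_tag="2A",
            chain="A", resnum=i, label=lab))
    return out


def _tiny_cfg(**kw):
    base = dict(input_grid=8, conv_channels=(4, 8, 8, 8), learning_rate=1e-3,
                epochs=8, batch_size=16, augment="none", downsample=1, seed=0)
    base.update(kw)
    return ModelConfig(**base)


class TestModelConfig:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ModelConfig(conv_channels=(8, 8, 8))          # not 4 layers
        with pytest.raises(ValueError):
            ModelConfig(learning_rate=0.0)
        with pytest.raises(ValueError):
            ModelConfig(pool=("max", "max", None, None))  # must end in gap
        with pytest.raises(ValueError):
            ModelConfig(augment="sometimes")
        cfg = ModelConfig()
        assert len(cfg.conv_channels) == 4
        assert cfg.learning_rate == 1e-5 and cfg.epochs == 40

    def test_sklearn_protocol(self):
        cfg = _tiny_cfg()
        reg = BccRegressor(cfg)
        assert reg.get_params()["config"] is cfg
        reg2 = BccRegressor().set_params(config=cfg)
        assert reg2.config is cfg


class TestFit:
    def test_constant_label_converges_to_constant(self, rng):
        X = rng.normal(size=(48, 5, 8, 8, 8)).astype(np.float32)
        y = np.full(48, 0.47, dtype=np.float32)
        reg = BccRegressor(_tiny_cfg(epochs=40, dropout=0.0)).fit(X, y)
        assert np.abs(reg.predict(X) - 0.47).max() < 0.05

    def test_loss_decreases_and_history_recorded(self, rng):
        recs = _records(64, rng)
        X = np.stack([r.channels for r in recs])
        y = np.array([r.label for r in recs], dtype=np.float32)
        reg = BccRegressor(_tiny_cfg(epochs=10)).fit(X, y)
        assert len(reg.history_) == 10
        assert reg.history_[-1] <= reg.history_[0]

    def test_doubling_epochs_does_not_worsen_final_loss(self, rng):
        X = rng.normal(size=(48, 5, 8, 8, 8)).astype(np.float32)
        y = rng.uniform(0, 1, 48).astype(np.float32)
        short = BccRegressor(_tiny_cfg(epochs=6, dropout=0.0)).fit(X, y)
        long = BccRegressor(_tiny_cfg(epochs=12, dropout=0.0)).fit(X, y)
        assert long.history_[-1] <= short.history_[-1] * (1 + 1e-6)

    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(40, 5, 8, 8, 8)).astype(np.float32)
        y = rng.uniform(0, 1, 40).astype(np.float32)
        p1 = BccRegressor(_tiny_cfg(augment="random")).fit(X, y).predict(X)
        p2 = BccRegressor(_tiny_cfg(augment="random")).fit(X, y).predict(X)
        assert np.array_equal(p1, p2)

    def test_predictions_clamped_and_deterministic(self, rng):
        X = rng.normal(size=(32, 5, 8, 8, 8)).astype(np.float32)
        y = rng.uniform(-0.5, 1.5, 32).astype(np.float32)
        reg = BccRegressor(_tiny_cfg()).fit(X, y)
        p = reg.predict(X)
        assert np.all((p >= 0) & (p <= 1))
        assert np.array_equal(p, reg.predict(X))

    def test_rotation_augmented_training_gives_stable_predictions(self, rng):
        """After training with full rotation augmentation, the 24 rotated
        copies of one record predict within a small spread."""
        recs = _records(40, rng)
        X = np.stack([r.channels for r in recs])
        y = np.array([r.label for r in recs], dtype=np.float32)
        reg = BccRegressor(_tiny_cfg(augment="all", epochs=6)).fit(X, y)
        rots = np.stack([rotate_voxels(X[0], k) for k in range(24)])
        spread = np.abs(reg.predict(rots) - reg.predict(X[:1])[0]).mean()
        assert spread < 0.05


class TestTrainedModel:
    @pytest.fixture()
    def archive(self, tmp_path, rng):
        arc = DatasetArchive.create(tmp_path / "a.h5", provenance={"seed": 0})
        arc.add_records(_records(40, rng))
        arc.finalize()
        yield arc
        arc.close()

    def test_train_model_and_roundtrip(self, archive, tmp_path, rng):
        model = train_model(archive, "ALA", _tiny_cfg(epochs=4))
        assert model.amino_acid == "ALA"
        assert model.manifest_hash == archive.manifest_hash()
        assert len(model.history) == 4
        path = tmp_path / "m.npz"
        model.save(path)
        back = TrainedModel.load(path)
        recs = _records(6, rng)
        assert np.allclose(predict_bcc(back, recs).bcc_pred,
                           predict_bcc(model, recs).bcc_pred)

    def test_too_few_records_rejected(self, archive):
        with pytest.raises(ValueError, match="need at least"):
            train_model(archive, "ALA", _tiny_cfg(batch_size=64))

    def test_type_mismatch_rejected(self, archive, rng):
        model = train_model(archive, "ALA", _tiny_cfg(epochs=2))
        with pytest.raises(ValueError, match="LEU"):
            predict_bcc(model, _records(3, rng, aa="LEU"))


class TestEvaluate:
    def test_perfect_and_anticorrelated(self):
        pred = pd.DataFrame({"chain": list("AAAAA"), "resnum": range(5),
                             "bcc_pred": [0.1, 0.3, 0.5, 0.7, 0.9]})
        act = pred.rename(columns={"bcc_pred": "bcc_act"})
        out = evaluate_predictions(pred, act)
        assert out["pearson_r"] == pytest.approx(1.0)
        assert out["mean_delta"] == 0 and out["sd_delta"] == 0
        anti = act.assign(bcc_act=lambda d: 1 - d.bcc_act)
        assert evaluate_predictions(pred, anti)["pearson_r"] == pytest.approx(-1.0)

    def test_five_row_arithmetic_oracle(self):
        p = np.array([0.2, 0.4, 0.5, 0.6, 0.9])
        a = np.array([0.25, 0.35, 0.55, 0.5, 0.8])
        pred = pd.DataFrame({"chain": list("AAAAA"), "resnum": range(5), "bcc_pred": p})
        act = pd.DataFrame({"chain": list("AAAAA"), "resnum": range(5), "bcc_act": a})
        out = evaluate_predictions(pred, act)
        # hand-computed Pearson r
        pc, ac = p - p.mean(), a - a.mean()
        r_hand = (pc @ ac) / np.sqrt((pc @ pc) * (ac @ ac))
        assert out["pearson_r"] == pytest.approx(r_hand, rel=1e-12)
        assert out["mean_delta"] == pytest.approx((p - a).mean())
        assert out["sd_delta"] == pytest.approx((p - a).std())

    def test_unmatched_reported_and_empty_join_raises(self):
        pred = pd.DataFrame({"chain": ["A", "A"], "resnum": [1, 2],
                             "bcc_pred": [0.5, 0.6]})
        act = pd.DataFrame({"chain": ["A", "B"], "resnum": [1, 9],
                            "bcc_act": [0.5, 0.7]})
        out = evaluate_predictions(pred, act)
        assert out["n"] == 1 and out["unmatched_pred"] == 1 and out["unmatched_act"] == 1
        with pytest.raises(ValueError):
            evaluate_predictions(pred, act.assign(chain=["Z", "Z"]))
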