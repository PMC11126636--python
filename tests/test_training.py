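"""Training loop, schedule/early-stop logic, checkpointing, evaluation
reports, and prediction tables — on small synthetic data."""

import dataclasses
import json

import numpy as np
import pytest

import mbranet.nn as nn
from mbranet.nn.optim import Adam, EarlyStopping, ReduceLROnPlateau
from mbranet.config import load_train_config
from mbranet.data import read_chestxray14_csv, split_records
from mbranet.losses import BCEWithLabelSmoothing
from mbranet.nn.autograd import Tensor
from mbranet.synthetic import SyntheticSpec, generate_synthetic_dataset
from mbranet.training import (TrainConfig, evaluate, load_checkpoint, predict,
                              save_checkpoint, train, count_components,
                              _load_batch)


def _smoke_config(**over):
    base = dict(seed=0, max_epochs=2)
    base.update(over)
    return TrainConfig.scaled_synthetic(**base)


@pytest.fixture(scope="module")
def fitted(tmp_path_factory):
    """A short smoke fit on 300 synthetic 64x64 images (240 train / 60 val),
    long enough that the easy motif task is clearly learned."""
    out = tmp_path_factory.mktemp("train")
    csv = generate_synthetic_dataset(
        SyntheticSpec(n_images=300, image_size=64, seed=21), out)
    records = read_chestxray14_csv(csv)
    tr, va = records[:240], records[240:]
    config = _smoke_config(max_epochs=8)
    ckpt = out / "model.npz"
    model, log = train(config, tr, va, checkpoint_path=ckpt)
    return {"model": model, "log": log, "config": config, "train": tr,
            "val": va, "ckpt": ckpt, "dir": out}


class TestTrainLoop:
    def test_smoke_run_reduces_training_loss(self, fitted):
        df = fitted["log"].to_dataframe()
        assert df.train_loss.iloc[-1] < df.train_loss.iloc[0]

    def test_label_smoothing_changes_first_batch_loss(self, fitted):
        batch = fitted["train"][:16]
        rng = np.random.default_rng(0)
        images, labels = _load_batch(batch, "eval_deterministic", rng, 72, 64)
        model = fitted["model"]
        model.eval()
        probs = model(Tensor(images)).probabilities
        smoothed = float(BCEWithLabelSmoothing(0.1)(probs, labels).data)
        plain = float(BCEWithLabelSmoothing(0.0)(probs, labels).data)
        assert smoothed != plain

    def test_identical_seeds_reproduce_the_run_log(self, fitted):
        tr, va = fitted["train"][:48], fitted["val"][:16]
        config = _smoke_config(max_epochs=1)
        _, log_a = train(config, tr, va)
        _, log_b = train(config, tr, va)
        assert log_a.epochs == log_b.epochs

    def test_empty_training_split_rejected(self, fitted):
        with pytest.raises(ValueError, match="empty"):
            train(_smoke_config(), [], fitted["val"])

    def test_run_log_embeds_resolved_config(self, fitted):
        assert fitted["log"].config == dataclasses.asdict(fitted["config"])

    def test_run_log_serialises(self, fitted, tmp_path):
        path = tmp_path / "log.json"
        fitted["log"].save(path)
        loaded = json.loads(path.read_text())
        assert loaded["epochs"] == fitted["log"].epochs


class TestSchedulerAndStopping:
    def test_lr_is_initial_times_factor_power(self):
        nn.seed(0)
        params = [nn.Parameter(np.zeros(1))]
        opt = Adam(params, lr=1e-4)
        sched = ReduceLROnPlateau(opt, mode="max", factor=0.1, patience=2)
        metrics = [0.5, 0.4, 0.4,          # 2 bad epochs -> first drop
                   0.4, 0.4,               # 2 more -> second drop
                   0.9]                    # recovery
        drops = sum(sched.step(m) for m in metrics)
        assert drops == 2
        assert opt.lr == pytest.approx(1e-4 * 0.1 ** 2)

    def test_early_stopping_fires_within_patience_of_best(self):
        stop = EarlyStopping(mode="max", patience=3)
        history = [0.6, 0.7, 0.65, 0.66, 0.64]
        fired_at = None
        for epoch, m in enumerate(history):
            if stop.step(m, epoch):
                fired_at = epoch
                break
        assert fired_at == 4 and stop.best_epoch == 1

    def test_early_stopping_counter_resets_on_improvement(self):
        stop = EarlyStopping(mode="max", patience=2)
        assert not stop.step(0.5, 0)
        assert not stop.step(0.4, 1)
        assert not stop.step(0.6, 2)   # improvement resets the counter
        assert not stop.step(0.5, 3)
        assert stop.step(0.5, 4)


class TestCheckpoint:
    def test_roundtrip_preserves_predictions(self, fitted, rng):
        model2, config2 = load_checkpoint(fitted["ckpt"])
        x = rng.standard_normal((2, 3, 64, 64)).astype(np.float32)
        np.testing.assert_array_equal(fitted["model"].predict_proba(x),
                                      model2.predict_proba(x))
        assert config2 == fitted["config"]

    def test_checkpoint_contains_config_echo_and_version(self, fitted):
        with np.load(fitted["ckpt"], allow_pickle=False) as data:
            meta = json.loads(str(data["__meta__"]))
        assert meta["config"]["alpha"] == 0.1
        assert "version" in meta


class TestEvaluate:
    def test_untrained_model_scores_near_chance(self, tmp_path_factory):
        out = tmp_path_factory.mktemp("null")
        csv = generate_synthetic_dataset(
            SyntheticSpec(n_images=1000, image_size=64, seed=5,
                          prevalence=np.full(14, 0.5)), out)
        records = read_chestxray14_csv(csv)
        config = _smoke_config(seed=123)
        model = config.build_model()
        report = evaluate(model, records, config)
        mean_row = report[report["class"] == "Mean"].auc.iloc[0]
        assert 0.45 <= mean_row <= 0.55

    def test_fitted_model_train_split_not_worse_than_validation(self, fitted):
        cfg = fitted["config"]
        tr = evaluate(fitted["model"], fitted["train"], cfg)
        va = evaluate(fitted["model"], fitted["val"], cfg)
        tr_mean = tr[tr["class"] == "Mean"].auc.iloc[0]
        va_mean = va[va["class"] == "Mean"].auc.iloc[0]
        assert tr_mean >= va_mean - 0.02

    def test_report_has_one_row_per_class_plus_mean(self, fitted):
        report = evaluate(fitted["model"], fitted["val"], fitted["config"])
        assert len(report) == 15
        assert report["class"].iloc[-1] == "Mean"

    def test_class_count_mismatch_rejected(self, fitted):
        bad = [dataclasses.replace(r, labels=r.labels[:5])
               for r in fitted["val"][:4]]
        with pytest.raises(ValueError, match="class-list mismatch"):
            evaluate(fitted["model"], bad, fitted["config"])


class TestPredict:
    def test_probabilities_and_sorted_top6(self, fitted):
        paths = [r.image_path for r in fitted["val"][:3]]
        table = predict(fitted["model"], paths, fitted["config"])
        assert len(table) == 3
        probs = table.iloc[0, 1:15].to_numpy(dtype=float)
        assert np.all((probs > 0) & (probs < 1))
        top = [float(item.split(":")[1])
               for item in table.top_predictions.iloc[0].split("; ")]
        assert len(top) == 6
        assert all(a >= b for a, b in zip(top, top[1:]))

    def test_identical_image_gives_identical_rows(self, fitted):
        path = fitted["val"][0].image_path
        table = predict(fitted["model"], [path, path], fitted["config"])
        assert table.iloc[0, 1:].equals(table.iloc[1, 1:])

    def test_unreadable_image_skipped_with_warning(self, fitted, tmp_path, caplog):
        bad = tmp_path / "bad.png"
        bad.write_bytes(b"nope")
        import logging
        with caplog.at_level(logging.WARNING, logger="mbranet.training"):
            table = predict(fitted["model"], [bad], fitted["config"])
        assert len(table) == 0
        assert any("skipping unreadable" in r.message for r in caplog.records)


class TestConfigPlumbing:
    def test_yaml_load_with_overrides(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("learning_rate: 0.002\nalpha: 0.05\nlambdas: [0.5, 0.4, 0.3, 0.1]\n")
        cfg = load_train_config(path, batch_size=8)
        assert cfg.learning_rate == 0.002 and cfg.alpha == 0.05
        assert cfg.batch_size == 8 and cfg.lambdas == (0.5, 0.4, 0.3, 0.1)

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("learning_rte: 0.1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            load_train_config(path)

    def test_component_counts_are_consistent(self):
        counts = count_components(TrainConfig(attention="ca"))
        assert counts["attention"] == 135_496
        assert counts["total"] == sum(v for k, v in counts.items() if k != "total")


def test_cli_make_synthetic_and_count_params(tmp_path):
    from click.testing import CliRunner
    from mbranet.cli import main
    runner = CliRunner()
    res = runner.invoke(main, ["make-synthetic", str(tmp_path / "d"),
                               "--n-images", "3", "--image-size", "64"])
    assert res.exit_code == 0, res.output
    assert (tmp_path / "d" / "labels.csv").exists()
    res = runner.invoke(main, ["count-params", "--model-scale", "reduced"])
    assert res.exit_code == 0, res.output
    assert "total" in res.output
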