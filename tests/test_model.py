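import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from m6awin.autograd import Tensor
from m6awin.dataset import BuilderConfig, build_dataset
from m6awin.encode import encode_batch
from m6awin.model import (
    ModelConfig,
    build_model,
    grid_search_cv,
    load_model,
    save_model,
    train,
    _make_window,
)
from m6awin.simulate import SimConfig, simulate

TOY = dict(filter_sizes=(4, 3), filter_counts=(4, 3), blstm_units=4,
           fc_units=4, dropout_rate=0.0, batch_size=16, max_epochs=2,
           patience=2)


def random_windows(n, length, rng, positive_fraction=0.5):
    windows = []
    for i in range(n):
        seq = "".join(rng.choice(list("ACGU"), length))
        label = 1.0 if i < n * positive_fraction else 0.0
        windows.append(_make_window(seq, label, i))
    return windows


class TestConfig:
    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            ModelConfig(filter_counts=(0, 8))
        with pytest.raises(ValueError):
            ModelConfig(dropout_rate=1.0)
        with pytest.raises(ValueError):
            ModelConfig(patience=60, max_epochs=50)
        with pytest.raises(ValueError):
            ModelConfig(blstm_reduction="max")


class TestForward:
    def test_scores_in_unit_interval(self, rng):
        model = build_model(ModelConfig(seed=0, **TOY))
        seqs = ["".join(rng.choice(list("ACGU"), 101)) for _ in range(8)]
        scores = model.predict_proba(seqs)
        assert np.all((scores > 0) & (scores < 1))

    def test_all_n_sequence_scores_without_error(self):
        model = build_model(ModelConfig(seed=0, **TOY))
        assert 0 < model.predict_proba(["N" * 60])[0] < 1

    def test_maxpool_halves_positions(self):
        cfg = ModelConfig(seed=0, **{**TOY, "maxpool": 2})
        model = build_model(cfg)
        # window 101, filters (4,3), pad 2: 101+4-4+1=102 -> 51 -> 49 -> 24
        assert model._feature_lengths(np.array([101]))[0] == 24
        assert 0 < model.predict_proba(["A" * 101])[0] < 1

    def test_batch_size_invariance(self, rng):
        model = build_model(ModelConfig(seed=1, **TOY))
        seqs = ["".join(rng.choice(list("ACGU"), 101)) for _ in range(10)]
        one_by_one = np.array([model.predict_proba([s])[0] for s in seqs])
        batched = model.predict_proba(seqs)
        np.testing.assert_allclose(one_by_one, batched, atol=1e-6)

    def test_determinism_same_input(self, rng):
        model = build_model(ModelConfig(seed=1, **TOY))
        seqs = ["".join(rng.choice(list("ACGU"), 101)) for _ in range(4)]
        np.testing.assert_array_equal(
            model.predict_proba(seqs), model.predict_proba(seqs)
        )

    def test_padding_neutrality(self, rng):
        """Extra all-zero pad columns beyond the required pad leave scores
        unchanged (valid conv + length-aware BLSTM)."""
        model = build_model(ModelConfig(seed=2, **TOY))
        seq = "".join(rng.choice(list("ACGU"), 60))
        x, lengths = encode_batch([seq], 4)
        base = model.forward(Tensor(x), lengths).data
        padded = np.concatenate([x, np.zeros((1, 4, 7))], axis=2)
        extra = model.forward(Tensor(padded), lengths).data
        np.testing.assert_allclose(base, extra, atol=1e-12)

    @pytest.mark.parametrize("reduction", ["final", "mean", "flatten"])
    def test_reductions_forward(self, reduction, rng):
        cfg = ModelConfig(seed=0, **{**TOY, "blstm_reduction": reduction})
        model = build_model(cfg)
        seqs = ["".join(rng.choice(list("ACGU"), 101)) for _ in range(3)]
        assert model.predict_proba(seqs).shape == (3,)


class TestTrain:
    def test_smoke_trains_on_50_windows(self, rng):
        windows = random_windows(50, 40, rng)
        cfg = ModelConfig(seed=0, **TOY)
        model = build_model(cfg)
        record = train(model, windows, windows[:20], cfg)
        assert record.stopped_epoch <= cfg.max_epochs
        assert record.best_epoch <= record.stopped_epoch
        assert len(record.train_loss) == record.stopped_epoch

    def test_single_class_raises(self, rng):
        windows = random_windows(20, 40, rng, positive_fraction=1.0)
        cfg = ModelConfig(seed=0, **TOY)
        with pytest.raises(ValueError, match="single class"):
            train(build_model(cfg), windows, windows, cfg)

    def test_reproducible_loss_trajectory(self, rng):
        windows = random_windows(40, 40, rng)
        cfg = ModelConfig(seed=7, **{**TOY, "max_epochs": 3, "patience": 3})
        records = [
            train(build_model(cfg), windows, windows[:16], cfg) for _ in range(2)
        ]
        assert records[0].train_loss == records[1].train_loss
        assert records[0].val_loss == records[1].val_loss

    def test_early_stop_on_noise(self, rng):
        windows = random_windows(40, 30, rng)
        cfg = ModelConfig(
            seed=0, **{**TOY, "max_epochs": 30, "patience": 2,
                       "learning_rate": 1e-5}
        )
        record = train(build_model(cfg), windows, windows[:16], cfg)
        assert record.stopped_epoch < 30

    def test_null_data_auroc_near_half(self):
        """No planted motif => test AUROC compatible with chance."""
        sim = simulate(
            SimConfig(n_transcripts=150, seed=5, sites_min=1, sites_max=1,
                      plant_probability=0.0)
        )
        built = build_dataset(sim.fasta, sim.sites, BuilderConfig(seed=5))
        cfg = ModelConfig(
            seed=5, filter_counts=(8, 4), blstm_units=8, fc_units=8,
            batch_size=32, learning_rate=1e-2, blstm_reduction="mean",
            max_epochs=6, patience=6, dropout_rate=0.1,
        )
        model = build_model(cfg)
        train(model, built.subset("train"), built.subset("val"), cfg)
        hold = built.subset("test") + built.subset("val")
        y = np.array([w.label == "positive" for w in hold], float)
        auroc = roc_auc_score(y, model.predict_proba([w.sequence for w in hold]))
        assert 0.4 <= auroc <= 0.6


class TestGridSearch:
    def test_single_setting(self, rng):
        windows = random_windows(50, 30, rng)
        base = ModelConfig(seed=0, **TOY)
        best, table = grid_search_cv(windows, [{"fc_units": 4}], k=5,
                                     base_config=base)
        assert best.fc_units == 4
        assert len(table) == 1
        assert 0 <= table[0]["mean_auroc"] <= 1

    def test_zero_learning_rate_loses(self, sim_small, dataset_small):
        windows = dataset_small.subset("train")[:120]
        base = ModelConfig(
            seed=0, filter_counts=(8, 4), blstm_units=8, fc_units=8,
            batch_size=32, blstm_reduction="mean", max_epochs=4, patience=4,
            dropout_rate=0.0,
        )
        grid = [{"learning_rate": 0.0}, {"learning_rate": 1e-2}]
        best, table = grid_search_cv(windows, grid, k=3, base_config=base)
        assert best.learning_rate == 1e-2
        assert table[1]["mean_auroc"] > table[0]["mean_auroc"]

    def test_empty_grid_raises(self, rng):
        with pytest.raises(ValueError):
            grid_search_cv(random_windows(20, 30, rng), [], k=2)


class TestCheckpoint:
    def test_round_trip_predictions_identical(self, tmp_path, rng):
        cfg = ModelConfig(seed=4, **TOY)
        model = build_model(cfg)
        seqs = ["".join(rng.choice(list("ACGU"), 101)) for _ in range(5)]
        before = model.predict_proba(seqs)
        path = tmp_path / "model.ckpt"
        save_model(model, path, metrics={"note": 1})
        loaded = load_model(path)
        np.testing.assert_array_equal(loaded.predict_proba(seqs), before)
        for key, value in model.state_dict().items():
            np.testing.assert_array_equal(loaded.state_dict()[key], value)
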