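"""Architecture fidelity, parameter counting, backprop correctness and the
training recipe (early stopping, LR finder, grid enumeration)."""

import numpy as np
import pandas as pd
import pytest

from radarvitals import nn
from radarvitals import model as mdl
from radarvitals.features import SegmentDataset


def _fake_dataset(n=64, width=100, seed=0, n_freqs=16, rec_id=0, encode=True):
    """Synthetic segments whose 1D mean value encodes the labels."""
    rng = np.random.default_rng(seed)
    y = np.stack([rng.uniform(10, 20, n), rng.uniform(60, 100, n)], axis=1)
    x1 = rng.normal(0, 0.1, (n, width)).astype(np.float32)
    if encode:
        # mean level encodes RR, linear slope encodes HR
        ramp = np.linspace(-1, 1, width, dtype=np.float32)
        x1 += ((y[:, :1] - 15) / 5).astype(np.float32)
        x1 += ramp[None, :] * ((y[:, 1:2] - 80) / 20).astype(np.float32)
    x2 = rng.normal(0, 0.1, (n, n_freqs, width)).astype(np.float32)
    return SegmentDataset(
        x1d=x1, x2d=x2, y=y, artifact=np.zeros(n, bool),
        t_end=np.arange(n, dtype=float), recording_id=np.full(n, rec_id),
        split_tag="",
    )


class TestArchitecture:
    """The stride-2 valid convolutions and stride-1 pools must reproduce the
    reference feature-map chain for the 15 s / 128-filter configuration."""

    @pytest.fixture(scope="class")
    def summary(self):
        model = mdl.build_model(mdl.ModelConfig())
        return mdl.count_parameters(model)

    @pytest.mark.parametrize(
        "layer,shape",
        [
            ("Conv 1D_1", (1, 149)), ("Max pool 1D_1", (1, 148)),
            ("Conv 1D_2", (1, 73)), ("Max pool 1D_2", (1, 72)),
            ("Conv 1D_3", (1, 35)), ("Max pool 1D_3", (1, 34)),
            ("Conv 2D_1", (61, 149)), ("Max pool 2D_1", (60, 148)),
            ("Conv 2D_2", (29, 73)), ("Max pool 2D_2", (28, 72)),
            ("Conv 2D_3", (13, 35)), ("Max pool 2D_3", (12, 34)),
            ("Flatten 1D", (4352,)), ("Flatten 2D", (52224,)),
        ],
    )
    def test_feature_map_shapes(self, summary, layer, shape):
        _, table = summary
        assert tuple(table.set_index("name").loc[layer, "output_shape"]) == shape

    @pytest.mark.parametrize(
        "layer,count",
        [
            ("Conv 1D_1", 512), ("BatchNorm 1D_1", 256),
            ("Conv 1D_2", 49_280), ("Conv 1D_3", 49_280),
            ("Conv 2D_1", 1_280), ("BatchNorm 2D_1", 256),
            ("Conv 2D_2", 147_584), ("Conv 2D_3", 147_584),
            ("1D FC_1", 43_530), ("2D FC_2", 522_250), ("Output", 42),
        ],
    )
    def test_parameter_counts(self, summary, layer, count):
        _, table = summary
        assert int(table.set_index("name").loc[layer, "n_params"]) == count

    def test_total_is_per_layer_sum(self, summary):
        total, table = summary
        assert total == table["n_params"].sum() == 962_878

    def test_closed_form_counts_for_other_configs(self):
        for cfg in (mdl.ModelConfig(branches="1d", n_conv_layers=2, n_filters=64),
                    mdl.ModelConfig(branches="2d", n_conv_layers=1, n_filters=32,
                                    window_s=10)):
            total, table = mdl.count_parameters(mdl.build_model(cfg))
            f = cfg.n_filters
            expected = 0
            k = 3 if cfg.branches == "1d" else 9
            cin = 1
            for _ in range(cfg.n_conv_layers):
                expected += k * cin * f + f + 2 * f     # conv + batchnorm
                cin = f
            flat = int(np.prod(table.set_index("name").loc[
                f"Flatten {cfg.branches.upper()}", "output_shape"]))
            expected += flat * 10 + 10                  # branch FC
            expected += 10 * 2 + 2                      # output head
            assert total == expected

    def test_window_too_short_for_depth_names_failing_layer(self):
        with pytest.raises(ValueError, match="2D_3"):
            mdl.build_model(mdl.ModelConfig(n_conv_layers=3), n_freqs=16)
        with pytest.raises(ValueError, match="2D_2"):
            mdl.build_model(mdl.ModelConfig(n_conv_layers=3), n_freqs=8)

    def test_config_grid_validation(self):
        with pytest.raises(ValueError, match="n_filters"):
            mdl.ModelConfig(n_filters=48)
        with pytest.raises(ValueError, match="branches"):
            mdl.ModelConfig(branches="3d")
        with pytest.raises(ValueError, match="window_s"):
            mdl.ModelConfig(window_s=20)


class TestBackprop:
    def test_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        m = mdl.build_model(
            mdl.ModelConfig(branches="1d+2d", n_conv_layers=2, n_filters=32,
                            window_s=5),
            n_freqs=16, dtype=np.float64, seed=1,
        )
        x1 = rng.normal(size=(3, 100))
        x2 = rng.normal(size=(3, 16, 100))
        y = rng.normal(size=(3, 2))
        pred = m.forward(x1, x2, train=True)
        m.backward(pred - y)   # gradient of 0.5*||pred-y||^2

        def loss():
            return 0.5 * np.sum((m.forward(x1, x2, train=True) - y) ** 2)

        eps = 1e-6
        for layer in m.layers():
            for key, p in layer.params.items():
                flat = p.ravel()
                for i in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                    old = flat[i]
                    flat[i] = old + eps
                    lp = loss()
                    flat[i] = old - eps
                    lm = loss()
                    flat[i] = old
                    num = (lp - lm) / (2 * eps)
                    ana = layer.grads[key].ravel()[i]
                    assert num == pytest.approx(ana, rel=1e-4, abs=1e-7), (
                        f"{layer.name}.{key}[{i}]"
                    )

    def test_maxpool_routes_gradient_to_first_max(self):
        pool = nn.MaxPool1D()
        x = np.array([[[1.0], [1.0], [0.5]]])
        out = pool.forward(x)
        assert np.allclose(out[0, :, 0], [1.0, 1.0])
        dx = pool.backward(np.ones_like(out))
        assert np.allclose(dx[0, :, 0], [1.0, 1.0, 0.0])   # ties -> earlier


class _ScriptedModel:
    """Stand-in whose validation error follows a fixed per-epoch schedule;
    isolates the early-stopping arithmetic from optimization dynamics."""

    def __init__(self, schedule):
        self.schedule = list(schedule)
        self.config = mdl.ModelConfig(branches="1d", n_conv_layers=1,
                                      n_filters=32, window_s=5)
        self.epoch = 0

    def layers(self):
        return []

    def state(self):
        return [{"epoch": self.epoch}]

    def load_state(self, state):
        self.restored_epoch = state[0]["epoch"]

    def forward(self, x1, x2, train=False):
        n = (x1 if x1 is not None else x2).shape[0]
        if train:       # one batch per epoch in these tests
            self.epoch += 1
            return np.zeros((n, 2))
        return np.full((n, 2), self.schedule[self.epoch - 1], dtype=float)

    def backward(self, dout):
        pass


class TestTraining:
    def test_patience_counts_consecutive_stalls(self):
        # improvements at epochs 1..3, plateau after: stop at epoch 10
        ds = _fake_dataset(32, seed=1, encode=False)
        val = _fake_dataset(16, seed=2, rec_id=1, encode=False)
        val.y[:] = 0.0
        ds.y[:] = 0.0
        m = _ScriptedModel([5, 4, 3] + [3] * 47)
        tc = mdl.TrainConfig(max_epochs=50, patience=7, lr=1e-3,
                             batch_size=64, seed=0)
        tr = mdl.train(m, ds, val, tc)
        assert tr.best_epoch == 3
        assert len(tr.history) == 10
        assert m.restored_epoch == 3

    def test_strictly_improving_runs_all_epochs(self):
        ds = _fake_dataset(32, seed=1, encode=False)
        val = _fake_dataset(16, seed=2, rec_id=1, encode=False)
        val.y[:] = 0.0
        ds.y[:] = 0.0
        m = _ScriptedModel(list(range(50, 0, -1)))
        tc = mdl.TrainConfig(max_epochs=50, patience=7, lr=1e-3,
                             batch_size=64, seed=0)
        tr = mdl.train(m, ds, val, tc)
        assert tr.best_epoch == 50
        assert len(tr.history) == 50

    def test_trains_past_mean_baseline_and_reverts_best(self):
        ds = _fake_dataset(192, seed=3)
        val = _fake_dataset(64, seed=4, rec_id=1)
        m = mdl.build_model(mdl.ModelConfig(branches="1d", n_conv_layers=1,
                                            n_filters=32, window_s=5), n_freqs=16)
        tc = mdl.TrainConfig(max_epochs=25, patience=7, lr=2e-3, batch_size=32, seed=0)
        tr = mdl.train(m, ds, val, tc)
        base_rr = np.mean(np.abs(val.y[:, 0] - ds.y[:, 0].mean()))
        base_hr = np.mean(np.abs(val.y[:, 1] - ds.y[:, 1].mean()))
        best = tr.history.iloc[tr.best_epoch - 1]
        assert best["val_rr_mae"] < base_rr
        assert best["val_hr_mae"] < base_hr
        assert tr.best_epoch == int(tr.history["val_monitor"].idxmin()) + 1
        # restored weights reproduce the best-epoch validation error
        pred = mdl.predict(tr, val)
        rr = np.mean(np.abs(pred[:, 0] - val.y[:, 0]))
        assert rr == pytest.approx(best["val_rr_mae"], rel=1e-5)

    def test_shared_recordings_between_splits_rejected(self):
        ds = _fake_dataset(32, rec_id=0)
        m = mdl.build_model(mdl.ModelConfig(branches="1d", n_conv_layers=1,
                                            n_filters=32, window_s=5), n_freqs=16)
        with pytest.raises(ValueError, match="share recordings"):
            mdl.train(m, ds, ds, mdl.TrainConfig(lr=1e-3))

    def test_patience_must_be_under_max_epochs(self):
        with pytest.raises(ValueError, match="patience"):
            mdl.TrainConfig(max_epochs=5, patience=7)


class TestLrFind:
    def _model(self):
        return mdl.build_model(mdl.ModelConfig(branches="1d", n_conv_layers=1,
                                               n_filters=32, window_s=5), n_freqs=16)

    def test_returned_rate_is_stable(self):
        ds = _fake_dataset(128, seed=5)
        lr = mdl.lr_find(self._model(), ds, batch_size=32, seed=0)
        assert 1e-6 < lr <= 1.0
        # retraining briefly at the returned rate reduces the loss
        m = self._model()
        tc = mdl.TrainConfig(max_epochs=9, patience=8, lr=lr, batch_size=32, seed=0)
        tr = mdl.train(m, ds, _fake_dataset(32, seed=6, rec_id=1), tc)
        assert tr.history["train_loss"].iloc[-1] < tr.history["train_loss"].iloc[0]

    def test_never_exploding_sweep_returns_max_decade_below(self):
        ds = _fake_dataset(64, seed=7)
        lr = mdl.lr_find(self._model(), ds, batch_size=32, seed=0,
                         explode_ratio=1e9, max_lr=1.0)
        assert lr == pytest.approx(0.1, rel=0.3)

    def test_non_finite_start_rejected(self):
        m = self._model()
        for layer in m.layers():
            for p in layer.params.values():
                p.fill(np.inf)
        with pytest.raises(ValueError, match="non-finite"):
            mdl.lr_find(m, _fake_dataset(64), batch_size=32)

    def test_empty_data_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mdl.lr_find(self._model(), _fake_dataset(0))


class TestPredict:
    @pytest.fixture(scope="class")
    def trained(self):
        ds = _fake_dataset(64, seed=8)
        val = _fake_dataset(32, seed=9, rec_id=1)
        m = mdl.build_model(mdl.ModelConfig(branches="1d", n_conv_layers=1,
                                            n_filters=32, window_s=5), n_freqs=16)
        return mdl.train(m, ds, val,
                         mdl.TrainConfig(max_epochs=9, patience=8, lr=1e-3,
                                         batch_size=32, seed=0))

    def test_one_pair_per_segment(self, trained):
        ds = _fake_dataset(17, seed=10)
        assert mdl.predict(trained, ds).shape == (17, 2)

    def test_duplicated_segment_identical_and_positive(self, trained):
        ds = _fake_dataset(4, seed=11)
        dup = ds.subset(np.array([0, 0, 1, 2]))
        pred = mdl.predict(trained, dup)
        assert np.array_equal(pred[0], pred[1])
        assert np.all(pred >= 0)

    def test_shape_mismatch_rejected(self, trained):
        ds = _fake_dataset(4, width=60, seed=12)
        with pytest.raises(ValueError, match="window"):
            mdl.predict(trained, ds)


class TestGridSearch:
    def test_full_space_has_81_distinct_configurations(self):
        space = mdl.enumerate_space()
        assert len(space) == 81
        assert len(set(space)) == 81
        assert (len(mdl.LAYER_GRID) * len(mdl.FILTER_GRID)
                * len(mdl.BRANCH_GRID) * len(mdl.WINDOW_GRID_S)) == 81

    def test_smoke_grid_single_row(self):
        ds = _fake_dataset(48, seed=13)
        val = _fake_dataset(24, seed=14, rec_id=1)
        space = mdl.GridSpace(layers=(1,), filters=(32,), branches=("1d",),
                              windows_s=(5,))
        tc = mdl.TrainConfig(max_epochs=8, patience=7, lr=1e-3, batch_size=24, seed=0)
        best, table = mdl.grid_search(ds, val, space=space, train_cfg=tc)
        assert len(table) == 1
        assert best == mdl.ModelConfig(branches="1d", n_conv_layers=1,
                                       n_filters=32, window_s=5)

    def test_cleaner_labels_win(self):
        rng = np.random.default_rng(15)
        clean = _fake_dataset(96, seed=16)
        noisy = _fake_dataset(96, seed=16)
        noisy.y = noisy.y + rng.normal(0, 30, noisy.y.shape)   # garbled labels
        val = _fake_dataset(48, seed=17, rec_id=1)
        tc = mdl.TrainConfig(max_epochs=9, patience=8, lr=1e-3, batch_size=32, seed=0)
        cfg = mdl.ModelConfig(branches="1d", n_conv_layers=1, n_filters=32, window_s=5)
        err = {}
        for tag, ds in (("clean", clean), ("noisy", noisy)):
            tr = mdl.train(mdl.build_model(cfg, n_freqs=16, seed=0), ds, val, tc)
            best = tr.history.iloc[tr.best_epoch - 1]
            err[tag] = best["val_rr_mae"] + best["val_hr_mae"]
        assert err["clean"] < err["noisy"]
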