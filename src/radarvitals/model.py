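"""Dual-branch 1D/2D CNN regressor for respiration and heart rate.

Each branch stacks ``n_conv_layers`` blocks of
[conv (kernel 3 per spatial dim, stride 2, valid) -> batch norm -> ReLU ->
max pool (kernel 2, stride 1)], flattens, and maps to 10 units with ReLU;
branch outputs are concatenated and a final linear layer emits (RR, HR).
The stride/padding/pooling combination is fixed by the reference feature-map
chain 300 -> 149 -> 148 -> 73 -> 72 -> 35 -> 34 (1D) and
123x300 -> 61x149 -> ... -> 12x34 (2D).

Training follows the recipe: Adam, MAE loss, learning rate from an
exponential LR-finder sweep starting at 1e-5, at most 50 epochs, early
stopping after 7 epochs without validation improvement, weights reverted to
the best epoch. Targets are z-scored internally (train-set statistics) so
the shared MAE loss weighs RR and HR comparably; predictions are returned
in RPM/BPM.
"""

from __future__ import annotations

import copy
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import nn
from .features import SegmentDataset

__all__ = [
    "LAYER_GRID", "FILTER_GRID", "BRANCH_GRID", "WINDOW_GRID_S",
    "ModelConfig", "TrainConfig", "TrainedModel", "VitalsCNN",
    "build_model", "count_parameters", "lr_find", "train", "predict",
    "enumerate_space", "grid_search",
]

LAYER_GRID = (1, 2, 3)
FILTER_GRID = (32, 64, 128)
BRANCH_GRID = ("1d", "2d", "1d+2d")
WINDOW_GRID_S = (5, 10, 15)


@dataclass(frozen=True)
class ModelConfig:
    branches: str = "1d+2d"
    n_conv_layers: int = 3
    n_filters: int = 128
    window_s: int = 15

    def __post_init__(self) -> None:
        if self.branches not in BRANCH_GRID:
            raise ValueError(f"branches must be one of {BRANCH_GRID}, got {self.branches!r}")
        if self.n_conv_layers not in LAYER_GRID:
            raise ValueError(f"n_conv_layers must be in {LAYER_GRID}, got {self.n_conv_layers}")
        if self.n_filters not in FILTER_GRID:
            raise ValueError(f"n_filters must be in {FILTER_GRID}, got {self.n_filters}")
        if self.window_s not in WINDOW_GRID_S:
            raise ValueError(f"window_s must be in {WINDOW_GRID_S}, got {self.window_s}")


@dataclass
class TrainConfig:
    max_epochs: int = 50
    patience: int = 7
    lr: float | None = None          # None -> learning-rate finder
    lr_finder_start: float = 1e-5
    batch_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("early-stop patience must be smaller than max_epochs")


class VitalsCNN:
    """The network; branch composition follows ``ModelConfig``."""

    def __init__(self, config: ModelConfig, n_freqs: int = 123,
                 frame_rate: float = 20.0, seed: int = 0, dtype=np.float32) -> None:
        self.config = config
        self.n_freqs = n_freqs
        self.input_len = int(round(config.window_s * frame_rate))
        rng = np.random.default_rng(seed)
        F = config.n_filters
        self.branch1d: list[nn.Layer] = []
        self.branch2d: list[nn.Layer] = []
        self._summary: list[dict] = []

        self.use_1d = config.branches in ("1d", "1d+2d")
        self.use_2d = config.branches in ("2d", "1d+2d")

        if self.use_1d:
            L = self.input_len
            self._summary.append({"name": "Input 1D", "output_shape": (1, L), "n_params": 0})
            cin = 1
            for i in range(1, config.n_conv_layers + 1):
                conv = nn.Conv1D(cin, F, rng=rng, dtype=dtype, name=f"Conv 1D_{i}")
                L = conv.out_length(L)
                self._summary.append({"name": conv.name, "output_shape": (1, L),
                                      "n_params": conv.n_params()})
                bn = nn.BatchNorm(F, dtype=dtype, name=f"BatchNorm 1D_{i}")
                self._summary.append({"name": bn.name, "output_shape": (1, L),
                                      "n_params": bn.n_params()})
                relu = nn.ReLU(name=f"ReLU 1D_{i}")
                pool = nn.MaxPool1D(name=f"Max pool 1D_{i}")
                if L < 2:
                    raise ValueError(f"{pool.name}: feature length {L} too short to pool")
                L -= 1
                self._summary.append({"name": pool.name, "output_shape": (1, L), "n_params": 0})
                self.branch1d += [conv, bn, relu, pool]
                cin = F
            flat = F * L
            self._summary.append({"name": "Flatten 1D", "output_shape": (flat,), "n_params": 0})
            fc = nn.Dense(flat, 10, rng=rng, dtype=dtype, name="1D FC_1")
            self._summary.append({"name": fc.name, "output_shape": (10,),
                                  "n_params": fc.n_params()})
            self.branch1d += [nn.Flatten(name="Flatten 1D"), fc, nn.ReLU(name="ReLU FC 1D")]

        if self.use_2d:
            H, W = n_freqs, self.input_len
            self._summary.append({"name": "Input 2D", "output_shape": (H, W), "n_params": 0})
            cin = 1
            for i in range(1, config.n_conv_layers + 1):
                conv = nn.Conv2D(cin, F, rng=rng, dtype=dtype, name=f"Conv 2D_{i}")
                H, W = conv.out_shape(H, W)
                self._summary.append({"name": conv.name, "output_shape": (H, W),
                                      "n_params": conv.n_params()})
                bn = nn.BatchNorm(F, dtype=dtype, name=f"BatchNorm 2D_{i}")
                self._summary.append({"name": bn.name, "output_shape": (H, W),
                                      "n_params": bn.n_params()})
                relu = nn.ReLU(name=f"ReLU 2D_{i}")
                pool = nn.MaxPool2D(name=f"Max pool 2D_{i}")
                if H < 2 or W < 2:
                    raise ValueError(f"{pool.name}: feature map {H}x{W} too small to pool")
                H, W = H - 1, W - 1
                self._summary.append({"name": pool.name, "output_shape": (H, W), "n_params": 0})
                self.branch2d += [conv, bn, relu, pool]
                cin = F
            flat = F * H * W
            self._summary.append({"name": "Flatten 2D", "output_shape": (flat,), "n_params": 0})
            fc = nn.Dense(flat, 10, rng=rng, dtype=dtype, name="2D FC_2")
            self._summary.append({"name": fc.name, "output_shape": (10,),
                                  "n_params": fc.n_params()})
            self.branch2d += [nn.Flatten(name="Flatten 2D"), fc, nn.ReLU(name="ReLU FC 2D")]

        n_concat = 10 * (int(self.use_1d) + int(self.use_2d))
        self.head = nn.Dense(n_concat, 2, rng=rng, dtype=dtype, name="Output")
        self._summary.append({"name": "Output", "output_shape": (2,),
                              "n_params": self.head.n_params()})
        self.dtype = dtype

    # -- plumbing -----------------------------------------------------------

    def layers(self) -> list[nn.Layer]:
        return self.branch1d + self.branch2d + [self.head]

    def layer_summary(self) -> pd.DataFrame:
        return pd.DataFrame(self._summary)

    def forward(self, x1d: np.ndarray | None, x2d: np.ndarray | None,
                train: bool = False) -> np.ndarray:
        feats = []
        if self.use_1d:
            h = np.asarray(x1d, dtype=self.dtype)[:, :, None]     # (B, L, 1)
            for layer in self.branch1d:
                h = layer.forward(h, train)
            feats.append(h)
        if self.use_2d:
            h = np.asarray(x2d, dtype=self.dtype)[:, :, :, None]  # (B, H, W, 1)
            for layer in self.branch2d:
                h = layer.forward(h, train)
            feats.append(h)
        self._split = [f.shape[1] for f in feats]
        return self.head.forward(np.concatenate(feats, axis=1), train)

    def backward(self, dout: np.ndarray) -> None:
        dcat = self.head.backward(dout)
        pieces = np.split(dcat, np.cumsum(self._split)[:-1], axis=1)
        idx = 0
        if self.use_1d:
            d = pieces[idx]; idx += 1
            for layer in reversed(self.branch1d):
                d = layer.backward(d)
        if self.use_2d:
            d = pieces[idx]
            for layer in reversed(self.branch2d):
                d = layer.backward(d)

    def copy(self) -> "VitalsCNN":
        return copy.deepcopy(self)

    def state(self) -> list[dict[str, np.ndarray]]:
        out = []
        for l in self.layers():
            s = {k: v.copy() for k, v in l.params.items()}
            if isinstance(l, nn.BatchNorm):
                s["_rm"], s["_rv"] = l.running_mean.copy(), l.running_var.copy()
            out.append(s)
        return out

    def load_state(self, state: list[dict[str, np.ndarray]]) -> None:
        for l, s in zip(self.layers(), state):
            for k in l.params:
                l.params[k][...] = s[k]
            if isinstance(l, nn.BatchNorm):
                l.running_mean[...] = s["_rm"]
                l.running_var[...] = s["_rv"]


def build_model(config: ModelConfig, n_freqs: int = 123, frame_rate: float = 20.0,
                seed: int = 0, dtype=np.float32) -> VitalsCNN:
    return VitalsCNN(config, n_freqs=n_freqs, frame_rate=frame_rate, seed=seed, dtype=dtype)


def count_parameters(model: VitalsCNN) -> tuple[int, pd.DataFrame]:
    """Total learnable parameters and the per-layer breakdown
    (weights + biases + batch-norm scale/shift)."""
    table = model.layer_summary()
    return int(table["n_params"].sum()), table


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


@dataclass
class FeatureScaler:
    """Input standardization fitted on the training split.

    The 1D window is z-scored globally; the scalogram is z-scored per
    frequency row (over segments and time). Row-wise scaling matters: the
    respiration rows carry orders of magnitude more energy than the heart
    band, and without it the weak heart line is numerically invisible to
    the convolutions.
    """

    x1_mean: float = 0.0
    x1_std: float = 1.0
    x2_mean: np.ndarray | None = None   # (n_freqs,)
    x2_std: np.ndarray | None = None

    @classmethod
    def fit(cls, ds: SegmentDataset) -> "FeatureScaler":
        x2m = ds.x2d.mean(axis=(0, 2))
        x2s = ds.x2d.std(axis=(0, 2))
        return cls(
            x1_mean=float(ds.x1d.mean()),
            x1_std=float(ds.x1d.std()) or 1.0,
            x2_mean=x2m.astype(np.float32),
            x2_std=np.where(x2s > 0, x2s, 1.0).astype(np.float32),
        )

    def transform_x1(self, x1: np.ndarray | None) -> np.ndarray | None:
        if x1 is None:
            return None
        return (x1 - self.x1_mean) / self.x1_std

    def transform_x2(self, x2: np.ndarray | None) -> np.ndarray | None:
        if x2 is None or self.x2_mean is None:
            return x2
        return (x2 - self.x2_mean[None, :, None]) / self.x2_std[None, :, None]


@dataclass
class TrainedModel:
    model: VitalsCNN
    config: ModelConfig
    train_config: TrainConfig
    best_epoch: int
    history: pd.DataFrame
    label_mean: np.ndarray
    label_std: np.ndarray
    lr: float
    scaler: FeatureScaler = field(default_factory=FeatureScaler)


def inputs_for(config: ModelConfig, ds: SegmentDataset,
               frame_rate: float = 20.0) -> tuple[np.ndarray | None, np.ndarray | None, np.ndarray]:
    """Slice dataset tensors to the model's window (most recent samples)."""
    w = int(round(config.window_s * frame_rate))
    if ds.x1d.shape[1] < w:
        raise ValueError(f"dataset window {ds.x1d.shape[1]} shorter than model window {w}")
    x1 = ds.x1d[:, -w:] if config.branches in ("1d", "1d+2d") else None
    x2 = ds.x2d[:, :, -w:] if config.branches in ("2d", "1d+2d") else None
    return x1, x2, ds.y


def _forward_batched(model: VitalsCNN, x1, x2, batch_size: int = 256,
                     train: bool = False,
                     scaler: FeatureScaler | None = None) -> np.ndarray:
    scaler = scaler or FeatureScaler()
    n = (x1 if x1 is not None else x2).shape[0]
    out = np.empty((n, 2), dtype=float)
    for s in range(0, n, batch_size):
        sl = slice(s, s + batch_size)
        out[sl] = model.forward(
            scaler.transform_x1(None if x1 is None else x1[sl]),
            scaler.transform_x2(None if x2 is None else x2[sl]),
            train=train,
        )
    return out


def lr_find(model: VitalsCNN, train_ds: SegmentDataset, start: float = 1e-5,
            factor: float = 1.25, max_lr: float = 10.0, batch_size: int = 256,
            seed: int = 0, explode_ratio: float = 1.3) -> float:
    """Exponential learning-rate sweep; returns one decade below explosion.

    A probe model (deep copy) takes one Adam step per mini-batch while the
    learning rate grows geometrically from ``start``. The smoothed loss is
    tracked; the sweep stops when it exceeds ``explode_ratio`` times its
    best value, and the learning rate one decade below that point is
    returned. If the loss never explodes, max-probed / 10 is returned.
    """
    if len(train_ds) == 0:
        raise ValueError("empty training data")
    probe = model.copy()
    scaler = FeatureScaler.fit(train_ds)
    x1, x2, y = inputs_for(model.config, train_ds)
    mu, sd = y.mean(axis=0), y.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    yn = (y - mu) / sd
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train_ds))
    opt = nn.Adam(probe.layers(), lr=start)
    lr = start
    smoothed, best = None, np.inf
    pos = 0
    while lr <= max_lr:
        idx = order[pos : pos + batch_size]
        if idx.size == 0:
            order = rng.permutation(len(train_ds))
            pos = 0
            continue
        pos += batch_size
        pred = probe.forward(
            scaler.transform_x1(None if x1 is None else x1[idx]),
            scaler.transform_x2(None if x2 is None else x2[idx]), train=True)
        loss, dloss = nn.mae_loss(pred, yn[idx])
        if not np.isfinite(loss):
            if smoothed is None:
                raise ValueError("loss non-finite at the starting learning rate")
            return lr / 10.0
        smoothed = loss if smoothed is None else 0.7 * smoothed + 0.3 * loss
        if smoothed < best:
            best = smoothed
        elif smoothed > explode_ratio * best:
            return lr / 10.0
        probe.backward(dloss)
        opt.lr = lr
        opt.step()
        lr *= factor
    return max_lr / 10.0


def train(model: VitalsCNN, train_ds: SegmentDataset, val_ds: SegmentDataset,
          cfg: TrainConfig | None = None) -> TrainedModel:
    """Adam + MAE training with early stopping and best-epoch revert."""
    cfg = cfg or TrainConfig()
    if len(train_ds) == 0 or len(val_ds) == 0:
        raise ValueError("train and validation splits must be non-empty")
    train_ids = set(np.unique(train_ds.recording_id).tolist())
    val_ids = set(np.unique(val_ds.recording_id).tolist())
    if train_ids & val_ids:
        raise ValueError(f"train/val share recordings: {sorted(train_ids & val_ids)}")

    scaler = FeatureScaler.fit(train_ds)
    x1, x2, y = inputs_for(model.config, train_ds)
    vx1, vx2, vy = inputs_for(model.config, val_ds)
    mu, sd = y.mean(axis=0), y.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    yn = (y - mu) / sd

    lr = cfg.lr if cfg.lr is not None else lr_find(
        model, train_ds, start=cfg.lr_finder_start,
        batch_size=cfg.batch_size, seed=cfg.seed,
    )
    opt = nn.Adam(model.layers(), lr=lr)
    rng = np.random.default_rng(cfg.seed)

    history = []
    best_monitor, best_epoch, best_state = np.inf, 0, model.state()
    stall = 0
    n = len(train_ds)
    for epoch in range(1, cfg.max_epochs + 1):
        order = rng.permutation(n)
        losses = []
        for s in range(0, n, cfg.batch_size):
            idx = order[s : s + cfg.batch_size]
            pred = model.forward(
                scaler.transform_x1(None if x1 is None else x1[idx]),
                scaler.transform_x2(None if x2 is None else x2[idx]), train=True)
            loss, dloss = nn.mae_loss(pred, yn[idx])
            model.backward(dloss)
            opt.step()
            losses.append(loss)
        vpred = _forward_batched(model, vx1, vx2, cfg.batch_size,
                                 scaler=scaler) * sd + mu
        val_rr = float(np.mean(np.abs(vpred[:, 0] - vy[:, 0])))
        val_hr = float(np.mean(np.abs(vpred[:, 1] - vy[:, 1])))
        monitor = val_rr / sd[0] + val_hr / sd[1]
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "val_rr_mae": val_rr, "val_hr_mae": val_hr,
                        "val_monitor": monitor})
        if monitor < best_monitor:
            best_monitor, best_epoch, best_state = monitor, epoch, model.state()
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience:
                break
    model.load_state(best_state)
    return TrainedModel(model=model, config=model.config, train_config=cfg,
                        best_epoch=best_epoch, history=pd.DataFrame(history),
                        label_mean=mu, label_std=sd, lr=lr, scaler=scaler)


def predict(trained: TrainedModel, ds_or_inputs, batch_size: int = 256) -> np.ndarray:
    """Per-segment (RR RPM, HR BPM); deterministic at inference."""
    if isinstance(ds_or_inputs, SegmentDataset):
        x1, x2, _ = inputs_for(trained.config, ds_or_inputs)
    else:
        x1, x2 = ds_or_inputs
    out = _forward_batched(trained.model, x1, x2, batch_size, scaler=trained.scaler)
    out = out * trained.label_std + trained.label_mean
    return np.clip(out, 0.0, None)


def save_model(trained: TrainedModel, path) -> None:
    """Checkpoint with the embedded model configuration."""
    import pickle
    with open(path, "wb") as f:
        pickle.dump(trained, f)


def load_model(path) -> TrainedModel:
    import pickle
    with open(path, "rb") as f:
        return pickle.load(f)


# ---------------------------------------------------------------------------
# hyperparameter grid
# ---------------------------------------------------------------------------


@dataclass
class GridSpace:
    layers: tuple = LAYER_GRID
    filters: tuple = FILTER_GRID
    branches: tuple = BRANCH_GRID
    windows_s: tuple = WINDOW_GRID_S


def enumerate_space(space: GridSpace | None = None) -> list[ModelConfig]:
    space = space or GridSpace()
    return [
        ModelConfig(branches=b, n_conv_layers=l, n_filters=f, window_s=w)
        for b, l, f, w in itertools.product(
            space.branches, space.layers, space.filters, space.windows_s
        )
    ]


def grid_search(train_ds: SegmentDataset, val_ds: SegmentDataset,
                space: GridSpace | None = None, train_cfg: TrainConfig | None = None,
                seed: int = 0) -> tuple[ModelConfig, pd.DataFrame]:
    """Train every configuration; select the lowest validation MAE
    (sum of RR and HR errors)."""
    configs = enumerate_space(space)
    rows = []
    for cfg in configs:
        model = build_model(cfg, seed=seed)
        trained = train(model, train_ds, val_ds, train_cfg)
        best = trained.history.iloc[trained.best_epoch - 1]
        rows.append({
            "branches": cfg.branches, "n_conv_layers": cfg.n_conv_layers,
            "n_filters": cfg.n_filters, "window_s": cfg.window_s,
            "val_rr_mae": best["val_rr_mae"], "val_hr_mae": best["val_hr_mae"],
            "val_mae_sum": best["val_rr_mae"] + best["val_hr_mae"],
            "best_epoch": trained.best_epoch,
        })
    table = pd.DataFrame(rows)
    best_cfg = configs[int(table["val_mae_sum"].idxmin())]
    return best_cfg, table
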