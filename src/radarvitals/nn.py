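"""Minimal NumPy neural-network layers with hand-written backpropagation.

Only what the vitals regressor needs: valid-padding strided convolutions
(1D/2D), batch normalization, ReLU, size-2 stride-1 max pooling, dense
layers, MAE loss and Adam. Arrays are channel-last — ``(B, L, C)`` for 1D
and ``(B, H, W, C)`` for 2D — so convolutions reduce to a handful of slice
matmuls.

Every layer implements ``forward(x, train)`` and ``backward(dout)``;
``backward`` fills ``grads`` (same keys as ``params``) and returns the
gradient with respect to the input.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Layer", "Conv1D", "Conv2D", "BatchNorm", "ReLU",
    "MaxPool1D", "MaxPool2D", "Flatten", "Dense",
    "Adam", "mae_loss",
]


class Layer:
    name: str = ""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return int(sum(p.size for p in self.params.values()))


class Conv1D(Layer):
    """Valid convolution, kernel ``k``, stride ``stride`` along axis 1."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 name: str = "conv1d") -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (k * cin))
        self.params = {
            "W": (rng.normal(0.0, std, (k, cin, cout))).astype(dtype),
            "b": np.zeros(cout, dtype=dtype),
        }
        self.k, self.stride, self.name = k, stride, name

    def out_length(self, L: int) -> int:
        if L < self.k:
            raise ValueError(f"{self.name}: input length {L} < kernel {self.k}")
        return (L - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        B, L, C = x.shape
        Lout = self.out_length(L)
        span = self.stride * (Lout - 1) + 1
        cols = np.empty((B, Lout, self.k, C), dtype=x.dtype)
        for o in range(self.k):
            cols[:, :, o, :] = x[:, o : o + span : self.stride, :]
        y = cols.reshape(B * Lout, self.k * C) @ W.reshape(self.k * C, -1)
        self._cols, self._xshape = cols, x.shape
        return y.reshape(B, Lout, -1) + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        B, Lout, F = dout.shape
        span = self.stride * (Lout - 1) + 1
        d2 = dout.reshape(B * Lout, F)
        dW = (self._cols.reshape(B * Lout, -1).T @ d2).reshape(W.shape)
        dcols = (d2 @ W.reshape(-1, F).T).reshape(self._cols.shape)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        for o in range(self.k):
            dx[:, o : o + span : self.stride, :] += dcols[:, :, o, :]
        self.grads = {"W": dW, "b": dout.sum(axis=(0, 1))}
        return dx


class Conv2D(Layer):
    """Valid convolution, ``k x k`` kernel, common stride on both axes."""

    def __init__(self, cin: int, cout: int, k: int = 3, stride: int = 2,
                 rng: np.random.Generator | None = None, dtype=np.float32,
                 name: str = "conv2d") -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / (k * k * cin))
        self.params = {
            "W": (rng.normal(0.0, std, (k, k, cin, cout))).astype(dtype),
            "b": np.zeros(cout, dtype=dtype),
        }
        self.k, self.stride, self.name = k, stride, name

    def out_shape(self, H: int, W_: int) -> tuple[int, int]:
        if H < self.k or W_ < self.k:
            raise ValueError(f"{self.name}: input {H}x{W_} smaller than kernel {self.k}")
        return (H - self.k) // self.stride + 1, (W_ - self.k) // self.stride + 1

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        B, H, W_, C = x.shape
        Ho, Wo = self.out_shape(H, W_)
        sh = self.stride * (Ho - 1) + 1
        sw = self.stride * (Wo - 1) + 1
        cols = np.empty((B, Ho, Wo, self.k * self.k, C), dtype=x.dtype)
        for u in range(self.k):
            for v in range(self.k):
                cols[:, :, :, u * self.k + v, :] = (
                    x[:, u : u + sh : self.stride, v : v + sw : self.stride, :]
                )
        y = cols.reshape(B * Ho * Wo, -1) @ W.reshape(self.k * self.k * C, -1)
        self._cols, self._xshape = cols, x.shape
        return y.reshape(B, Ho, Wo, -1) + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        W = self.params["W"]
        B, Ho, Wo, F = dout.shape
        sh = self.stride * (Ho - 1) + 1
        sw = self.stride * (Wo - 1) + 1
        d2 = dout.reshape(B * Ho * Wo, F)
        dW = (self._cols.reshape(B * Ho * Wo, -1).T @ d2).reshape(W.shape)
        dcols = (d2 @ W.reshape(-1, F).T).reshape(self._cols.shape)
        dx = np.zeros(self._xshape, dtype=dout.dtype)
        for u in range(self.k):
            for v in range(self.k):
                dx[:, u : u + sh : self.stride, v : v + sw : self.stride, :] += (
                    dcols[:, :, :, u * self.k + v, :]
                )
        self.grads = {"W": dW, "b": dout.sum(axis=(0, 1, 2))}
        return dx


class BatchNorm(Layer):
    """Normalizes over every axis but the last (channels)."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float32, name: str = "bn") -> None:
        super().__init__()
        self.params = {"gamma": np.ones(c, dtype=dtype), "beta": np.zeros(c, dtype=dtype)}
        self.running_mean = np.zeros(c, dtype=dtype)
        self.running_var = np.ones(c, dtype=dtype)
        self.momentum, self.eps, self.name = momentum, eps, name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if train:
            mu = x.mean(axis=axes)
            xr = x.reshape(-1, x.shape[-1])
            var = np.einsum("nc,nc->c", xr, xr) / xr.shape[0] - mu * mu
            np.maximum(var, 0.0, out=var)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var).astype(self.running_var.dtype)
        else:
            mu, var = self.running_mean, self.running_var
        ivar = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * ivar
        self._cache = (xhat, ivar, train)
        return self.params["gamma"] * xhat + self.params["beta"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        xhat, ivar, train = self._cache
        axes = tuple(range(dout.ndim - 1))
        dgamma = (dout * xhat).sum(axis=axes)
        dbeta = dout.sum(axis=axes)
        self.grads = {"gamma": dgamma, "beta": dbeta}
        g = self.params["gamma"]
        if not train:
            return dout * g * ivar
        n = dout.size // dout.shape[-1]
        return (g * ivar / n) * (n * dout - dbeta - xhat * dgamma)


class ReLU(Layer):
    def __init__(self, name: str = "relu") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Kernel 2, stride 1: pairwise max of neighbours (length L -> L-1)."""

    def __init__(self, name: str = "pool1d") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        a, b = x[:, :-1, :], x[:, 1:, :]
        self._left = a >= b          # ties route to the earlier position
        self._shape = x.shape
        return np.maximum(a, b)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, :-1, :] += dout * self._left
        dx[:, 1:, :] += dout * ~self._left
        return dx


class MaxPool2D(Layer):
    """2x2 kernel, stride 1 on both axes (H x W -> H-1 x W-1)."""

    def __init__(self, name: str = "pool2d") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        # two-stage pairwise max: width pairs, then height pairs
        a, b = x[:, :, :-1, :], x[:, :, 1:, :]
        self._wleft = a >= b                      # ties -> earlier column
        p = np.maximum(a, b)
        c, d = p[:, :-1, :, :], p[:, 1:, :, :]
        self._hleft = c >= d                      # ties -> earlier row
        self._shape = x.shape
        return np.maximum(c, d)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        B, H, W, C = self._shape
        dp = np.zeros((B, H, W - 1, C), dtype=dout.dtype)
        dp[:, :-1, :, :] += dout * self._hleft
        dp[:, 1:, :, :] += dout * ~self._hleft
        dx = np.zeros(self._shape, dtype=dout.dtype)
        dx[:, :, :-1, :] += dp * self._wleft
        dx[:, :, 1:, :] += dp * ~self._wleft
        return dx


class Flatten(Layer):
    def __init__(self, name: str = "flatten") -> None:
        super().__init__()
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._shape)


class Dense(Layer):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator | None = None,
                 dtype=np.float32, name: str = "dense") -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        std = np.sqrt(2.0 / nin)
        self.params = {
            "W": rng.normal(0.0, std, (nin, nout)).astype(dtype),
            "b": np.zeros(nout, dtype=dtype),
        }
        self.name = name

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.params["W"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {"W": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["W"].T


def mae_loss(pred: np.ndarray, target: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean absolute error and its (sub)gradient w.r.t. ``pred``."""
    diff = pred - target
    return float(np.mean(np.abs(diff))), np.sign(diff) / diff.size


class Adam:
    """Adam over a list of layers (operates on their params/grads dicts)."""

    def __init__(self, layers: list[Layer], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8) -> None:
        self.layers = [l for l in layers if l.params]
        self.lr, self.betas, self.eps = lr, betas, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in l.params.items()} for l in self.layers]

    def step(self) -> None:
        b1, b2 = self.betas
        self.t += 1
        bc1 = 1 - b1**self.t
        bc2 = 1 - b2**self.t
        for layer, m, v in zip(self.layers, self.m, self.v):
            for k, p in layer.params.items():
                g = layer.grads[k]
                m[k] = b1 * m[k] + (1 - b1) * g
                v[k] = b2 * v[k] + (1 - b2) * g * g
                p -= (self.lr * (m[k] / bc1) / (np.sqrt(v[k] / bc2) + self.eps)).astype(p.dtype)
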