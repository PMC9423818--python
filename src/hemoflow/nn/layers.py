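"""Layer implementations: forward passes cache what backward needs.

Convolutions use im2col/col2im so the inner loop is a BLAS matmul; the
transposed convolution is implemented as the exact adjoint of the strided
convolution (its forward is conv's input-gradient and vice versa), which
makes the pair self-consistent under gradient checking.
"""

from __future__ import annotations

import numpy as np

#: working precision; single precision doubles GEMM throughput and is ample
#: for GAN training, while tests may upcast parameters for gradient checks
DTYPE = np.float32


def _conv_out(size: int, k: int, stride: int, pad: int) -> int:
    return (size + 2 * pad - k) // stride + 1


def im2col(x: np.ndarray, k: int, stride: int, pad: int) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, Ho*Wo) patch matrix."""
    n, c, h, w = x.shape
    ho, wo = _conv_out(h, k, stride, pad), _conv_out(w, k, stride, pad)
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s0, s1, s2, s3 = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp,
        shape=(n, c, k, k, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    return np.ascontiguousarray(view).reshape(n, c * k * k, ho * wo)


def col2im(
    cols: np.ndarray, x_shape: tuple[int, int, int, int], k: int, stride: int, pad: int
) -> np.ndarray:
    """Adjoint of im2col: scatter-add patches back to (N, C, H, W)."""
    n, c, h, w = x_shape
    ho, wo = _conv_out(h, k, stride, pad), _conv_out(w, k, stride, pad)
    cols6 = cols.reshape(n, c, k, k, ho, wo)
    xp = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=cols.dtype)
    for i in range(k):
        for j in range(k):
            xp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += (
                cols6[:, :, i, j]
            )
    return xp[:, :, pad : pad + h, pad : pad + w]


class Layer:
    """Base class: parameters/gradients as name->array dicts."""

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(
        self, n_in: int, n_out: int, rng: np.random.Generator, w_sd: float = 0.02
    ) -> None:
        super().__init__()
        self.params = {
            "w": rng.normal(0.0, w_sd, size=(n_in, n_out)).astype(DTYPE),
            "b": np.zeros(n_out, dtype=DTYPE),
        }

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["w"] + self.params["b"]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.grads = {"w": self._x.T @ dout, "b": dout.sum(axis=0)}
        return dout @ self.params["w"].T


class Conv2d(Layer):
    """Strided convolution, kernel k, padding p; weight (Cout, Cin, k, k)."""

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
        w_sd: float = 0.02,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.params = {
            "w": rng.normal(0.0, w_sd, size=(c_out, c_in, k, k)).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x_shape = x.shape
        n, _, h, w = x.shape
        ho = _conv_out(h, self.k, self.stride, self.pad)
        wo = _conv_out(w, self.k, self.stride, self.pad)
        self._cols = im2col(x, self.k, self.stride, self.pad)
        w2 = self.params["w"].reshape(self.c_out, -1)
        out = np.matmul(w2, self._cols).reshape(n, self.c_out, ho, wo)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        dflat = dout.reshape(n, self.c_out, -1)
        dw = np.tensordot(dflat, self._cols, axes=([0, 2], [0, 2])).reshape(
            self.params["w"].shape
        )
        self.grads = {"w": dw, "b": dout.sum(axis=(0, 2, 3))}
        w2 = self.params["w"].reshape(self.c_out, -1)
        dcols = np.matmul(w2.T, dflat)
        return col2im(dcols, self._x_shape, self.k, self.stride, self.pad)


class ConvTranspose2d(Layer):
    """Fractionally-strided convolution; weight (Cin, Cout, k, k).

    Output size is (H-1)*stride - 2*pad + k; with the DCGAN choice
    k=4, stride=2, pad=1 each block exactly doubles the spatial size.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        rng: np.random.Generator,
        k: int = 4,
        stride: int = 2,
        pad: int = 1,
        w_sd: float = 0.02,
    ) -> None:
        super().__init__()
        self.c_in, self.c_out, self.k, self.stride, self.pad = c_in, c_out, k, stride, pad
        self.params = {
            "w": rng.normal(0.0, w_sd, size=(c_in, c_out, k, k)).astype(DTYPE),
            "b": np.zeros(c_out, dtype=DTYPE),
        }

    def _out_shape(self, n: int, h: int, w: int) -> tuple[int, int, int, int]:
        ho = (h - 1) * self.stride - 2 * self.pad + self.k
        wo = (w - 1) * self.stride - 2 * self.pad + self.k
        return (n, self.c_out, ho, wo)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, _, h, w = x.shape
        self._x_flat = x.reshape(n, self.c_in, h * w)
        self._out_shape_cache = self._out_shape(n, h, w)
        w2 = self.params["w"].reshape(self.c_in, -1)  # (Cin, Cout*k*k)
        cols = np.matmul(w2.T, self._x_flat)  # (N, Cout*k*k, h*w)
        out = col2im(cols, self._out_shape_cache, self.k, self.stride, self.pad)
        return out + self.params["b"][None, :, None, None]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n = dout.shape[0]
        dcols = im2col(dout, self.k, self.stride, self.pad)  # (N, Cout*k*k, h*w)
        dw = np.tensordot(self._x_flat, dcols, axes=([0, 2], [0, 2])).reshape(
            self.params["w"].shape
        )
        self.grads = {"w": dw, "b": dout.sum(axis=(0, 2, 3))}
        w2 = self.params["w"].reshape(self.c_in, -1)
        dx_flat = np.matmul(w2, dcols)
        _, _, h, w = (
            n,
            self.c_in,
            (self._out_shape_cache[2] + 2 * self.pad - self.k) // self.stride + 1,
            (self._out_shape_cache[3] + 2 * self.pad - self.k) // self.stride + 1,
        )
        return dx_flat.reshape(n, self.c_in, h, w)


class BatchNorm2d(Layer):
    """Per-channel batch normalization with running statistics.

    Training normalizes by batch moments over (N, H, W) and updates running
    moments; inference uses the running moments, which keeps the latent
    inversion deterministic and batch-size independent.
    """

    def __init__(self, c: int, eps: float = 1e-5, momentum: float = 0.9) -> None:
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.params = {"gamma": np.ones(c, dtype=DTYPE), "beta": np.zeros(c, dtype=DTYPE)}
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        b = self.params["beta"][None, :, None, None]
        if train:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
            self._std = np.sqrt(var + self.eps)[None, :, None, None]
            self._xhat = (x - mean[None, :, None, None]) / self._std
            self._train = True
            return g * self._xhat + b
        self._train = False
        std = np.sqrt(self.running_var + self.eps)[None, :, None, None]
        self._xhat = (x - self.running_mean[None, :, None, None]) / std
        return g * self._xhat + b

    def backward(self, dout: np.ndarray) -> np.ndarray:
        g = self.params["gamma"][None, :, None, None]
        if not self._train:
            # frozen statistics: the map is affine in x
            self.grads = {
                "gamma": (dout * self._xhat).sum(axis=(0, 2, 3)),
                "beta": dout.sum(axis=(0, 2, 3)),
            }
            return dout * g / np.sqrt(self.running_var + self.eps)[None, :, None, None]
        m = dout.shape[0] * dout.shape[2] * dout.shape[3]
        dgamma = (dout * self._xhat).sum(axis=(0, 2, 3))
        dbeta = dout.sum(axis=(0, 2, 3))
        self.grads = {"gamma": dgamma, "beta": dbeta}
        dxhat = dout * g
        dx = (
            dxhat
            - dxhat.mean(axis=(0, 2, 3), keepdims=True)
            - self._xhat * (dxhat * self._xhat).sum(axis=(0, 2, 3), keepdims=True) / m
        ) / self._std
        return dx


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, 0.0)


class LeakyReLU(Layer):
    def __init__(self, slope: float = 0.2) -> None:
        super().__init__()
        self.slope = slope

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, self.slope * x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return np.where(self._mask, dout, self.slope * dout)


class Tanh(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._y = np.tanh(x)
        return self._y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * (1.0 - self._y**2)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]) -> None:
        super().__init__()
        self.shape = shape

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Flatten(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout.reshape(self._in_shape)


class Sequential:
    """Ordered layer container; backward returns the gradient w.r.t. input."""

    def __init__(self, *layers: Layer) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    __call__ = forward

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def named_params(self):
        for i, layer in enumerate(self.layers):
            for name, p in layer.params.items():
                yield f"{i}.{name}", layer, name, p

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {full: p.copy() for full, _, _, p in self.named_params()}
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                state[f"{i}.running_mean"] = layer.running_mean.copy()
                state[f"{i}.running_var"] = layer.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for full, layer, name, _ in self.named_params():
            layer.params[name] = state[full].copy()
        for i, layer in enumerate(self.layers):
            if isinstance(layer, BatchNorm2d):
                layer.running_mean = state[f"{i}.running_mean"].copy()
                layer.running_var = state[f"{i}.running_var"].copy()
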