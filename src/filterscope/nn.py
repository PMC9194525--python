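"""Minimal dense/convolutional network engine in numpy.

Float64 end to end, single-threaded deterministic given a seed, with exact
weight get/set round-trips — the properties the perturbation and relevance
engines in this package rely on.  Only the pieces the interpretable-CNN
architecture needs are implemented: 1-D and 2-D valid convolutions (stride
1), max pooling with arbitrary stride, dense layers, ReLU, and a softmax
cross-entropy loss with per-sample weights.

Every layer caches its input (and pooling layers their argmax routing) on
the forward pass, which is what relevance propagation consumes.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .errors import ShapeError

__all__ = [
    "Layer",
    "Conv1D",
    "MaxPool1D",
    "ToImage",
    "Conv2D",
    "MaxPool2D",
    "Flatten",
    "Dense",
    "Sequential",
    "softmax",
    "glorot_uniform",
]


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def glorot_uniform(rng: np.random.Generator, shape: tuple, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Layer:
    """Base layer: parameter dict, forward with cache, backward to grads."""

    name: str = "layer"

    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}
        self.cache: dict[str, np.ndarray] = {}

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        """Allocate parameters for ``input_shape`` (per-sample, no batch axis)
        and return the per-sample output shape."""
        return input_shape

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - abstract
        raise NotImplementedError

    def backward(self, dout: np.ndarray, compute_dx: bool = True) -> np.ndarray | None:  # pragma: no cover
        raise NotImplementedError

    def clear_cache(self) -> None:
        self.cache = {}


class Conv1D(Layer):
    """Valid 1-D convolution (cross-correlation), stride 1, optional ReLU.

    Input ``(n, T)`` -> output ``(n, T - filter_len + 1, n_filters)``.
    Forward and weight-gradient correlations run through length-T FFTs;
    with the output restricted to the valid range this is exactly the
    direct sliding-dot-product (no circular wrap-around enters), just
    cheaper for long windows.
    """

    def __init__(self, n_filters: int, filter_len: int, relu: bool = True,
                 name: str = "conv1d") -> None:
        super().__init__()
        self.n_filters = n_filters
        self.filter_len = filter_len
        self.relu = relu
        self.name = name

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        (t,) = input_shape
        if t < self.filter_len:
            raise ShapeError(
                f"layer {self.name!r}: input length {t} shorter than "
                f"filter length {self.filter_len}"
            )
        self.params["W"] = glorot_uniform(
            rng, (self.n_filters, self.filter_len),
            fan_in=self.filter_len, fan_out=self.n_filters,
        )
        self.params["b"] = np.zeros(self.n_filters)
        return (t - self.filter_len + 1, self.n_filters)

    def forward(self, x: np.ndarray) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        t = x.shape[1]
        p = t - self.filter_len + 1
        xf = np.fft.rfft(x, axis=1)  # (n, B)
        wf = np.fft.rfft(W, n=t, axis=1)  # (F, B)
        corr = np.fft.irfft(xf[:, None, :] * np.conj(wf)[None], n=t, axis=2)
        z = corr[:, :, :p].transpose(0, 2, 1) + b  # (n, P, F)
        self.cache = {"x": x, "xf": xf, "z": z}
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout: np.ndarray, compute_dx: bool = True) -> np.ndarray | None:
        xf, z = self.cache["xf"], self.cache["z"]
        dz = dout * (z > 0.0) if self.relu else dout
        t = self.cache["x"].shape[1]
        dzf = np.fft.rfft(dz, n=t, axis=1)  # (n, B, F), dz zero-padded to T
        prod = np.einsum("nb,nbf->fb", xf, np.conj(dzf))
        self.grads["W"] = np.fft.irfft(prod, n=t, axis=1)[:, : self.filter_len]
        self.grads["b"] = dz.sum(axis=(0, 1))
        if not compute_dx:
            return None
        wf = np.fft.rfft(self.params["W"], n=t, axis=1)  # (F, B)
        return np.fft.irfft(np.einsum("nbf,fb->nb", dzf, wf), n=t, axis=1)


class MaxPool1D(Layer):
    """Max pooling over the position axis of ``(n, P, F)``."""

    def __init__(self, size: int, stride: int, name: str = "pool1d") -> None:
        super().__init__()
        self.size = size
        self.stride = stride
        self.name = name

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        p, f = input_shape
        if p < self.size:
            raise ShapeError(
                f"layer {self.name!r}: {p} positions cannot be pooled by {self.size}"
            )
        q = (p - self.size) // self.stride + 1
        return (q, f)

    def forward(self, x: np.ndarray) -> np.ndarray:
        v = sliding_window_view(x, self.size, axis=1)[:, :: self.stride]  # (n,Q,F,size)
        idx = v.argmax(axis=-1)
        out = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]
        self.cache = {"x_shape": x.shape, "idx": idx}
        return out

    def backward(self, dout: np.ndarray, compute_dx: bool = True) -> np.ndarray:
        idx = self.cache["idx"]
        n, q, f = dout.shape
        dx = np.zeros(self.cache["x_shape"])
        ni, qi, fi = np.ogrid[:n, :q, :f]
        pos = qi * self.stride + idx
        np.add.at(dx, (ni, pos, fi), dout)
        return dx

    def winner_positions(self) -> np.ndarray:
        """Absolute input-position index of each pooled maximum, shape (n,Q,F)."""
        idx = self.cache["idx"]
        q = idx.shape[1]
        return np.arange(q)[None, :, None] * self.stride + idx


class ToImage(Layer):
    """Reshape ``(n, Q, F)`` to a one-channel image ``(n, Q, F, 1)``.

    Time positions become the image height and the first-layer filter axis
    the width, so a 2-D kernel spans time x filters.
    """

    name = "to_image"

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        q, f = input_shape
        return (q, f, 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.cache = {"x_shape": x.shape}
        return x[..., None]

    def backward(self, dout: np.ndarray, compute_dx: bool = True) -> np.ndarray:
        return dout[..., 0]


class Conv2D(Layer):
    """Valid 2-D convolution, stride 1x1, optional ReLU.

    Input ``(n, H, W, C)`` -> ``(n, H-kh+1, W-kw+1, n_filters)``.
    """

    def __init__(self, n_filters: int, kh: int, kw: int, relu: bool = True,
                 name: str = "conv2d") -> None:
        super().__init__()
        self.n_filters = n_filters
        self.kh = kh
        self.kw = kw
        self.relu = relu
        self.name = name

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        h, w, c = input_shape
        if h < self.kh or w < self.kw:
            raise ShapeError(
                f"layer {self.name!r}: input {h}x{w} smaller than kernel "
                f"{self.kh}x{self.kw}"
            )
        k = self.kh * self.kw * c
        self.params["W"] = glorot_uniform(
            rng, (self.kh, self.kw, c, self.n_filters),
            fan_in=k, fan_out=self.n_filters,
        )
        self.params["b"] = np.zeros(self.n_filters)
        return (h - self.kh + 1, w - self.kw + 1, self.n_filters)

    def _cols(self, x: np.ndarray) -> np.ndarray:
        # (n, OH, OW, C, kh, kw) -> (n, OH, OW, kh*kw*C)
        v = sliding_window_view(x, (self.kh, self.kw), axis=(1, 2))
        v = v.transpose(0, 1, 2, 4, 5, 3)
        n, oh, ow = v.shape[:3]
        return np.ascontiguousarray(v).reshape(n, oh, ow, -1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        W, b = self.params["W"], self.params["b"]
        cols = self._cols(x)
        z = cols @ W.reshape(-1, self.n_filters) + b
        self.cache = {"x": x, "cols": cols, "z": z}
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout: np.ndarray, compute_dx: bool = True) -> np.ndarray | None:
        x, cols, z = self.cache["x"], self.cache["cols"], self.cache["z"]
        dz = dout * (z > 0.0) if self.relu else dout
        n, oh, ow, f = dz.shape
        k = cols.shape[-1]
        dWmat = cols.reshape(-1, k).T @ dz.reshape(-1, f)
        c = x.shape[-1]
        self.grads["W"] = dWmat.reshape(self.kh, self.kw, c, f)
        self.grads["b"] = dz.sum(axis=(0, 1, 2))
        if not compute_dx:
            return None
        c = x.shape[-1]
        wmat = self.params["W"].reshape(-1, f)
        dcols = (dz.reshape(-1, f) @ wmat.T).reshape(
            n, oh, ow, self.kh, self.kw, c
        )
        dx = np.zeros_like(x)
        for i in range(self.kh):
            for j in range(self.kw):
                dx[:, i : i + oh, j : j + ow, :] += dcols[:, :, :, i, j]
        return dx


class MaxPool2D(Layer):
    """Max pooling over ``(n, H, W, C)`` with window ``size`` and ``stride``."""

    def __init__(self, size: tuple[int, int], stride: tuple[int, int],
                 name: str = "pool2d") -> None:
        super().__init__()
        self.size = size
        self.stride = stride
        self.name = name

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        h, w, c = input_shape
        ph, pw = self.size
        if h < ph or w < pw:
            raise ShapeError(
                f"layer {self.name!r}: input {h}x{w} cannot be pooled by {ph}x{pw}"
            )
        sh, sw = self.stride
        return ((h - ph) // sh + 1, (w - pw) // sw + 1, c)

    def forward(self, x: np.ndarray) -> np.ndarray:
        ph, pw = self.size
        sh, sw = self.stride
        v = sliding_window_view(x, (ph, pw), axis=(1, 2))[:, ::sh, ::sw]
        n, oh, ow, c = v.shape[:4]
        vr = np.ascontiguousarray(v).reshape(n, oh, ow, c, ph * pw)
        idx = vr.argmax(axis=-1)
        out = np.take_along_axis(vr, idx[..., None], axis=-1)[..., 0]
        self.cache = {"x_shape": x.shape, "idx": idx}
        return out

    def _abs_positions(self) -> tuple[np.ndarray, np.ndarray]:
        idx = self.cache["idx"]
        _, oh, ow, _ = idx.shape
        ph, pw = self.size
        sh, sw = self.stride
        hi = np.arange(oh)[None, :, None, None] * sh + idx // pw
        wi = np.arange(ow)[None, None, :, None] * sw + idx % pw
        return hi, wi

    def backward(self, dout: np.ndarray, compute_dx: bool = True) -> np.ndarray:
        n, oh, ow, c = dout.shape
        dx = np.zeros(self.cache["x_shape"])
        hi, wi = self._abs_positions()
        ni = np.arange(n)[:, None, None, None]
        ci = np.arange(c)[None, None, None, :]
        np.add.at(dx, (ni, hi, wi, ci), dout)
        return dx


class Flatten(Layer):
    name = "flatten"

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        return (int(np.prod(input_shape)),)

    def forward(self, x: np.ndarray) -> np.ndarray:
        self.cache = {"x_shape": x.shape}
        return x.reshape(x.shape[0], -1)

    def backward(self, dout: np.ndarray, compute_dx: bool = True) -> np.ndarray:
        return dout.reshape(self.cache["x_shape"])


class Dense(Layer):
    """Fully connected layer, optional ReLU."""

    def __init__(self, units: int, relu: bool = True, name: str = "dense") -> None:
        super().__init__()
        self.units = units
        self.relu = relu
        self.name = name

    def build(self, input_shape: tuple, rng: np.random.Generator) -> tuple:
        (d,) = input_shape
        self.params["W"] = glorot_uniform(rng, (d, self.units), d, self.units)
        self.params["b"] = np.zeros(self.units)
        return (self.units,)

    def forward(self, x: np.ndarray) -> np.ndarray:
        z = x @ self.params["W"] + self.params["b"]
        self.cache = {"x": x, "z": z}
        return np.maximum(z, 0.0) if self.relu else z

    def backward(self, dout: np.ndarray, compute_dx: bool = True) -> np.ndarray:
        x, z = self.cache["x"], self.cache["z"]
        dz = dout * (z > 0.0) if self.relu else dout
        self.grads["W"] = x.T @ dz
        self.grads["b"] = dz.sum(axis=0)
        return dz @ self.params["W"].T


class Sequential:
    """Ordered stack of layers with softmax classification head.

    The final layer must be a linear :class:`Dense`; :meth:`predict_proba`
    applies the softmax, so the raw forward output is the pre-softmax score
    that relevance propagation seeds from.
    """

    def __init__(self, layers: list[Layer], input_shape: tuple, seed: int) -> None:
        self.layers = layers
        self.input_shape = tuple(input_shape)
        rng = np.random.default_rng(seed)
        shape = self.input_shape
        for layer in layers:
            shape = layer.build(shape, rng)
        self.output_shape = shape

    # ------------------------------------------------------------- forward
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Full forward pass returning pre-softmax scores; caches stay on
        the layers for backprop / relevance propagation."""
        if x.shape[1:] != self.input_shape:
            raise ShapeError(
                f"input shape {x.shape[1:]} does not match model input "
                f"{self.input_shape}"
            )
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        out = [softmax(self.forward(x[i : i + batch_size]))
               for i in range(0, len(x), batch_size)]
        self.clear_caches()
        return np.concatenate(out, axis=0)

    def clear_caches(self) -> None:
        for layer in self.layers:
            layer.clear_cache()

    # ------------------------------------------------------------- weights
    def get_weights(self) -> list[dict[str, np.ndarray]]:
        return [{k: v.copy() for k, v in layer.params.items()}
                for layer in self.layers]

    def set_weights(self, weights: list[dict[str, np.ndarray]]) -> None:
        if len(weights) != len(self.layers):
            raise ShapeError(
                f"expected {len(self.layers)} weight dicts, got {len(weights)}"
            )
        for layer, w in zip(self.layers, weights):
            if set(w) != set(layer.params):
                raise ShapeError(f"layer {layer.name!r}: parameter names differ")
            for k, v in w.items():
                if v.shape != layer.params[k].shape:
                    raise ShapeError(
                        f"layer {layer.name!r} param {k!r}: shape {v.shape} != "
                        f"{layer.params[k].shape}"
                    )
            for k, v in w.items():
                layer.params[k] = v.copy()

    # ------------------------------------------------------------ training
    def train_batch(self, x: np.ndarray, y: np.ndarray,
                    sample_weight: np.ndarray, lr: float) -> float:
        """One SGD step on weighted softmax cross-entropy; returns the
        mean weighted loss of the batch."""
        scores = self.forward(x)
        p = softmax(scores)
        n = len(x)
        eps = 1e-12
        loss = float(
            -(sample_weight * np.log(p[np.arange(n), y] + eps)).sum() / n
        )
        dscores = p.copy()
        dscores[np.arange(n), y] -= 1.0
        dscores *= sample_weight[:, None] / n
        grad = dscores
        for i in reversed(range(len(self.layers))):
            grad = self.layers[i].backward(grad, compute_dx=(i > 0))
        for layer in self.layers:
            for k, g in layer.grads.items():
                layer.params[k] -= lr * g
            layer.grads = {}
        self.clear_caches()
        return loss
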