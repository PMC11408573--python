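"""A small convolutional network implemented directly on numpy.

Architecture (size-agnostic thanks to global average pooling):

    conv3x3(c1) - layernorm - leaky ReLU - maxpool2
    conv3x3(c2) - layernorm - leaky ReLU - maxpool2
    conv3x3(c3) - layernorm - leaky ReLU  <- "last convolutional layer" for CAM
    global average pool ++ global max pool   (concatenated)
    dense(hidden) - leaky ReLU
    dense(n_classes)              -> softmax

Layer norm is per sample (over channels and space, with per-channel gain and
bias), so inference needs no running statistics and training is stable at
learning rates around 1e-3 from random init.

Convolutions are stride-1 with same padding, computed as im2col + GEMM in
float32.  Backpropagation is implemented by hand; the gradient of a class
score with respect to the last-conv activations — the quantity CAM needs —
is available analytically through the dense head.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["SmallConvNet", "softmax", "ContractViolation"]


class ContractViolation(ValueError):
    """Shapes handed to the model violate its activation/gradient contract."""


_LEAK = np.float32(0.05)


def _lrelu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, _LEAK * x)


def _lrelu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, np.float32(1.0), _LEAK)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _im2col(x: np.ndarray) -> np.ndarray:
    """(N,C,H,W) -> (N*H*W, C*9) patch matrix for a 3x3 same-padded conv."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(2, 3))
    # win: (N, C, H, W, 3, 3) -> (N, H, W, C, 3, 3) -> (N*H*W, C*9)
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5))
    return cols.reshape(n * h * w, c * 9)


def _col2im(dcols: np.ndarray, shape: tuple[int, int, int, int]) -> np.ndarray:
    """Adjoint of :func:`_im2col`: scatter-add patches back to (N,C,H,W)."""
    n, c, h, w = shape
    d = dcols.reshape(n, h, w, c, 3, 3)
    dxp = np.zeros((n, c, h + 2, w + 2), dtype=dcols.dtype)
    for di in range(3):
        for dj in range(3):
            dxp[:, :, di:di + h, dj:dj + w] += d[:, :, :, :, di, dj] \
                .transpose(0, 3, 1, 2)
    return dxp[:, :, 1:-1, 1:-1]


def _conv_forward(x: np.ndarray, weight: np.ndarray, bias: np.ndarray):
    """weight: (out_c, in_c, 3, 3).  Returns (out, cache)."""
    n, c, h, w = x.shape
    out_c = weight.shape[0]
    cols = _im2col(x)
    wmat = weight.reshape(out_c, c * 9).T          # (C*9, out_c)
    out = cols @ wmat + bias
    out = out.reshape(n, h, w, out_c).transpose(0, 3, 1, 2)
    return out, (cols, x.shape, wmat)


def _conv_backward(dout: np.ndarray, weight: np.ndarray, cache,
                   need_dx: bool = True):
    cols, x_shape, wmat = cache
    n, c, h, w = x_shape
    out_c = weight.shape[0]
    dflat = dout.transpose(0, 2, 3, 1).reshape(n * h * w, out_c)
    dw = (cols.T @ dflat).T.reshape(out_c, c, 3, 3)
    db = dflat.sum(axis=0)
    if not need_dx:
        return None, dw, db
    dcols = dflat @ wmat.T
    dx = _col2im(dcols, x_shape)
    return dx, dw, db


def _ln_forward(x: np.ndarray, gamma: np.ndarray, beta: np.ndarray,
                eps: float = 1e-5):
    """Per-sample layer norm over (C,H,W) with per-channel gain/bias."""
    mu = x.mean(axis=(1, 2, 3), keepdims=True)
    var = x.var(axis=(1, 2, 3), keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x - mu) * inv
    out = gamma[None, :, None, None] * xhat + beta[None, :, None, None]
    return out, (xhat, inv, gamma)


def _ln_backward(dout: np.ndarray, cache):
    xhat, inv, gamma = cache
    n, c, h, w = dout.shape
    m = c * h * w
    dgamma = (dout * xhat).sum(axis=(0, 2, 3))
    dbeta = dout.sum(axis=(0, 2, 3))
    dxhat = dout * gamma[None, :, None, None]
    mean1 = dxhat.mean(axis=(1, 2, 3), keepdims=True)
    mean2 = (dxhat * xhat).mean(axis=(1, 2, 3), keepdims=True)
    dx = (dxhat - mean1 - xhat * mean2) * inv
    return dx, dgamma, dbeta


def _maxpool_forward(x: np.ndarray):
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    xe = x[:, :, :h2 * 2, :w2 * 2]
    out = np.maximum(np.maximum(xe[:, :, 0::2, 0::2], xe[:, :, 0::2, 1::2]),
                     np.maximum(xe[:, :, 1::2, 0::2], xe[:, :, 1::2, 1::2]))
    return out, (x, out)


def _maxpool_backward(dout: np.ndarray, cache):
    x, out = cache
    n, c, h, w = x.shape
    h2, w2 = h // 2, w // 2
    dx = np.zeros(x.shape, dtype=dout.dtype)
    used = np.zeros(out.shape, dtype=bool)
    # Route each output gradient to the first matching quadrant only.
    for i, j in ((0, 0), (0, 1), (1, 0), (1, 1)):
        quad = x[:, :, i:h2 * 2:2, j:w2 * 2:2]
        take = (quad == out) & ~used
        dx[:, :, i:h2 * 2:2, j:w2 * 2:2] = dout * take
        used |= take
    return dx


class SmallConvNet:
    """Two-class CNN sized for CPU training on 64-128 px slices.

    Contract surface used by the CAM module:

    * ``forward(image)`` -> probability vector of length 2 summing to 1
    * ``last_conv_activations(image)`` -> (channels, h, w) post-activation map
    * ``class_score_gradient(image, target_class)`` -> gradient of the
      pre-softmax class score w.r.t. those activations, same shape
    * ``score_from_activations(activations, target_class)`` -> the class
      score as a function of the last-conv activations (head forward pass)
    """

    def __init__(self, conv_channels: tuple[int, int, int] = (8, 12, 24),
                 hidden_units: int = 16, n_classes: int = 2, seed: int = 0):
        self.conv_channels = tuple(conv_channels)
        self.hidden_units = int(hidden_units)
        self.n_classes = int(n_classes)
        rng = np.random.default_rng(seed)
        c1, c2, c3 = self.conv_channels
        f32 = np.float32

        def he(shape, fan_in):
            return rng.normal(0, np.sqrt(2.0 / fan_in), shape).astype(f32)

        self.params: dict[str, np.ndarray] = {
            "conv1_w": he((c1, 1, 3, 3), 9),
            "conv1_b": np.zeros(c1, f32),
            "conv2_w": he((c2, c1, 3, 3), 9 * c1),
            "conv2_b": np.zeros(c2, f32),
            "conv3_w": he((c3, c2, 3, 3), 9 * c2),
            "conv3_b": np.zeros(c3, f32),
            "fc1_w": he((self.hidden_units, 2 * c3), 2 * c3),
            "fc1_b": np.zeros(self.hidden_units, f32),
            "fc2_w": he((self.n_classes, self.hidden_units),
                        self.hidden_units),
            "fc2_b": np.zeros(self.n_classes, f32),
            "ln1_g": np.ones(c1, f32), "ln1_b": np.zeros(c1, f32),
            "ln2_g": np.ones(c2, f32), "ln2_b": np.zeros(c2, f32),
            "ln3_g": np.ones(c3, f32), "ln3_b": np.zeros(c3, f32),
        }

    # ------------------------------------------------------------------ core

    @staticmethod
    def _as_batch(images: np.ndarray) -> np.ndarray:
        x = np.asarray(images, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if x.ndim != 3:
            raise ContractViolation(f"expected (H,W) or (N,H,W) grayscale "
                                    f"input, got shape {x.shape}")
        # fixed affine centering of [0,1] intensities; not data-dependent
        return (x[:, None] - 0.5) * 2.0  # (N,1,H,W)

    def _forward_full(self, x: np.ndarray):
        p = self.params
        caches = {}
        z1, caches["c1"] = _conv_forward(x, p["conv1_w"], p["conv1_b"])
        a1, caches["n1"] = _ln_forward(z1, p["ln1_g"], p["ln1_b"])
        r1 = _lrelu(a1)
        p1, caches["p1"] = _maxpool_forward(r1)
        z2, caches["c2"] = _conv_forward(p1, p["conv2_w"], p["conv2_b"])
        a2, caches["n2"] = _ln_forward(z2, p["ln2_g"], p["ln2_b"])
        r2 = _lrelu(a2)
        p2, caches["p2"] = _maxpool_forward(r2)
        z3, caches["c3"] = _conv_forward(p2, p["conv3_w"], p["conv3_b"])
        a3, caches["n3"] = _ln_forward(z3, p["ln3_g"], p["ln3_b"])
        r3 = _lrelu(a3)                              # last-conv activations
        gavg = r3.mean(axis=(2, 3))                  # GAP: (N, c3)
        gmax = r3.max(axis=(2, 3))                   # GMP: (N, c3)
        g = np.concatenate([gavg, gmax], axis=1)
        h1 = g @ p["fc1_w"].T + p["fc1_b"]
        rh = _lrelu(h1)
        logits = rh @ p["fc2_w"].T + p["fc2_b"]
        caches.update(a1=a1, a2=a2, a3=a3, r3=r3, g=g, h1=h1, rh=rh, x=x)
        return logits, caches

    def _backward(self, dlogits: np.ndarray, caches) -> dict[str, np.ndarray]:
        p = self.params
        grads: dict[str, np.ndarray] = {}
        rh, h1, g, r3, a3 = (caches[k] for k in ("rh", "h1", "g", "r3", "a3"))
        grads["fc2_w"] = dlogits.T @ rh
        grads["fc2_b"] = dlogits.sum(axis=0)
        drh = dlogits @ p["fc2_w"]
        dh1 = drh * _lrelu_grad(h1)
        grads["fc1_w"] = dh1.T @ g
        grads["fc1_b"] = dh1.sum(axis=0)
        dg = dh1 @ p["fc1_w"]
        n, c3, hh, ww = r3.shape
        dgavg, dgmax = dg[:, :c3], dg[:, c3:]
        dr3 = np.broadcast_to(dgavg[:, :, None, None] / (hh * ww),
                              r3.shape).astype(np.float32).copy()
        # route max-pool gradient to each channel's (first) argmax pixel
        flat = r3.reshape(n, c3, hh * ww)
        idx = flat.argmax(axis=2)
        ni, ci = np.meshgrid(np.arange(n), np.arange(c3), indexing="ij")
        dr3.reshape(n, c3, hh * ww)[ni, ci, idx] += dgmax
        da3 = dr3 * _lrelu_grad(a3)
        dz3, grads["ln3_g"], grads["ln3_b"] = _ln_backward(da3, caches["n3"])
        dp2, grads["conv3_w"], grads["conv3_b"] = \
            _conv_backward(dz3, p["conv3_w"], caches["c3"])
        dr2 = _maxpool_backward(dp2, caches["p2"])
        da2 = dr2 * _lrelu_grad(caches["a2"])
        dz2, grads["ln2_g"], grads["ln2_b"] = _ln_backward(da2, caches["n2"])
        dp1, grads["conv2_w"], grads["conv2_b"] = \
            _conv_backward(dz2, p["conv2_w"], caches["c2"])
        dr1 = _maxpool_backward(dp1, caches["p1"])
        da1 = dr1 * _lrelu_grad(caches["a1"])
        dz1, grads["ln1_g"], grads["ln1_b"] = _ln_backward(da1, caches["n1"])
        _, grads["conv1_w"], grads["conv1_b"] = \
            _conv_backward(dz1, p["conv1_w"], caches["c1"], need_dx=False)
        return grads

    # ----------------------------------------------------------- public API

    def forward_batch(self, images: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Class probabilities, (N, n_classes), rows summing to 1."""
        x = self._as_batch(images)
        out = []
        for i in range(0, x.shape[0], chunk):
            logits, _ = self._forward_full(x[i:i + chunk])
            out.append(softmax(logits))
        return np.concatenate(out, axis=0)

    def forward(self, image: np.ndarray) -> np.ndarray:
        """Probability vector for a single (H, W) image."""
        return self.forward_batch(image)[0]

    def last_conv_activations(self, image: np.ndarray) -> np.ndarray:
        """Post-activation output of the last conv layer, (c3, h, w)."""
        x = self._as_batch(image)
        if x.shape[0] != 1:
            raise ContractViolation("last_conv_activations takes one image")
        _, caches = self._forward_full(x)
        return caches["r3"][0].astype(np.float64)

    def score_from_activations(self, activations: np.ndarray,
                               target_class: int) -> float:
        """Pre-softmax class score as a function of last-conv activations."""
        a = np.asarray(activations, dtype=np.float64)
        if a.ndim != 3 or a.shape[0] != self.conv_channels[2]:
            raise ContractViolation(
                f"activations must be ({self.conv_channels[2]}, h, w), got "
                f"{a.shape}")
        p = self.params
        g = np.concatenate([a.mean(axis=(1, 2)), a.max(axis=(1, 2))])
        rh = _lrelu(g @ p["fc1_w"].T.astype(np.float64) + p["fc1_b"])
        logits = rh @ p["fc2_w"].T.astype(np.float64) + p["fc2_b"]
        return float(logits[int(target_class)])

    def class_score_gradient(self, image: np.ndarray,
                             target_class: int) -> np.ndarray:
        """d(score of target_class) / d(last-conv activations), (c3, h, w)."""
        a = self.last_conv_activations(image)
        p = self.params
        g = np.concatenate([a.mean(axis=(1, 2)), a.max(axis=(1, 2))])
        h1 = g @ p["fc1_w"].T.astype(np.float64) + p["fc1_b"]
        dscore_drh = p["fc2_w"][int(target_class)].astype(np.float64)
        dh1 = dscore_drh * _lrelu_grad(h1)
        dg = dh1 @ p["fc1_w"].astype(np.float64)
        c3, hh, ww = a.shape
        dgavg, dgmax = dg[:c3], dg[c3:]
        grad = np.broadcast_to(dgavg[:, None, None] / (hh * ww),
                               a.shape).copy()
        flat = a.reshape(c3, hh * ww)
        idx = flat.argmax(axis=1)
        grad.reshape(c3, hh * ww)[np.arange(c3), idx] += dgmax
        if grad.shape != a.shape:  # pragma: no cover - defensive
            raise ContractViolation("gradient/activation shape mismatch")
        return grad

    # -------------------------------------------------------------- persist

    def save(self, path: str | Path) -> None:
        meta = {"conv_channels": list(self.conv_channels),
                "hidden_units": self.hidden_units,
                "n_classes": self.n_classes}
        np.savez(Path(path), _meta=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.params)

    @classmethod
    def load(cls, path: str | Path) -> "SmallConvNet":
        with np.load(Path(path)) as data:
            meta = json.loads(bytes(data["_meta"]).decode())
            net = cls(conv_channels=tuple(meta["conv_channels"]),
                      hidden_units=meta["hidden_units"],
                      n_classes=meta["n_classes"])
            for key in net.params:
                net.params[key] = data[key]
        return net
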