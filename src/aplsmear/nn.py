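"""Minimal numpy CNN used by both the single-cell and the MIL classifier.

The topology is fixed: four valid-padding strided convolutions with ReLU,
a global max pool over the remaining spatial grid (this is what makes the
network translation-invariant and input-size agnostic), three fully
connected ReLU layers and a softmax classification layer.  Forward,
backward (parameter gradients and, when requested, the gradient with
respect to the input image — needed for integrated gradients) and an Adam
optimizer are implemented directly on numpy arrays.

Arrays are float32 internally; softmax probabilities are returned in
float64 so that downstream bag averaging is numerically exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view


@dataclass(frozen=True)
class ArchitectureConfig:
    """Sizes of the shared cell/MIL backbone.

    ``fc_sizes`` defaults to (32, 22, 11) so that the concatenated
    activations of the last four layers (three FC layers plus the
    ``n_classes``-way softmax) span a 68-dimensional latent space.
    """

    conv_filters: tuple[int, ...] = (16, 32, 64, 128)
    conv_kernel: int = 3
    conv_stride: int = 2
    fc_sizes: tuple[int, ...] = (32, 22, 11)
    n_classes: int = 3

    def __post_init__(self):
        object.__setattr__(self, "conv_filters", tuple(int(f) for f in self.conv_filters))
        object.__setattr__(self, "fc_sizes", tuple(int(f) for f in self.fc_sizes))
        if len(self.conv_filters) != 4:
            raise ValueError(f"conv_filters must have exactly 4 entries, got {len(self.conv_filters)}")
        if len(self.fc_sizes) != 3:
            raise ValueError(f"fc_sizes must have exactly 3 entries, got {len(self.fc_sizes)}")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3 (3-class training with blurred outgroup is the default)")
        if any(f < 1 for f in self.conv_filters) or any(f < 1 for f in self.fc_sizes):
            raise ValueError("layer sizes must be positive")
        if self.conv_kernel < 1 or self.conv_stride < 1:
            raise ValueError("kernel and stride must be positive")

    @property
    def latent_dim(self) -> int:
        """Dimensionality of the last-four-layer feature vector (68 by default)."""
        return sum(self.fc_sizes) + self.n_classes

    @property
    def min_input_size(self) -> int:
        """Smallest square input for which all four conv layers are defined."""
        n = 1
        for _ in range(4):
            n = (n - 1) * self.conv_stride + self.conv_kernel
        return n

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureConfig":
        return cls(
            conv_filters=tuple(d["conv_filters"]),
            conv_kernel=int(d["conv_kernel"]),
            conv_stride=int(d["conv_stride"]),
            fc_sizes=tuple(d["fc_sizes"]),
            n_classes=int(d["n_classes"]),
        )


# ---------------------------------------------------------------------------
# layer primitives (NHWC layout)
# ---------------------------------------------------------------------------

def _conv_forward(x, w_mat, b, k, stride):
    """Valid-padding strided convolution via im2col.

    x: (N, H, W, C); w_mat: (C*k*k, F) with (C, k, k) ordering; returns
    (out, cols) with out (N, Ho, Wo, F).
    """
    win = sliding_window_view(x, (k, k), axis=(1, 2))          # (N, H-k+1, W-k+1, C, k, k)
    win = win[:, ::stride, ::stride]
    n, ho, wo = win.shape[:3]
    cols = np.ascontiguousarray(win).reshape(n, ho, wo, -1)
    out = cols @ w_mat + b
    return out, cols


def _conv_backward(dout, cols, x_shape, w_mat, k, stride):
    """Gradients of a _conv_forward call; returns (dx, dw_mat, db)."""
    n, ho, wo, _ = dout.shape
    dw = np.tensordot(cols, dout, axes=([0, 1, 2], [0, 1, 2]))
    db = dout.sum(axis=(0, 1, 2))
    dcols = dout @ w_mat.T
    c = x_shape[3]
    dcols = dcols.reshape(n, ho, wo, c, k, k)
    dx = np.zeros(x_shape, dtype=dout.dtype)
    for ki in range(k):
        for kj in range(k):
            dx[:, ki : ki + stride * (ho - 1) + 1 : stride,
                  kj : kj + stride * (wo - 1) + 1 : stride, :] += dcols[:, :, :, :, ki, kj]
    return dx, dw, db


def _softmax(z):
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


class CellNet:
    """The shared convolutional backbone + classification head.

    A single instance serves both roles: the single-cell classifier calls
    :meth:`predict_probs` per image, the MIL sample classifier averages the
    same per-cell softmax assignments over a bag.
    """

    def __init__(self, config: ArchitectureConfig, seed: int):
        self.config = config
        self.seed = int(seed)
        rng = np.random.default_rng(self.seed)
        k, s = config.conv_kernel, config.conv_stride
        self.params: dict[str, np.ndarray] = {}
        cin = 3
        for i, f in enumerate(config.conv_filters):
            fan_in = cin * k * k
            self.params[f"cw{i}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, f)).astype(np.float32)
            self.params[f"cb{i}"] = np.zeros(f, dtype=np.float32)
            cin = f
        din = config.conv_filters[-1]
        dims = list(config.fc_sizes) + [config.n_classes]
        for i, d in enumerate(dims):
            scale = np.sqrt(2.0 / din) if i < len(dims) - 1 else np.sqrt(1.0 / din)
            self.params[f"fw{i}"] = rng.normal(0.0, scale, size=(din, d)).astype(np.float32)
            self.params[f"fb{i}"] = np.zeros(d, dtype=np.float32)
            din = d
        self._k, self._s = k, s

    # -- forward ------------------------------------------------------------

    def forward(self, x: np.ndarray, want_cache: bool = False):
        """Map a batch of images (N, H, W, 3) in [0, 1] to class probabilities.

        Returns ``(probs, hidden, cache)``: probs (N, n_classes) float64,
        hidden the list of post-ReLU FC activations plus probs (the
        "last four layers"), cache ``None`` unless requested.
        """
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[3] != 3:
            raise ValueError(f"expected input of shape (N, H, W, 3), got {x.shape}")
        if min(x.shape[1], x.shape[2]) < self.config.min_input_size:
            raise ValueError(
                f"input spatial size {x.shape[1]}x{x.shape[2]} below the minimum "
                f"{self.config.min_input_size} for this architecture"
            )
        cache = {"x_shape": x.shape} if want_cache else None
        h = x
        for i in range(4):
            out, cols = _conv_forward(h, self.params[f"cw{i}"], self.params[f"cb{i}"], self._k, self._s)
            relu = np.maximum(out, 0.0)
            if want_cache:
                cache[f"conv{i}"] = (cols, out.shape, h.shape, relu > 0)
            h = relu
        pooled = h.max(axis=(1, 2))                             # global max pool
        if want_cache:
            cache["pool"] = (h, pooled)
        hidden = []
        a = pooled
        n_fc = len(self.config.fc_sizes)
        for i in range(n_fc + 1):
            z = a @ self.params[f"fw{i}"] + self.params[f"fb{i}"]
            if i < n_fc:
                a_next = np.maximum(z, 0.0)
                if want_cache:
                    cache[f"fc{i}"] = (a, z > 0)
                hidden.append(a_next)
                a = a_next
            else:
                if want_cache:
                    cache[f"fc{i}"] = (a, None)
                probs = _softmax(z.astype(np.float64))
        hidden.append(probs)
        return probs, hidden, cache

    def predict_probs(self, x: np.ndarray) -> np.ndarray:
        """Class probabilities, (N, n_classes) float64, rows summing to 1."""
        if len(x) == 0:
            return np.zeros((0, self.config.n_classes))
        probs, _, _ = self.forward(x)
        return probs

    # -- backward -----------------------------------------------------------

    def backward(self, cache, dlogits, want_dx: bool = False, want_dparams: bool = True):
        """Backprop from logit gradients; returns (grads dict or None, dx or None)."""
        dlogits = np.asarray(dlogits, dtype=np.float32)
        grads = {} if want_dparams else None
        da = dlogits
        n_fc = len(self.config.fc_sizes)
        for i in range(n_fc, -1, -1):
            a_in, relu_mask = self.cache_fc(cache, i)
            if want_dparams:
                grads[f"fw{i}"] = a_in.T @ da
                grads[f"fb{i}"] = da.sum(axis=0)
            da = da @ self.params[f"fw{i}"].T
            if i > 0:
                _, prev_mask = self.cache_fc(cache, i - 1)
                da = da * prev_mask
        # through global max pool: route gradient to (possibly tied) maxima
        h, pooled = cache["pool"]
        mask = h == pooled[:, None, None, :]
        counts = mask.sum(axis=(1, 2))
        dh = mask * (da / counts)[:, None, None, :]
        dx = None
        for i in range(3, -1, -1):
            cols, out_shape, in_shape, relu_mask = cache[f"conv{i}"]
            dh = dh * relu_mask
            need_dx = want_dx or i > 0
            dxi, dw, db = _conv_backward(dh, cols, in_shape, self.params[f"cw{i}"], self._k, self._s)
            if want_dparams:
                grads[f"cw{i}"] = dw
                grads[f"cb{i}"] = db
            dh = dxi if need_dx else None
            if i == 0:
                dx = dxi if want_dx else None
        return grads, dx

    @staticmethod
    def cache_fc(cache, i):
        return cache[f"fc{i}"]

    # -- gradients of scalar targets ----------------------------------------

    def delta_p(self, x: np.ndarray) -> np.ndarray:
        """P(APL) - P(non-APL) per image (class 1 minus class 0)."""
        probs = self.predict_probs(x)
        return probs[:, 1] - probs[:, 0]

    def delta_grad(self, x: np.ndarray) -> np.ndarray:
        """Gradient of P(APL) - P(non-APL) with respect to each input pixel."""
        probs, _, cache = self.forward(x, want_cache=True)
        g = np.zeros_like(probs)
        g[:, 0] = -1.0
        g[:, 1] = 1.0
        # softmax vector-Jacobian product: dz_j = p_j (g_j - sum_k g_k p_k)
        dlogits = probs * (g - (g * probs).sum(axis=1, keepdims=True))
        _, dx = self.backward(cache, dlogits, want_dx=True, want_dparams=False)
        return dx.astype(np.float64)

    def loss_and_grads(self, x: np.ndarray, y: np.ndarray):
        """Mean cross-entropy on integer labels y, plus parameter gradients."""
        probs, _, cache = self.forward(x, want_cache=True)
        n = len(x)
        eps = 1e-12
        loss = -np.mean(np.log(probs[np.arange(n), y] + eps))
        dlogits = probs.copy()
        dlogits[np.arange(n), y] -= 1.0
        dlogits /= n
        grads, _ = self.backward(cache, dlogits)
        return float(loss), grads

    def bag_loss_and_grads(self, x: np.ndarray, y: int):
        """Cross-entropy of the bag probability (mean per-cell softmax) for one bag."""
        probs, _, cache = self.forward(x, want_cache=True)
        bag = probs.mean(axis=0)
        eps = 1e-12
        loss = -np.log(bag[y] + eps)
        g = np.zeros_like(probs)
        g[:, y] = -1.0 / (bag[y] + eps) / len(x)
        dlogits = probs * (g - (g * probs).sum(axis=1, keepdims=True))
        grads, _ = self.backward(cache, dlogits)
        return float(loss), grads, bag

    def cell_loss(self, x: np.ndarray, y: np.ndarray, batch: int = 256) -> float:
        """Mean cross-entropy without gradients (for convergence monitoring)."""
        tot, n = 0.0, len(x)
        for i in range(0, n, batch):
            probs = self.predict_probs(x[i : i + batch])
            yi = y[i : i + batch]
            tot += -np.log(probs[np.arange(len(yi)), yi] + 1e-12).sum()
        return tot / n

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        np.savez(path, __arch__=np.array(
            [*self.config.conv_filters, self.config.conv_kernel, self.config.conv_stride,
             *self.config.fc_sizes, self.config.n_classes, self.seed], dtype=np.int64),
            **self.params)

    @classmethod
    def load(cls, path) -> "CellNet":
        data = np.load(path)
        a = data["__arch__"]
        cfg = ArchitectureConfig(conv_filters=tuple(a[0:4]), conv_kernel=int(a[4]),
                                 conv_stride=int(a[5]), fc_sizes=tuple(a[6:9]), n_classes=int(a[9]))
        net = cls(cfg, seed=int(a[10]))
        for k in net.params:
            net.params[k] = data[k]
        return net


class Adam:
    """Adam optimizer over a CellNet parameter dict."""

    def __init__(self, params: dict, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            g = g.astype(np.float32, copy=False)
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
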