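"""Minimal NumPy neural-network core for the recurrent deficit scorer.

The scorer is a single LSTM layer read out through temporal max-pooling,
dropout, and a dense head:

    per-frame features (T x F) -> LSTM (U units, per-timestep outputs)
        -> max over time -> dropout -> dense head (ReLU / sigmoid / softmax)

Everything needed to train it (backpropagation through time, Adam, MSE and
cross-entropy losses) and to explain it (the epsilon-rule of layer-wise
relevance propagation, gradient x input, saliency) is implemented here on
plain ``float32`` NumPy arrays, so training and attribution are exactly
reproducible from a seed on any machine.

Shapes use B = batch, T = frames per clip, F = input features per frame,
U = LSTM units, K = head outputs.  LSTM gates are stored in one matrix with
column blocks ordered (input, forget, candidate, output).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LSTMScorerNet",
    "DenseNet",
    "Adam",
    "eps_rule",
    "mse_loss",
    "cross_entropy_loss",
]

_F32 = np.float32


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _softmax(x: np.ndarray) -> np.ndarray:
    z = x - x.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out)).astype(_F32)


def _sign_eps(z: np.ndarray) -> np.ndarray:
    """sign(z) with sign(0) := +1, as used by the epsilon stabilizer."""
    s = np.sign(z)
    s[s == 0] = 1.0
    return s


def eps_rule(
    a: np.ndarray,
    w: np.ndarray,
    z: np.ndarray,
    relevance_out: np.ndarray,
    epsilon: float,
) -> np.ndarray:
    """Distribute relevance through a linear map with the epsilon rule.

    For a layer ``z_j = sum_i a_i w_ij (+ b_j)``, the relevance assigned to
    input ``i`` is ``R_i = sum_j a_i w_ij / (z_j + eps * sign(z_j)) * R_j``.
    ``a`` has shape (..., I), ``w`` (I, J), ``z`` and ``relevance_out``
    (..., J); the bias keeps its share of relevance (it is simply not
    redistributed), which is the standard epsilon-LRP convention.
    """
    denom = z + epsilon * _sign_eps(z)
    msg = relevance_out / denom
    return a * (msg @ w.T)


def mse_loss(y: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean squared error and its gradient w.r.t. ``y``."""
    d = y - t
    loss = float(np.mean(d * d))
    grad = (2.0 / d.size) * d
    return loss, grad.astype(_F32)


def cross_entropy_loss(p: np.ndarray, t: np.ndarray) -> tuple[float, np.ndarray]:
    """Cross-entropy for softmax probabilities ``p`` against one-hot ``t``.

    Returns the gradient w.r.t. the softmax *pre-activations*, using the
    standard softmax/CE simplification.
    """
    eps = 1e-12
    loss = float(-np.mean(np.sum(t * np.log(p + eps), axis=-1)))
    grad = (p - t) / p.shape[0]
    return loss, grad.astype(_F32)


class Adam:
    """Adam optimizer over a dict of named parameter arrays.

    ``weight_decay`` applies decoupled (AdamW-style) shrinkage; besides its
    usual regularizing role it lets weights that never receive coherent
    gradient decay away, which sharpens post-hoc relevance attribution.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.weight_decay = weight_decay
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for k, g in grads.items():
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / bc1
            vhat = self.v[k] / bc2
            update = self.lr * mhat / (np.sqrt(vhat) + self.eps)
            if self.weight_decay and not k.startswith("b"):
                update = update + self.lr * self.weight_decay * params[k]
            params[k] -= update.astype(_F32)


@dataclass
class _ForwardCache:
    """Intermediate activations retained for BPTT / relevance propagation."""
    x: np.ndarray            # B x T x F
    gates: np.ndarray        # B x T x 4U post-activation (i, f, g, o)
    z_gates: np.ndarray      # B x T x 4U pre-activation
    c: np.ndarray            # B x T x U cell states
    tanh_c: np.ndarray       # B x T x U
    h: np.ndarray            # B x T x U hidden states
    pooled: np.ndarray       # B x U (after max pool)
    argmax_t: np.ndarray     # B x U winning timestep per unit
    drop_mask: np.ndarray | None  # B x U inverted-dropout mask, or None
    head_pre: np.ndarray     # B x K dense pre-activation
    y: np.ndarray            # B x K head output


class LSTMScorerNet:
    """LSTM -> temporal max-pool -> dropout -> dense head, in NumPy.

    Parameters
    ----------
    n_features : input features per frame (2,048 in the full-scale setting).
    lstm_units : LSTM units; the full-scale architecture uses 2,048, CPU-sized
        runs use 32-64 (the architecture is robust to this).
    n_outputs : head width (1 cumulative / 7 elements / 2 votes / n classes).
    head_activation : {"relu", "sigmoid", "softmax", "linear"}.
    dropout_rate : fraction of pooled units zeroed during training.
    seed : weight-initialization seed (Glorot uniform; forget-gate bias 1).
    """

    def __init__(self, n_features: int, lstm_units: int, n_outputs: int,
                 head_activation: str = "relu", dropout_rate: float = 0.1,
                 seed: int = 0):
        if head_activation not in ("relu", "sigmoid", "softmax", "linear"):
            raise ValueError(f"unknown head activation {head_activation!r}")
        if not (0.0 <= dropout_rate < 1.0):
            raise ValueError("dropout_rate must be in [0, 1)")
        if lstm_units < 1 or n_features < 1 or n_outputs < 1:
            raise ValueError("n_features, lstm_units and n_outputs must be >= 1")
        self.n_features = int(n_features)
        self.units = int(lstm_units)
        self.n_outputs = int(n_outputs)
        self.head_activation = head_activation
        self.dropout_rate = float(dropout_rate)
        self.seed = int(seed)

        rng = np.random.default_rng(seed)
        u, f, k = self.units, self.n_features, self.n_outputs
        # Per-feature input centering (set from training data).  Encoder
        # activations have a large positive mean; feeding them raw drives the
        # LSTM pre-activations deep into gate saturation, so training sets
        # this to the training-set feature mean and inference subtracts it.
        self.input_center = np.zeros(f, dtype=_F32)
        self.params: dict[str, np.ndarray] = {
            "Wx": _glorot(rng, f, 4 * u),
            "Wh": _glorot(rng, u, 4 * u),
            "b": np.zeros(4 * u, dtype=_F32),
            "Wd": _glorot(rng, u, k),
            "bd": np.zeros(k, dtype=_F32),
        }
        # Forget-gate bias of 1 is the standard LSTM trainability trick; a
        # small positive bias on a ReLU head keeps its output unit alive at
        # initialization (a dead output unit would never receive gradient).
        self.params["b"][u:2 * u] = 1.0
        if head_activation == "relu":
            self.params["bd"][:] = 0.5

    # -- forward -----------------------------------------------------------

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None,
                keep_cache: bool = False) -> tuple[np.ndarray, _ForwardCache | None]:
        """Run the network on ``x`` of shape (B, T, F) or (T, F)."""
        if x.ndim == 2:
            x = x[None]
        if x.shape[-1] != self.n_features:
            raise ValueError(
                f"feature dimension {x.shape[-1]} != model n_features {self.n_features}")
        x = np.ascontiguousarray(x, dtype=_F32)
        if self.input_center.any():
            x = x - self.input_center
        bsz, tlen, _ = x.shape
        u = self.units
        p = self.params

        # Input projection for all timesteps in one BLAS call.
        xp = x.reshape(bsz * tlen, -1) @ p["Wx"]
        xp = xp.reshape(bsz, tlen, 4 * u) + p["b"]

        gates = np.empty((bsz, tlen, 4 * u), dtype=_F32)
        z_gates = np.empty((bsz, tlen, 4 * u), dtype=_F32)
        cs = np.empty((bsz, tlen, u), dtype=_F32)
        tanh_cs = np.empty((bsz, tlen, u), dtype=_F32)
        hs = np.empty((bsz, tlen, u), dtype=_F32)

        h = np.zeros((bsz, u), dtype=_F32)
        c = np.zeros((bsz, u), dtype=_F32)
        for t in range(tlen):
            z = xp[:, t] + h @ p["Wh"]
            i = _sigmoid(z[:, :u])
            fg = _sigmoid(z[:, u:2 * u])
            g = np.tanh(z[:, 2 * u:3 * u])
            o = _sigmoid(z[:, 3 * u:])
            c = fg * c + i * g
            tc = np.tanh(c)
            h = o * tc
            z_gates[:, t] = z
            gates[:, t, :u] = i
            gates[:, t, u:2 * u] = fg
            gates[:, t, 2 * u:3 * u] = g
            gates[:, t, 3 * u:] = o
            cs[:, t] = c
            tanh_cs[:, t] = tc
            hs[:, t] = h

        argmax_t = hs.argmax(axis=1)                       # B x U
        pooled = np.take_along_axis(hs, argmax_t[:, None, :], axis=1)[:, 0, :]

        if train and self.dropout_rate > 0.0:
            if rng is None:
                raise ValueError("training-mode forward with dropout needs an rng")
            keep = 1.0 - self.dropout_rate
            mask = (rng.random(pooled.shape) < keep).astype(_F32) / _F32(keep)
            dropped = pooled * mask
        else:
            mask = None
            dropped = pooled

        head_pre = dropped @ p["Wd"] + p["bd"]
        if self.head_activation == "relu":
            y = np.maximum(head_pre, 0.0)
        elif self.head_activation == "sigmoid":
            y = _sigmoid(head_pre)
        elif self.head_activation == "softmax":
            y = _softmax(head_pre)
        else:
            y = head_pre

        cache = None
        if keep_cache:
            cache = _ForwardCache(x, gates, z_gates, cs, tanh_cs, hs,
                                  pooled, argmax_t, mask, head_pre, y)
        return y, cache

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Inference forward pass (dropout inactive)."""
        y, _ = self.forward(x, train=False)
        return y

    def center_input(self, x: np.ndarray) -> np.ndarray:
        """The network's view of the input: features minus the stored center."""
        return np.asarray(x, dtype=_F32) - self.input_center

    # -- backward ----------------------------------------------------------

    def backward(self, cache: _ForwardCache, dy_pre: np.ndarray,
                 need_dx: bool = False) -> tuple[dict[str, np.ndarray], np.ndarray | None]:
        """Backpropagate from head pre-activation gradients ``dy_pre``.

        ``dy_pre`` is the loss gradient w.r.t. ``head_pre`` (for softmax/CE the
        caller passes ``p - t`` directly; for other activations use
        :meth:`head_pre_grad`).
        """
        p = self.params
        x = cache.x
        bsz, tlen, _ = x.shape
        u = self.units

        dropped = cache.pooled if cache.drop_mask is None else cache.pooled * cache.drop_mask
        grads = {
            "Wd": dropped.T @ dy_pre,
            "bd": dy_pre.sum(axis=0),
        }
        dpooled = dy_pre @ p["Wd"].T
        if cache.drop_mask is not None:
            dpooled = dpooled * cache.drop_mask

        # Route pooled gradients to each unit's winning timestep.
        dh_ext = np.zeros((bsz, tlen, u), dtype=_F32)
        np.put_along_axis(dh_ext, cache.argmax_t[:, None, :], dpooled[:, None, :], axis=1)

        dz_all = np.empty((bsz, tlen, 4 * u), dtype=_F32)
        dWh = np.zeros_like(p["Wh"])
        dh_next = np.zeros((bsz, u), dtype=_F32)
        dc_next = np.zeros((bsz, u), dtype=_F32)
        for t in range(tlen - 1, -1, -1):
            i = cache.gates[:, t, :u]
            fg = cache.gates[:, t, u:2 * u]
            g = cache.gates[:, t, 2 * u:3 * u]
            o = cache.gates[:, t, 3 * u:]
            tc = cache.tanh_c[:, t]
            c_prev = cache.c[:, t - 1] if t > 0 else np.zeros((bsz, u), dtype=_F32)

            dh = dh_ext[:, t] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * fg

            dz = np.empty((bsz, 4 * u), dtype=_F32)
            dz[:, :u] = di * i * (1.0 - i)
            dz[:, u:2 * u] = df * fg * (1.0 - fg)
            dz[:, 2 * u:3 * u] = dg * (1.0 - g * g)
            dz[:, 3 * u:] = do * o * (1.0 - o)
            dz_all[:, t] = dz

            h_prev = cache.h[:, t - 1] if t > 0 else np.zeros((bsz, u), dtype=_F32)
            dWh += h_prev.T @ dz
            dh_next = dz @ p["Wh"].T

        dz2 = dz_all.reshape(bsz * tlen, 4 * u)
        grads["Wx"] = x.reshape(bsz * tlen, -1).T @ dz2
        grads["Wh"] = dWh
        grads["b"] = dz2.sum(axis=0)

        dx = None
        if need_dx:
            dx = (dz2 @ p["Wx"].T).reshape(bsz, tlen, -1)
        return grads, dx

    def head_pre_grad(self, cache: _ForwardCache, dy: np.ndarray) -> np.ndarray:
        """Convert a gradient w.r.t. head output into one w.r.t. pre-activation."""
        if self.head_activation == "relu":
            return dy * (cache.head_pre > 0)
        if self.head_activation == "sigmoid":
            return dy * cache.y * (1.0 - cache.y)
        if self.head_activation == "softmax":
            # Full softmax Jacobian; for CE training prefer cross_entropy_loss.
            dot = np.sum(dy * cache.y, axis=-1, keepdims=True)
            return cache.y * (dy - dot)
        return dy

    def input_gradient(self, x: np.ndarray, output_index: int = 0) -> np.ndarray:
        """d(head output[output_index]) / d(input features), inference mode."""
        single = x.ndim == 2
        y, cache = self.forward(x, train=False, keep_cache=True)
        dy = np.zeros_like(y)
        dy[:, output_index] = 1.0
        dy_pre = self.head_pre_grad(cache, dy)
        _, dx = self.backward(cache, dy_pre, need_dx=True)
        return dx[0] if single else dx

    # -- epsilon-LRP -------------------------------------------------------

    def elrp(self, x: np.ndarray, output_index: int = 0,
             epsilon: float = 1e-4) -> tuple[np.ndarray, float]:
        """Epsilon-LRP relevance of input features for one head output.

        Uses the modified-gradient formulation: epsilon-LRP equals
        input x modified-gradient, where the derivative of every
        zero-preserving nonlinearity (tanh, ReLU) in the backward pass is
        replaced by the stabilized ratio act(z) / (z + eps * sign(z)).
        Sigmoid gates keep their true derivative — their ratio sigma(z)/z
        diverges at z = 0 because sigma(0) = 1/2, so the ratio substitution
        is only well-posed for activations with act(0) = 0.  Multiplicative
        LSTM interactions pass relevance through both factors (the product
        rule), matching gradient-override LRP implementations; on purely
        linear networks the result reduces exactly to gradient x input.

        Returns ``(relevance, output_value)`` where relevance has the shape
        of ``x`` (T x F for a single clip).
        """
        if epsilon <= 0:
            raise ValueError("epsilon must be > 0 for epsilon-LRP")
        single = x.ndim == 2
        y, cache = self.forward(x, train=False, keep_cache=True)
        bsz, tlen, _ = cache.x.shape
        u = self.units
        p = self.params

        def ratio(act, z):
            return act / (z + epsilon * _sign_eps(z))

        out_val = y[:, output_index].astype(np.float64)
        head_pre = cache.head_pre.astype(np.float64)
        dy = np.zeros((bsz, self.n_outputs))
        dy[:, output_index] = 1.0
        yd = y.astype(np.float64)
        if self.head_activation == "relu":
            mg_pre = dy * ratio(yd, head_pre)
        elif self.head_activation == "sigmoid":
            mg_pre = dy * yd * (1.0 - yd)
        elif self.head_activation == "softmax":
            mg_pre = yd * (dy - np.sum(dy * yd, axis=-1, keepdims=True))
        else:
            mg_pre = dy

        dpooled = mg_pre @ p["Wd"].T.astype(np.float64)
        dh_ext = np.zeros((bsz, tlen, u))
        np.put_along_axis(dh_ext, cache.argmax_t[:, None, :],
                          dpooled[:, None, :], axis=1)

        wx = p["Wx"].astype(np.float64)
        wh = p["Wh"].astype(np.float64)
        dz_all = np.empty((bsz, tlen, 4 * u))
        dh_next = np.zeros((bsz, u))
        dc_next = np.zeros((bsz, u))
        for t in range(tlen - 1, -1, -1):
            i = cache.gates[:, t, :u].astype(np.float64)
            fg = cache.gates[:, t, u:2 * u].astype(np.float64)
            g = cache.gates[:, t, 2 * u:3 * u].astype(np.float64)
            o = cache.gates[:, t, 3 * u:].astype(np.float64)
            z = cache.z_gates[:, t].astype(np.float64)
            c = cache.c[:, t].astype(np.float64)
            tc = cache.tanh_c[:, t].astype(np.float64)
            c_prev = (cache.c[:, t - 1].astype(np.float64)
                      if t > 0 else np.zeros((bsz, u)))

            dh = dh_ext[:, t] + dh_next
            do = dh * tc
            dc = dh * o * ratio(tc, c) + dc_next
            di = dc * g
            dg = dc * i
            df = dc * c_prev
            dc_next = dc * fg

            dz = np.empty((bsz, 4 * u))
            dz[:, :u] = di * i * (1.0 - i)                   # sigmoid gate
            dz[:, u:2 * u] = df * fg * (1.0 - fg)            # sigmoid gate
            dz[:, 2 * u:3 * u] = dg * ratio(g, z[:, 2 * u:3 * u])  # tanh
            dz[:, 3 * u:] = do * o * (1.0 - o)               # sigmoid gate
            dz_all[:, t] = dz
            dh_next = dz @ wh.T

        mgrad = (dz_all.reshape(bsz * tlen, 4 * u) @ wx.T).reshape(
            bsz, tlen, self.n_features)
        r_x = (cache.x.astype(np.float64) * mgrad).astype(_F32)
        if single:
            return r_x[0], float(out_val[0])
        return r_x, out_val


@dataclass
class DenseNet:
    """A plain fully connected net used as a hand-checkable attribution oracle.

    ``weights[l]`` has shape (in, out); ``biases[l]`` shape (out,);
    ``activations[l]`` in {"relu", "linear"}.  Small enough that the epsilon-
    LRP recursion can be verified against manual arithmetic.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activations: list[str] = field(default_factory=list)

    def __post_init__(self):
        if not self.activations:
            self.activations = ["linear"] * len(self.weights)
        if not (len(self.weights) == len(self.biases) == len(self.activations)):
            raise ValueError("layer spec lengths disagree")

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, list[np.ndarray], list[np.ndarray]]:
        a = np.asarray(x, dtype=np.float64)
        pre, post = [], [a]
        for w, b, act in zip(self.weights, self.biases, self.activations):
            z = a @ w + b
            pre.append(z)
            a = np.maximum(z, 0.0) if act == "relu" else z
            post.append(a)
        return a, pre, post

    def elrp(self, x: np.ndarray, output_index: int = 0,
             epsilon: float = 1e-4) -> tuple[np.ndarray, float]:
        """Epsilon-LRP through the dense stack for one output unit."""
        y, pre, post = self.forward(x)
        r = np.zeros_like(y)
        r[..., output_index] = y[..., output_index]
        for w, z, a in zip(self.weights[::-1], pre[::-1], post[-2::-1]):
            r = eps_rule(a, w, z, r, epsilon)
        return r, float(np.asarray(y)[..., output_index])

    def input_gradient(self, x: np.ndarray, output_index: int = 0) -> np.ndarray:
        _, pre, _ = self.forward(x)
        grad = None
        for l in range(len(self.weights) - 1, -1, -1):
            if grad is None:
                grad = np.zeros_like(pre[-1])
                grad[..., output_index] = 1.0
            if self.activations[l] == "relu":
                grad = grad * (pre[l] > 0)
            grad = grad @ self.weights[l].T
        return grad
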