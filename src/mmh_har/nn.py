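"""Minimal numpy neural-network runtime.

Implements exactly the layer set the architecture specs use — dense,
(Bi)LSTM, GRU, valid 2-D convolution with stride and dilation, instance
normalization, ReLU, fold/unfold/flatten plumbing — with forward passes and
hand-written backward passes, Glorot-uniform seeded initialization, and an
Adam optimizer with a piecewise-constant learning-rate schedule.

Array layouts: sequences are ``(B, T, D)``, feature maps ``(B, H, W, C)``,
vectors ``(B, D)``. Gate order is (input, forget, cell, output) for LSTM
and (reset, update, candidate) for GRU, with a single bias vector per gate
block; the candidate GRU gate applies the reset gate to the recurrent
product, ``n = tanh(W_n x + b_n + r * (R_n h))``.
"""

from __future__ import annotations

import numpy as np

from .specs import ArchitectureSpec, infer_shapes


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            shape: tuple) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Param:
    """A weight array with its gradient accumulator."""

    def __init__(self, value: np.ndarray):
        self.value = np.asarray(value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    """Base runtime layer. Subclasses cache what backward needs."""

    def params(self) -> list[Param]:
        return []

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, gout: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class InputLayer(Layer):
    """Transposes (B, channels, samples) windows into (B, T, D) sequences."""

    def forward(self, x, train=False):
        return np.transpose(x, (0, 2, 1))

    def backward(self, gout):
        return np.transpose(gout, (0, 2, 1))


class Dense(Layer):
    def __init__(self, d: int, o: int, rng: np.random.Generator,
                 activation: str | None = None):
        self.w = Param(_glorot(rng, d, o, (d, o)))
        self.b = Param(np.zeros(o))
        self.activation = activation

    def params(self):
        return [self.w, self.b]

    def forward(self, x, train=False):
        self._x = x
        z = x @ self.w.value + self.b.value
        if self.activation == "logsig":
            self._a = _sigmoid(z)
            return self._a
        self._a = None
        return z

    def backward(self, gout):
        if self.activation == "logsig":
            gout = gout * self._a * (1.0 - self._a)
        self.w.grad += self._x.T @ gout
        self.b.grad += gout.sum(axis=0)
        return gout @ self.w.value.T


class ReLU(Layer):
    def forward(self, x, train=False):
        self._mask = x > 0
        return x * self._mask

    def backward(self, gout):
        return gout * self._mask


class SeqFold(Layer):
    """(B, T, D) sequence -> (B, D, T, 1) single-map image per window."""

    def forward(self, x, train=False):
        self._shape = x.shape
        return np.transpose(x, (0, 2, 1))[..., None]

    def backward(self, gout):
        return np.transpose(gout[..., 0], (0, 2, 1))


class SeqUnfold(Layer):
    """Restores the sequence context after a convolution block.

    ``frame`` mode (default) treats each image as one timestep and is a
    shape no-op here; ``width`` mode turns the image width into the time
    axis with rows x maps as the per-step features.
    """

    def __init__(self, mode: str = "frame"):
        self.mode = mode

    def forward(self, x, train=False):
        if self.mode == "width":
            b, h, w, c = x.shape
            self._shape = x.shape
            return np.transpose(x, (0, 2, 1, 3)).reshape(b, w, h * c)
        return x

    def backward(self, gout):
        if self.mode == "width":
            b, h, w, c = self._shape
            return np.transpose(gout.reshape(b, w, h, c), (0, 2, 1, 3))
        return gout


class Flatten(Layer):
    """Image -> length-1 feature sequence; sequence -> flat vector."""

    def forward(self, x, train=False):
        self._shape = x.shape
        if x.ndim == 4:      # (B, H, W, C) -> (B, 1, H*W*C)
            return x.reshape(x.shape[0], 1, -1)
        return x.reshape(x.shape[0], -1)  # (B, T, D) -> (B, T*D)

    def backward(self, gout):
        return gout.reshape(self._shape)


class SoftmaxHead(Layer):
    """Terminal softmax. Training happens on the logits (the model's
    cross-entropy combines log-softmax for stability), so backward here
    passes the gradient straight through."""

    def forward(self, x, train=False):
        if train:
            return x
        z = x - x.max(axis=-1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=-1, keepdims=True)

    def backward(self, gout):
        return gout


class Conv2D(Layer):
    """Valid 2-D convolution with stride and dilation, NHWC layout."""

    def __init__(self, cin: int, filters: int, kernel: tuple[int, int],
                 stride: tuple[int, int], dilation: tuple[int, int],
                 rng: np.random.Generator):
        kh, kw = kernel
        fan_in = kh * kw * cin
        self.w = Param(_glorot(rng, fan_in, filters, (kh, kw, cin, filters)))
        self.b = Param(np.zeros(filters))
        self.kernel, self.stride, self.dilation = kernel, stride, dilation

    def params(self):
        return [self.w, self.b]

    def _slices(self, h, w, oh, ow):
        kh, kw = self.kernel
        sh, sw = self.stride
        dh, dw = self.dilation
        for p in range(kh):
            for q in range(kw):
                rs = slice(p * dh, p * dh + (oh - 1) * sh + 1, sh)
                cs = slice(q * dw, q * dw + (ow - 1) * sw + 1, sw)
                yield p, q, rs, cs

    def forward(self, x, train=False):
        self._x = x
        b, h, w, c = x.shape
        kh, kw = self.kernel
        sh, sw = self.stride
        dh, dw = self.dilation
        oh = (h - ((kh - 1) * dh + 1)) // sh + 1
        ow = (w - ((kw - 1) * dw + 1)) // sw + 1
        out = np.broadcast_to(
            self.b.value, (b, oh, ow, self.b.size)
        ).copy()
        for p, q, rs, cs in self._slices(h, w, oh, ow):
            out += np.tensordot(x[:, rs, cs, :], self.w.value[p, q],
                                axes=([3], [0]))
        self._oshape = (oh, ow)
        return out

    def backward(self, gout):
        x = self._x
        b, h, w, c = x.shape
        oh, ow = self._oshape
        gx = np.zeros_like(x)
        for p, q, rs, cs in self._slices(h, w, oh, ow):
            self.w.grad[p, q] += np.tensordot(
                x[:, rs, cs, :], gout, axes=([0, 1, 2], [0, 1, 2])
            )
            gx[:, rs, cs, :] += np.tensordot(
                gout, self.w.value[p, q], axes=([3], [1])
            )
        self.b.grad += gout.sum(axis=(0, 1, 2))
        return gx


class InstanceNorm(Layer):
    """Per-observation, per-channel normalization over the spatial axes."""

    EPS = 1e-5

    def __init__(self, c: int):
        self.gamma = Param(np.ones(c))
        self.beta = Param(np.zeros(c))

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x, train=False):
        mu = x.mean(axis=(1, 2), keepdims=True)
        var = x.var(axis=(1, 2), keepdims=True)
        self._istd = 1.0 / np.sqrt(var + self.EPS)
        self._xhat = (x - mu) * self._istd
        return self.gamma.value * self._xhat + self.beta.value

    def backward(self, gout):
        xhat, istd = self._xhat, self._istd
        n = xhat.shape[1] * xhat.shape[2]
        self.gamma.grad += (gout * xhat).sum(axis=(0, 1, 2))
        self.beta.grad += gout.sum(axis=(0, 1, 2))
        gxhat = gout * self.gamma.value
        s1 = gxhat.sum(axis=(1, 2), keepdims=True)
        s2 = (gxhat * xhat).sum(axis=(1, 2), keepdims=True)
        return (istd / n) * (n * gxhat - s1 - xhat * s2)


class LSTMCore:
    """One LSTM direction. Gate order (i, f, g, o); W (d,4h), R (h,4h)."""

    def __init__(self, d: int, h: int, rng: np.random.Generator):
        self.d, self.h = d, h
        self.w = Param(_glorot(rng, d, 4 * h, (d, 4 * h)))
        self.r = Param(_glorot(rng, h, 4 * h, (h, 4 * h)))
        self.b = Param(np.zeros(4 * h))

    def params(self):
        return [self.w, self.r, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        """x: (B, T, d) -> hidden sequence (B, T, h)."""
        b, t, d = x.shape
        h = self.h
        xw = x.reshape(b * t, d) @ self.w.value
        xw = xw.reshape(b, t, 4 * h) + self.b.value
        hs = np.zeros((b, t, h))
        self._gates = np.empty((b, t, 4 * h))
        self._cs = np.zeros((b, t, h))
        self._tanhc = np.zeros((b, t, h))
        h_prev = np.zeros((b, h))
        c_prev = np.zeros((b, h))
        for step in range(t):
            z = xw[:, step] + h_prev @ self.r.value
            i = _sigmoid(z[:, :h])
            f = _sigmoid(z[:, h:2 * h])
            g = np.tanh(z[:, 2 * h:3 * h])
            o = _sigmoid(z[:, 3 * h:])
            c = f * c_prev + i * g
            tc = np.tanh(c)
            hcur = o * tc
            self._gates[:, step] = np.concatenate([i, f, g, o], axis=1)
            self._cs[:, step] = c
            self._tanhc[:, step] = tc
            hs[:, step] = hcur
            h_prev, c_prev = hcur, c
        self._x, self._hs = x, hs
        return hs

    def backward(self, ghs: np.ndarray) -> np.ndarray:
        """ghs: gradient w.r.t. the full hidden sequence (B, T, h)."""
        x, hs = self._x, self._hs
        b, t, d = x.shape
        h = self.h
        dz_all = np.empty((b, t, 4 * h))
        dh_next = np.zeros((b, h))
        dc_next = np.zeros((b, h))
        for step in range(t - 1, -1, -1):
            i = self._gates[:, step, :h]
            f = self._gates[:, step, h:2 * h]
            g = self._gates[:, step, 2 * h:3 * h]
            o = self._gates[:, step, 3 * h:]
            tc = self._tanhc[:, step]
            c_prev = self._cs[:, step - 1] if step > 0 else np.zeros((b, h))
            dh = ghs[:, step] + dh_next
            do = dh * tc
            dc = dh * o * (1.0 - tc * tc) + dc_next
            df = dc * c_prev
            di = dc * g
            dg = dc * i
            dc_next = dc * f
            dz = np.concatenate(
                [di * i * (1 - i), df * f * (1 - f),
                 dg * (1 - g * g), do * o * (1 - o)], axis=1,
            )
            dz_all[:, step] = dz
            dh_next = dz @ self.r.value.T
            if step > 0:
                self.r.grad += hs[:, step - 1].T @ dz
        dz_flat = dz_all.reshape(b * t, 4 * h)
        self.w.grad += x.reshape(b * t, d).T @ dz_flat
        self.b.grad += dz_flat.sum(axis=0)
        gx = (dz_flat @ self.w.value.T).reshape(b, t, d)
        return gx


class GRUCore:
    """One GRU direction. Gate order (r, z, n); W (d,3h), R (h,3h)."""

    def __init__(self, d: int, h: int, rng: np.random.Generator):
        self.d, self.h = d, h
        self.w = Param(_glorot(rng, d, 3 * h, (d, 3 * h)))
        self.r = Param(_glorot(rng, h, 3 * h, (h, 3 * h)))
        self.b = Param(np.zeros(3 * h))

    def params(self):
        return [self.w, self.r, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        b, t, d = x.shape
        h = self.h
        xw = x.reshape(b * t, d) @ self.w.value
        xw = xw.reshape(b, t, 3 * h) + self.b.value
        hs = np.zeros((b, t, h))
        self._cache = []
        h_prev = np.zeros((b, h))
        for step in range(t):
            rh = h_prev @ self.r.value  # (B, 3h): [Rr h, Rz h, Rn h]
            r = _sigmoid(xw[:, step, :h] + rh[:, :h])
            z = _sigmoid(xw[:, step, h:2 * h] + rh[:, h:2 * h])
            n = np.tanh(xw[:, step, 2 * h:] + r * rh[:, 2 * h:])
            hcur = (1.0 - z) * n + z * h_prev
            self._cache.append((r, z, n, rh[:, 2 * h:], h_prev))
            hs[:, step] = hcur
            h_prev = hcur
        self._x, self._hs = x, hs
        return hs

    def backward(self, ghs: np.ndarray) -> np.ndarray:
        x = self._x
        b, t, d = x.shape
        h = self.h
        dz_all = np.empty((b, t, 3 * h))
        dh_next = np.zeros((b, h))
        for step in range(t - 1, -1, -1):
            r, z, n, rnh, h_prev = self._cache[step]
            dh = ghs[:, step] + dh_next
            dz_gate = dh * (h_prev - n)
            dn = dh * (1.0 - z)
            dh_prev = dh * z
            dn_pre = dn * (1.0 - n * n)
            dr = dn_pre * rnh
            drnh = dn_pre * r
            dr_pre = dr * r * (1.0 - r)
            dz_pre = dz_gate * z * (1.0 - z)
            dz = np.concatenate([dr_pre, dz_pre, dn_pre], axis=1)
            dz_all[:, step] = dz
            # recurrent grads: r and z gates see h_prev directly, the
            # candidate gate sees it through r * (R_n h_prev)
            dh_prev = dh_prev + \
                np.concatenate([dr_pre, dz_pre, drnh], axis=1) @ self.r.value.T
            self.r.grad += h_prev.T @ np.concatenate(
                [dr_pre, dz_pre, drnh], axis=1
            )
            dh_next = dh_prev
        dz_flat = dz_all.reshape(b * t, 3 * h)
        self.w.grad += x.reshape(b * t, d).T @ dz_flat
        self.b.grad += dz_flat.sum(axis=0)
        return (dz_flat @ self.w.value.T).reshape(b, t, d)


class Recurrent(Layer):
    """(Bi)LSTM / GRU layer over (B, T, D) or (B, D) inputs.

    Output mode is the last timestep's hidden state (concatenated across
    directions for the bidirectional case) unless ``return_sequences``.
    """

    def __init__(self, kind: str, d: int, h: int, rng: np.random.Generator,
                 return_sequences: bool = False):
        self.kind = kind
        self.return_sequences = return_sequences
        core = GRUCore if kind == "gru" else LSTMCore
        self.fwd = core(d, h, rng)
        self.bwd = core(d, h, rng) if kind == "bilstm" else None

    def params(self):
        ps = self.fwd.params()
        if self.bwd is not None:
            ps = ps + self.bwd.params()
        return ps

    def forward(self, x, train=False):
        self._was_vec = x.ndim == 2
        if self._was_vec:
            x = x[:, None, :]
        hs_f = self.fwd.forward(x)
        if self.bwd is not None:
            hs_b = self.bwd.forward(x[:, ::-1])[:, ::-1]
            if self.return_sequences:
                return np.concatenate([hs_f, hs_b], axis=2)
            # forward direction's last step + backward direction's first
            # (which is the last the reversed pass computed)
            return np.concatenate([hs_f[:, -1], hs_b[:, 0]], axis=1)
        if self.return_sequences:
            return hs_f
        return hs_f[:, -1]

    def backward(self, gout):
        t = self.fwd._x.shape[1]
        h = self.fwd.h
        if self.bwd is not None:
            if self.return_sequences:
                gf, gb = gout[..., :h], gout[..., h:]
            else:
                gf = np.zeros((gout.shape[0], t, h))
                gb = np.zeros((gout.shape[0], t, h))
                gf[:, -1] = gout[:, :h]
                gb[:, 0] = gout[:, h:]
            gx = self.fwd.backward(gf) + \
                self.bwd.backward(gb[:, ::-1])[:, ::-1]
        else:
            if self.return_sequences:
                gseq = gout
            else:
                gseq = np.zeros((gout.shape[0], t, h))
                gseq[:, -1] = gout
            gx = self.fwd.backward(gseq)
        if self._was_vec:
            gx = gx[:, 0, :]
        return gx


# ---------------------------------------------------------------------------
# Model assembly
# ---------------------------------------------------------------------------

def build_runtime(spec: ArchitectureSpec, seed: int = 0) -> "Model":
    """Instantiate seeded runtime layers from an architecture spec."""
    from .specs import layer_input_shapes

    rng = np.random.default_rng(seed)
    in_shapes = layer_input_shapes(spec)
    layers: list[Layer] = []
    for lspec, ishape in zip(spec.layers, in_shapes):
        k = lspec.kind
        if k == "sequence_input":
            layers.append(InputLayer())
        elif k == "seq_fold":
            layers.append(SeqFold())
        elif k == "seq_unfold":
            layers.append(SeqUnfold(lspec.p("mode", "frame")))
        elif k == "flatten":
            layers.append(Flatten())
        elif k == "relu":
            layers.append(ReLU())
        elif k == "softmax":
            layers.append(SoftmaxHead())
        elif k == "conv2d":
            cin = ishape[3]
            layers.append(Conv2D(
                cin, lspec.p("filters"), tuple(lspec.p("kernel")),
                tuple(lspec.p("stride", (1, 1))),
                tuple(lspec.p("dilation", (1, 1))), rng,
            ))
        elif k == "instance_norm":
            layers.append(InstanceNorm(ishape[3]))
        elif k in ("bilstm", "lstm", "gru"):
            d = ishape[2] if ishape[0] == "seq" else ishape[1]
            layers.append(Recurrent(
                k, d, lspec.p("units"), rng,
                return_sequences=lspec.p("return_sequences", False),
            ))
        elif k in ("dense", "encoder_dense"):
            d = ishape[1]
            layers.append(Dense(
                d, lspec.p("units"), rng,
                activation=lspec.p("activation"),
            ))
        else:  # pragma: no cover - spec validation catches this earlier
            raise ValueError(f"unsupported layer kind {k}")
    return Model(spec, layers)


class Model:
    """A runtime network: ordered layers plus the training loss."""

    def __init__(self, spec: ArchitectureSpec, layers: list[Layer]):
        self.spec = spec
        self.layers = layers

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def n_params(self) -> int:
        return sum(p.size for p in self.params())

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, gout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            gout = layer.backward(gout)
        return gout

    def zero_grad(self) -> None:
        for p in self.params():
            p.grad[...] = 0.0

    def loss_and_grad(self, x: np.ndarray, y: np.ndarray,
                      l2: float = 0.0) -> float:
        """Cross-entropy on logits; fills parameter grads (plus L2)."""
        logits = self.forward(x, train=True)
        zmax = logits.max(axis=1, keepdims=True)
        logz = zmax + np.log(np.exp(logits - zmax).sum(axis=1, keepdims=True))
        n = x.shape[0]
        loss = float(
            (logz.squeeze(1) - logits[np.arange(n), y]).mean()
        )
        p = np.exp(logits - logz)
        g = p
        g[np.arange(n), y] -= 1.0
        g /= n
        self.backward(g)
        if l2 > 0:
            for prm in self.params():
                loss += 0.5 * l2 * float((prm.value ** 2).sum())
                prm.grad += l2 * prm.value
        return loss

    def per_layer_output_shapes(self) -> list[tuple]:
        """Tagged output shapes, identical to the spec-level inference."""
        return infer_shapes(self.spec)


class Adam:
    """Adam with a piecewise-constant learning-rate drop schedule."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def step(self, lr: float | None = None) -> None:
        lr = self.lr if lr is None else lr
        self.t += 1
        b1c = 1.0 - self.beta1 ** self.t
        b2c = 1.0 - self.beta2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * p.grad
            v *= self.beta2
            v += (1 - self.beta2) * p.grad ** 2
            p.value -= lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)
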