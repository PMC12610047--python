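"""Independent brute-force oracles for the test suite.

The op-counting oracle executes layer forward passes scalar-by-scalar with
explicit Python loops, incrementing counters for every multiplication and
addition actually performed (MAC = multiplications inside dot products).
Transcendental activations, divisions and square roots are not counted.
These loops are deliberately naive; they share no code with the analytic
profiler.
"""

from __future__ import annotations

import math

import numpy as np


class OpCounter:
    """Counts scalar multiplications/additions; MACs are dot-product mults."""

    def __init__(self) -> None:
        self.mac = 0
        self.mults = 0
        self.adds = 0

    @property
    def ma(self) -> int:
        return self.mults + self.adds

    def mul(self, a: float, b: float, dot: bool = False) -> float:
        self.mults += 1
        if dot:
            self.mac += 1
        return a * b

    def add(self, a: float, b: float) -> float:
        self.adds += 1
        return a + b


def dense_forward(ctr: OpCounter, x: np.ndarray, w: np.ndarray,
                  b: np.ndarray) -> np.ndarray:
    """x (d,), w (d, o), b (o,) -> (o,)"""
    d, o = w.shape
    out = np.empty(o)
    for j in range(o):
        acc = ctr.mul(x[0], w[0, j], dot=True)
        for i in range(1, d):
            acc = ctr.add(acc, ctr.mul(x[i], w[i, j], dot=True))
        out[j] = ctr.add(acc, b[j])
    return out


def conv2d_forward(ctr: OpCounter, x: np.ndarray, w: np.ndarray,
                   b: np.ndarray, stride: tuple[int, int],
                   dilation: tuple[int, int]) -> np.ndarray:
    """x (H, W, C), w (kh, kw, C, F), b (F,) -> valid convolution output."""
    h, wid, c = x.shape
    kh, kw, _, f = w.shape
    sh, sw = stride
    dh, dw = dilation
    oh = (h - ((kh - 1) * dh + 1)) // sh + 1
    ow = (wid - ((kw - 1) * dw + 1)) // sw + 1
    out = np.empty((oh, ow, f))
    for i in range(oh):
        for j in range(ow):
            for fo in range(f):
                acc = None
                for p in range(kh):
                    for q in range(kw):
                        for ci in range(c):
                            term = ctr.mul(
                                x[i * sh + p * dh, j * sw + q * dw, ci],
                                w[p, q, ci, fo], dot=True,
                            )
                            acc = term if acc is None else ctr.add(acc, term)
                out[i, j, fo] = ctr.add(acc, b[fo])
    return out


def instance_norm_forward(ctr: OpCounter, x: np.ndarray, gamma: np.ndarray,
                          beta: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """x (H, W, C), per-channel statistics over the spatial axes."""
    h, w, c = x.shape
    n = h * w
    out = np.empty_like(x)
    for ci in range(c):
        flat = x[:, :, ci].ravel()
        acc = flat[0]
        for v in flat[1:]:
            acc = ctr.add(acc, v)
        mean = acc / n  # division not counted
        centered = np.empty(n)
        for i, v in enumerate(flat):
            centered[i] = ctr.add(v, -mean)
        acc = ctr.mul(centered[0], centered[0])
        for v in centered[1:]:
            acc = ctr.add(acc, ctr.mul(v, v))
        var = acc / n
        istd = 1.0 / math.sqrt(var + eps)  # sqrt/div not counted
        for i in range(n):
            y = ctr.mul(centered[i], istd)
            y = ctr.mul(y, gamma[ci])
            out[i // w, i % w, ci] = ctr.add(y, beta[ci])
    return out


def _sig(v: float) -> float:
    return 1.0 / (1.0 + math.exp(-v))


def _gate_row(ctr: OpCounter, x: np.ndarray, h_prev: np.ndarray,
              wcol: np.ndarray, rcol: np.ndarray, bias: float) -> float:
    """One gate unit: x . wcol + h_prev . rcol + bias, all counted."""
    acc = ctr.mul(x[0], wcol[0], dot=True)
    for i in range(1, x.size):
        acc = ctr.add(acc, ctr.mul(x[i], wcol[i], dot=True))
    acc2 = ctr.mul(h_prev[0], rcol[0], dot=True)
    for i in range(1, h_prev.size):
        acc2 = ctr.add(acc2, ctr.mul(h_prev[i], rcol[i], dot=True))
    return ctr.add(ctr.add(acc, acc2), bias)


def lstm_forward(ctr: OpCounter, x: np.ndarray, w: np.ndarray,
                 r: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (T, d); gate order (i, f, g, o); returns (T, h)."""
    t_len, d = x.shape
    h = w.shape[1] // 4
    hs = np.zeros((t_len, h))
    h_prev = np.zeros(h)
    c_prev = np.zeros(h)
    for t in range(t_len):
        i_g = np.empty(h)
        f_g = np.empty(h)
        g_g = np.empty(h)
        o_g = np.empty(h)
        for u in range(h):
            i_g[u] = _sig(_gate_row(ctr, x[t], h_prev, w[:, u], r[:, u], b[u]))
            f_g[u] = _sig(_gate_row(ctr, x[t], h_prev, w[:, h + u],
                                    r[:, h + u], b[h + u]))
            g_g[u] = math.tanh(_gate_row(ctr, x[t], h_prev, w[:, 2 * h + u],
                                         r[:, 2 * h + u], b[2 * h + u]))
            o_g[u] = _sig(_gate_row(ctr, x[t], h_prev, w[:, 3 * h + u],
                                    r[:, 3 * h + u], b[3 * h + u]))
        c = np.empty(h)
        h_new = np.empty(h)
        for u in range(h):
            c[u] = ctr.add(ctr.mul(f_g[u], c_prev[u]),
                           ctr.mul(i_g[u], g_g[u]))
            h_new[u] = ctr.mul(o_g[u], math.tanh(c[u]))
        h_prev, c_prev = h_new, c
        hs[t] = h_new
    return hs


def gru_forward(ctr: OpCounter, x: np.ndarray, w: np.ndarray,
                r: np.ndarray, b: np.ndarray) -> np.ndarray:
    """x (T, d); gate order (r, z, n); candidate applies the reset gate to
    the recurrent product. Returns (T, h)."""
    t_len, d = x.shape
    h = w.shape[1] // 3
    hs = np.zeros((t_len, h))
    h_prev = np.zeros(h)
    for t in range(t_len):
        r_g = np.empty(h)
        z_g = np.empty(h)
        n_g = np.empty(h)
        for u in range(h):
            r_g[u] = _sig(_gate_row(ctr, x[t], h_prev, w[:, u], r[:, u], b[u]))
            z_g[u] = _sig(_gate_row(ctr, x[t], h_prev, w[:, h + u],
                                    r[:, h + u], b[h + u]))
        for u in range(h):
            # W_n x + b_n
            acc = ctr.mul(x[t][0], w[0, 2 * h + u], dot=True)
            for i in range(1, d):
                acc = ctr.add(acc, ctr.mul(x[t][i], w[i, 2 * h + u], dot=True))
            # R_n h_prev
            acc2 = ctr.mul(h_prev[0], r[0, 2 * h + u], dot=True)
            for i in range(1, h):
                acc2 = ctr.add(acc2, ctr.mul(h_prev[i], r[i, 2 * h + u],
                                             dot=True))
            gated = ctr.mul(r_g[u], acc2)  # elementwise, not a MAC
            n_g[u] = math.tanh(ctr.add(ctr.add(acc, gated), b[2 * h + u]))
        h_new = np.empty(h)
        for u in range(h):
            one_minus_z = ctr.add(1.0, -z_g[u])
            h_new[u] = ctr.add(ctr.mul(one_minus_z, n_g[u]),
                               ctr.mul(z_g[u], h_prev[u]))
        hs[t] = h_new
        h_prev = h_new
    return hs


def rms_envelope_naive(x: np.ndarray, fs: float,
                       window_ms: float = 250.0) -> np.ndarray:
    """O(n*w) per-sample sliding RMS with shrink-to-valid edges."""
    x = np.asarray(x, dtype=float)
    w = int(round(window_ms * fs / 1000.0))
    n = x.size
    left = (w - 1) // 2
    right = w - left
    out = np.empty(n)
    for i in range(n):
        a, b = max(0, i - left), min(n, i + right)
        acc = 0.0
        for j in range(a, b):
            acc += x[j] * x[j]
        out[i] = math.sqrt(acc / (b - a))
    return out
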