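"""Analytic network-complexity accounting.

From an :class:`ArchitectureSpec` alone (no runtime model needed) this
module counts learnable parameters (LP), multiply-accumulate operations
(MAC), total multiplications-plus-additions (MA), the memory needed to
store the parameters, and an estimated inference latency on an embedded
target.

Counting conventions (pinned by an instrumented-forward-pass oracle in the
test suite):

* LP — dense/encoder: (d+1)*o; LSTM per direction: 4h(d+h+1); GRU:
  3h(d+h+1); BiLSTM: twice the LSTM count; conv2d: (kh*kw*cin + 1)*F;
  instance norm: 2 per channel; everything else: 0.
* MAC — multiplications inside dot products (dense rows, convolution
  kernels, recurrent gate matrix products), accumulated over the full
  inference of one input: dense d*o; conv kh*kw*cin per output element;
  recurrent G*h*(d+h) per timestep per direction (G = 4 for LSTM, 3 for
  GRU), every timestep counted including the first.
* MA — all scalar multiplications and additions: dot-product mults and
  adds, bias adds, gate-combination adds, elementwise gate arithmetic, and
  instance-norm statistics. Transcendental activations (sigmoid, tanh,
  exp), divisions and square roots are excluded, as is the softmax.

Memory uses 4 bytes per parameter and the MiB convention
(1 MB = 1,048,576 bytes), the unique pairing consistent with reporting
750,607 parameters as 2.863 MB.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .specs import ArchitectureSpec, LayerSpec, layer_input_shapes, infer_shapes


class UnsupportedLayerError(ValueError):
    """The profiler has no closed form for this layer kind."""


@dataclass(frozen=True)
class LayerComplexity:
    kind: str
    lp: int
    mac: int
    mults: int
    adds: int

    @property
    def ma(self) -> int:
        return self.mults + self.adds


@dataclass(frozen=True)
class ComplexityReport:
    """Whole-network complexity: LP, MAC, MA, parameter memory (MB, MiB
    convention, 3 decimals) and estimated latency in seconds."""

    name: str
    lp: int
    mac: int
    ma: int
    memory_mb: float
    latency_s: float
    per_layer: tuple[LayerComplexity, ...]

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lp": self.lp,
            "mac": self.mac,
            "ma": self.ma,
            "memory_mb": self.memory_mb,
            "latency_s": self.latency_s,
            "per_layer": [
                {"kind": l.kind, "lp": l.lp, "mac": l.mac, "ma": l.ma}
                for l in self.per_layer
            ],
        }


def _recurrent_dims(layer: LayerSpec, ishape: tuple) -> tuple[int, int, int]:
    """(T, d, h) seen by a recurrent layer."""
    h = layer.p("units")
    if ishape[0] == "seq":
        return ishape[1], ishape[2], h
    return 1, ishape[1], h


def _layer_complexity(layer: LayerSpec, ishape: tuple,
                      oshape: tuple) -> LayerComplexity:
    k = layer.kind
    if k in ("sequence_input", "seq_fold", "seq_unfold", "flatten",
             "relu", "softmax"):
        return LayerComplexity(k, 0, 0, 0, 0)

    if k in ("dense", "encoder_dense"):
        d = ishape[1]
        o = layer.p("units")
        lp = (d + 1) * o
        mac = d * o
        mults = d * o
        adds = (d - 1) * o + o  # dot-product sums + bias
        return LayerComplexity(k, lp, mac, mults, adds)

    if k == "conv2d":
        _, h, w, cin = ishape
        _, oh, ow, f = oshape
        kh, kw = layer.p("kernel")
        kk = kh * kw * cin
        lp = (kk + 1) * f
        vol = oh * ow * f
        mac = kk * vol
        mults = kk * vol
        adds = (kk - 1) * vol + vol  # kernel sums + bias per output element
        return LayerComplexity(k, lp, mac, mults, adds)

    if k == "instance_norm":
        _, h, w, c = ishape
        n = h * w
        lp = 2 * c
        # per channel: mean (n-1 adds), centering (n adds), variance
        # (n mults + n-1 adds), then per element scale by 1/std and gamma
        # (2 mults) and beta (1 add); sqrt and the division are excluded
        mults = c * (n + 2 * n)
        adds = c * ((n - 1) + n + (n - 1) + n)
        return LayerComplexity(k, lp, 0, mults, adds)

    if k in ("lstm", "bilstm", "gru"):
        t, d, h = _recurrent_dims(layer, ishape)
        gates = 3 if k == "gru" else 4
        dirs = 2 if k == "bilstm" else 1
        lp = dirs * gates * h * (d + h + 1)
        mac_step = gates * h * (d + h)
        dot_mults = gates * h * (d + h)
        # per gate row: (d-1)+(h-1) dot adds + combine + bias = d+h adds
        dot_adds = gates * h * (d + h)
        if k == "gru":
            # r*(Rn h): h mults; (1-z): h adds; (1-z)*n + z*h: 2h mults,
            # h adds
            elem_mults = 3 * h
            elem_adds = 2 * h
        else:
            # c = f*c_prev + i*g: 2h mults + h adds; h = o*tanh(c): h mults
            elem_mults = 3 * h
            elem_adds = h
        mults = t * dirs * (dot_mults + elem_mults)
        adds = t * dirs * (dot_adds + elem_adds)
        return LayerComplexity(k, lp, t * dirs * mac_step, mults, adds)

    raise UnsupportedLayerError(f"no complexity model for layer kind {k!r}")


def per_layer_complexity(spec: ArchitectureSpec) -> list[LayerComplexity]:
    ins = layer_input_shapes(spec)
    outs = infer_shapes(spec)
    return [
        _layer_complexity(layer, i, o)
        for layer, i, o in zip(spec.layers, ins, outs)
    ]


def count_learnables(spec: ArchitectureSpec) -> int:
    """Total learnable parameters (weights and biases)."""
    return sum(l.lp for l in per_layer_complexity(spec))


def count_mac(spec: ArchitectureSpec) -> int:
    """Multiply-accumulate operations over one full inference."""
    return sum(l.mac for l in per_layer_complexity(spec))


def count_ma(spec: ArchitectureSpec) -> int:
    """Total scalar multiplications + additions over one full inference."""
    return sum(l.ma for l in per_layer_complexity(spec))


def memory_mb(lp: int, bytes_per_param: int = 4) -> float:
    """Parameter storage in MB (MiB convention), rounded to 3 decimals."""
    if lp < 0:
        raise ValueError(f"parameter count must be non-negative, got {lp}")
    return round(lp * bytes_per_param / 1_048_576, 3)


def latency_estimate(
    total_ops: int, attainable_ops_per_s: float, efficiency: float = 0.7
) -> float:
    """Estimated inference time: ops / (attainable rate x efficiency).

    The efficiency factor (default 0.7) accounts for kernel inefficiency
    on the embedded target."""
    if attainable_ops_per_s <= 0:
        raise ValueError("attainable_ops_per_s must be positive")
    if not (0.0 < efficiency <= 1.0):
        raise ValueError("efficiency must be in (0, 1]")
    return total_ops / (attainable_ops_per_s * efficiency)


#: Default attainable scalar-op rate used for latency estimates: a small
#: embedded x86 CPU sustaining ~8 Gops/s before the efficiency factor.
DEFAULT_ATTAINABLE_OPS_PER_S = 8.0e9


def profile(
    spec: ArchitectureSpec,
    attainable_ops_per_s: float = DEFAULT_ATTAINABLE_OPS_PER_S,
    efficiency: float = 0.7,
) -> ComplexityReport:
    """Full complexity report for one architecture. Latency is estimated
    from the MA count (every scalar operation of one inference)."""
    layers = per_layer_complexity(spec)
    lp = sum(l.lp for l in layers)
    mac = sum(l.mac for l in layers)
    ma = sum(l.ma for l in layers)
    return ComplexityReport(
        name=spec.name,
        lp=lp,
        mac=mac,
        ma=ma,
        memory_mb=memory_mb(lp),
        latency_s=latency_estimate(ma, attainable_ops_per_s, efficiency),
        per_layer=tuple(layers),
    )


def markdown_table(reports: list[ComplexityReport]) -> str:
    """Comparison table mirroring the usual complexity-summary columns."""
    header = "| Metric | " + " | ".join(r.name for r in reports) + " |"
    sep = "|" + "---|" * (len(reports) + 1)
    rows = [
        ("MAC", [f"{r.mac:,}" for r in reports]),
        ("MA", [f"{r.ma:,}" for r in reports]),
        ("LP", [f"{r.lp:,}" for r in reports]),
        ("Memory (MB)", [f"{r.memory_mb:.3f}" for r in reports]),
        ("Latency (ms)", [f"{r.latency_s * 1e3:.3f}" for r in reports]),
    ]
    lines = [header, sep]
    for name, vals in rows:
        lines.append("| " + name + " | " + " | ".join(vals) + " |")
    return "\n".join(lines)
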