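"""Declarative network architectures and shape inference.

An :class:`ArchitectureSpec` is an ordered list of :class:`LayerSpec`
entries (layer kind + hyperparameters). Both the runtime model builder and
the analytic complexity profiler consume the same spec, so the two can
never disagree about shapes or parameter counts.

Shape inference tracks three tagged shapes:

* ``("seq", T, d)``  — a sequence of ``T`` feature vectors of size ``d``;
* ``("img", h, w, c)`` — a 2-D feature map inside a fold/unfold block;
* ``("vec", d)``     — a flat feature vector.

Convolution output sizes follow the valid-convolution closed form
``out = floor((in - dilated_kernel) / stride) + 1`` with
``dilated_kernel = (k - 1) * dilation + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from .activities import N_CHANNELS, N_CLASSES, WINDOW_SAMPLES

LAYER_KINDS = {
    "sequence_input", "bilstm", "lstm", "gru", "dense", "softmax",
    "conv2d", "instance_norm", "relu", "seq_fold", "seq_unfold",
    "flatten", "encoder_dense",
}


class SpecError(ValueError):
    """An architecture spec is malformed or shape-inconsistent."""


@dataclass(frozen=True)
class LayerSpec:
    """One layer: its kind and the hyperparameters that define it."""

    kind: str
    params: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in LAYER_KINDS:
            raise SpecError(f"unknown layer kind {self.kind!r}")

    def p(self, key: str, default: Any = None) -> Any:
        return self.params.get(key, default)


@dataclass(frozen=True)
class ArchitectureSpec:
    """Named ordered layer graph with a fixed input window and class count."""

    name: str
    layers: tuple[LayerSpec, ...]
    input_shape: tuple[int, int] = (N_CHANNELS, WINDOW_SAMPLES)
    n_classes: int = N_CLASSES

    def __post_init__(self) -> None:
        object.__setattr__(self, "layers", tuple(self.layers))

    def validate(self, classifier: bool = True) -> None:
        """Check structural invariants and the whole shape chain."""
        if not self.layers:
            raise SpecError(f"{self.name}: empty layer list")
        if self.layers[0].kind != "sequence_input":
            raise SpecError(f"{self.name}: first layer must be sequence_input")
        if classifier:
            if (
                len(self.layers) < 3
                or self.layers[-1].kind != "softmax"
                or self.layers[-2].kind != "dense"
                or self.layers[-2].p("units") != self.n_classes
            ):
                raise SpecError(
                    f"{self.name}: classifier specs must end with "
                    f"dense(->{self.n_classes}) then softmax"
                )
        infer_shapes(self)  # raises SpecError on any inconsistency

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "input_shape": list(self.input_shape),
            "n_classes": self.n_classes,
            "layers": [
                {"kind": l.kind, "params": dict(l.params)} for l in self.layers
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArchitectureSpec":
        return cls(
            name=d["name"],
            layers=tuple(
                LayerSpec(l["kind"], dict(l["params"])) for l in d["layers"]
            ),
            input_shape=tuple(d["input_shape"]),
            n_classes=d["n_classes"],
        )


def conv_out(size: int, k: int, stride: int, dilation: int) -> int:
    """Valid-convolution output length along one axis."""
    dk = (k - 1) * dilation + 1
    return (size - dk) // stride + 1


def _infer_one(layer: LayerSpec, shape: tuple, name: str, idx: int) -> tuple:
    """Output shape of ``layer`` given the tagged input ``shape``."""
    kind = layer.kind
    err = lambda msg: SpecError(f"{name}: layer {idx} ({kind}): {msg}")

    if kind == "sequence_input":
        ch = layer.p("channels")
        ts = layer.p("samples")
        return ("seq", ts, ch)

    if kind == "seq_fold":
        if shape[0] != "seq":
            raise err(f"expects a sequence, got {shape}")
        _, t, d = shape
        return ("img", d, t, 1)

    if kind == "conv2d":
        if shape[0] != "img":
            raise err(f"expects a feature map, got {shape}")
        _, h, w, c = shape
        kh, kw = layer.p("kernel")
        sh, sw = layer.p("stride", (1, 1))
        dh, dw = layer.p("dilation", (1, 1))
        oh = conv_out(h, kh, sh, dh)
        ow = conv_out(w, kw, sw, dw)
        if oh < 1 or ow < 1:
            raise err(
                f"non-positive output map {oh}x{ow} from input {h}x{w} with "
                f"kernel {kh}x{kw}, stride {sh}x{sw}, dilation {dh}x{dw}"
            )
        return ("img", oh, ow, layer.p("filters"))

    if kind in ("instance_norm", "relu"):
        return shape

    if kind == "seq_unfold":
        if shape[0] != "img":
            raise err(f"expects a feature map, got {shape}")
        _, h, w, c = shape
        if layer.p("mode", "frame") == "width":
            # image width becomes the time axis; rows x maps become features
            return ("seq", w, h * c)
        return shape  # frame mode: restores the (length-1) image sequence

    if kind == "flatten":
        if shape[0] == "img":
            _, h, w, c = shape
            return ("seq", 1, h * w * c)
        if shape[0] == "seq":
            _, t, d = shape
            return ("vec", t * d)
        raise err(f"cannot flatten {shape}")

    if kind in ("bilstm", "lstm", "gru"):
        hu = layer.p("units")
        if hu is None or hu < 1:
            raise err(f"units must be >= 1, got {hu}")
        if shape[0] == "seq":
            t, d = shape[1], shape[2]
        elif shape[0] == "vec":
            t, d = 1, shape[1]  # a single feature vector = length-1 sequence
        else:
            raise err(f"expects a sequence or vector, got {shape}")
        width = 2 * hu if kind == "bilstm" else hu
        if layer.p("return_sequences", False):
            return ("seq", t, width)
        return ("vec", width)

    if kind in ("dense", "encoder_dense"):
        if shape[0] != "vec":
            raise err(f"expects a flat vector, got {shape}")
        units = layer.p("units")
        if units is None or units < 1:
            raise err(f"units must be >= 1, got {units}")
        return ("vec", units)

    if kind == "softmax":
        if shape[0] != "vec":
            raise err(f"expects a flat vector, got {shape}")
        return shape

    raise err("unsupported kind")


def infer_shapes(spec: ArchitectureSpec) -> list[tuple]:
    """Per-layer output shapes; raises :class:`SpecError` on inconsistency."""
    shapes: list[tuple] = []
    shape: tuple = ("none",)
    for idx, layer in enumerate(spec.layers):
        shape = _infer_one(layer, shape, spec.name, idx)
        shapes.append(shape)
    return shapes


def layer_input_shapes(spec: ArchitectureSpec) -> list[tuple]:
    """Input shape seen by each layer (the predecessor's output)."""
    outs = infer_shapes(spec)
    return [("none",)] + outs[:-1]
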