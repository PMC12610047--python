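"""Complexity accounting: LP closed forms, the MiB memory convention,
MAC/MA against the instrumented-forward-pass oracle, latency, and
cross-module consistency with the runtime parameter store."""

import numpy as np
import pytest

from mmh_har.complexity import (
    count_learnables, count_ma, count_mac, latency_estimate, memory_mb,
    per_layer_complexity, profile,
)
from mmh_har.models import (
    SpDAEConfig, build_bilstm, build_deepconvlstm, build_rcnn,
    build_recurrent_spdae, build_spdae,
)
from mmh_har.nn import build_runtime
from mmh_har.specs import ArchitectureSpec, LayerSpec

from oracles import (
    OpCounter, conv2d_forward, dense_forward, gru_forward,
    instance_norm_forward, lstm_forward,
)


class TestLearnableParameters:
    def test_bilstm_300_matches_published_count(self):
        assert count_learnables(build_bilstm(300)) == 750_607

    def test_bilstm_1_closed_form(self):
        # 8*1*10 + 8*1*1 + 8*1 (bidirectional LSTM) + (2+1)*7 (dense+bias)
        assert count_learnables(build_bilstm(1)) == 96 + 21

    def test_dense_closed_form(self):
        spec = ArchitectureSpec("d", (
            LayerSpec("sequence_input", {"channels": 10, "samples": 60}),
            LayerSpec("flatten"),
            LayerSpec("dense", {"units": 7}),
            LayerSpec("softmax"),
        ), input_shape=(10, 60))
        # (600+1)*7
        assert count_learnables(spec) == 4_207

    def test_conv_closed_form(self):
        spec = ArchitectureSpec("c", (
            LayerSpec("sequence_input", {"channels": 10, "samples": 240}),
            LayerSpec("seq_fold"),
            LayerSpec("conv2d", {"filters": 32, "kernel": (3, 3),
                                 "stride": (1, 1), "dilation": (1, 1)}),
        ))
        # (9*1+1)*32
        assert count_learnables(spec) == 320

    @pytest.mark.parametrize("build", [
        lambda: build_bilstm(5),
        lambda: build_rcnn(6),
        lambda: build_deepconvlstm(4),
        lambda: build_recurrent_spdae(8, 3),
        lambda: build_spdae(SpDAEConfig(hidden_units=9)).classifier,
    ])
    def test_lp_equals_runtime_parameter_store(self, build):
        spec = build()
        assert count_learnables(spec) == build_runtime(spec, 0).n_params()


class TestMemory:
    @pytest.mark.parametrize("lp,mb", [
        (750_607, 2.863),
        (756_675, 2.886),
        (15_989_191, 60.994),
        (0, 0.0),
    ])
    def test_mib_convention_reproduces_published_cells(self, lp, mb):
        assert memory_mb(lp) == pytest.approx(mb, abs=5e-4)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            memory_mb(-1)


class TestLatency:
    def test_unit_ratio(self):
        assert latency_estimate(1000, 1000.0, efficiency=1.0) == 1.0

    def test_efficiency_factor(self):
        assert latency_estimate(1000, 1000.0, efficiency=0.7) == \
            pytest.approx(1 / 0.7)

    def test_zero_ops(self):
        assert latency_estimate(0, 1e9) == 0.0

    def test_bad_rate_rejected(self):
        with pytest.raises(ValueError):
            latency_estimate(10, 0.0)


def _spec_ops_oracle(spec: ArchitectureSpec, seed: int) -> OpCounter:
    """Run the instrumented scalar forward pass through every countable
    layer of a (tiny) spec, reusing the runtime model's actual weights."""
    from mmh_har.specs import infer_shapes, layer_input_shapes

    rng = np.random.default_rng(seed)
    model = build_runtime(spec, seed=seed)
    ins = layer_input_shapes(spec)
    ctr = OpCounter()
    for layer, rt, ishape in zip(spec.layers, model.layers, ins):
        k = layer.kind
        if k in ("dense", "encoder_dense"):
            x = rng.standard_normal(ishape[1])
            dense_forward(ctr, x, rt.w.value, rt.b.value)
        elif k == "conv2d":
            x = rng.standard_normal(ishape[1:])
            conv2d_forward(ctr, x, rt.w.value, rt.b.value,
                           layer.p("stride", (1, 1)),
                           layer.p("dilation", (1, 1)))
        elif k == "instance_norm":
            x = rng.standard_normal(ishape[1:])
            instance_norm_forward(ctr, x, rt.gamma.value, rt.beta.value)
        elif k in ("lstm", "gru", "bilstm"):
            t = ishape[1] if ishape[0] == "seq" else 1
            d = ishape[2] if ishape[0] == "seq" else ishape[1]
            x = rng.standard_normal((t, d))
            fwd = gru_forward if k == "gru" else lstm_forward
            fwd(ctr, x, rt.fwd.w.value, rt.fwd.r.value, rt.fwd.b.value)
            if k == "bilstm":
                lstm_forward(ctr, x[::-1], rt.bwd.w.value, rt.bwd.r.value,
                             rt.bwd.b.value)
    return ctr


def _random_tiny_spec(rng: np.random.Generator) -> ArchitectureSpec:
    """One of several tiny countable architectures with random dims."""
    choice = rng.integers(0, 4)
    ch = int(rng.integers(2, 5))
    t = int(rng.integers(6, 14))
    if choice == 0:
        layers = (
            LayerSpec("sequence_input", {"channels": ch, "samples": t}),
            LayerSpec("bilstm", {"units": int(rng.integers(1, 5))}),
            LayerSpec("dense", {"units": 7}),
            LayerSpec("softmax"),
        )
    elif choice == 1:
        layers = (
            LayerSpec("sequence_input", {"channels": ch, "samples": t}),
            LayerSpec("gru", {"units": int(rng.integers(1, 5))}),
            LayerSpec("dense", {"units": 7}),
            LayerSpec("softmax"),
        )
    elif choice == 2:
        layers = (
            LayerSpec("sequence_input", {"channels": ch, "samples": t}),
            LayerSpec("seq_fold"),
            LayerSpec("conv2d", {
                "filters": int(rng.integers(1, 4)),
                "kernel": (2, 2),
                "stride": (1, int(rng.integers(1, 3))),
                "dilation": (1, int(rng.integers(1, 3))),
            }),
            LayerSpec("instance_norm"),
            LayerSpec("relu"),
            LayerSpec("seq_unfold"),
            LayerSpec("flatten"),
            LayerSpec("gru", {"units": int(rng.integers(1, 4))}),
            LayerSpec("dense", {"units": 7}),
            LayerSpec("softmax"),
        )
    else:
        layers = (
            LayerSpec("sequence_input", {"channels": ch, "samples": t}),
            LayerSpec("flatten"),
            LayerSpec("encoder_dense",
                      {"units": int(rng.integers(2, 6)),
                       "activation": "logsig"}),
            LayerSpec("dense", {"units": 7}),
            LayerSpec("softmax"),
        )
    spec = ArchitectureSpec(f"tiny{choice}", layers, input_shape=(ch, t))
    spec.validate()
    return spec


class TestMacMaOracle:
    def test_dense_examples(self):
        ctr = OpCounter()
        rng = np.random.default_rng(0)
        dense_forward(ctr, rng.standard_normal(3),
                      rng.standard_normal((3, 2)), rng.standard_normal(2))
        assert ctr.mac == 6          # 3*2 products
        assert ctr.ma == 6 + 6       # 6 mults + 4 sum-adds + 2 bias-adds

    def test_conv_example(self):
        ctr = OpCounter()
        rng = np.random.default_rng(0)
        conv2d_forward(ctr, rng.standard_normal((3, 3, 1)),
                       rng.standard_normal((2, 2, 1, 1)), np.zeros(1),
                       (1, 1), (1, 1))
        assert ctr.mac == 16         # 2x2 output volume x 4 products

    def test_analytic_dense_ma(self):
        spec = ArchitectureSpec("d32", (
            LayerSpec("sequence_input", {"channels": 3, "samples": 1}),
            LayerSpec("flatten"),
            LayerSpec("dense", {"units": 2}),
        ), input_shape=(3, 1))
        assert count_mac(spec) == 6
        assert count_ma(spec) == 12

    def test_analytic_equals_oracle_on_random_tiny_specs(self):
        """30 random tiny specs: the closed-form MAC/MA totals equal the
        instrumented scalar forward pass, operation for operation."""
        rng = np.random.default_rng(2024)
        for trial in range(30):
            spec = _random_tiny_spec(rng)
            ctr = _spec_ops_oracle(spec, seed=trial)
            assert count_mac(spec) == ctr.mac, spec.name
            assert count_ma(spec) == ctr.ma, spec.name

    def test_monotonicity_adding_a_layer(self):
        """Appending a countable layer never decreases LP, MAC or MA."""
        base = build_bilstm(4)
        widened = ArchitectureSpec("wide", (
            base.layers[0],
            LayerSpec("bilstm", {"units": 4, "return_sequences": True}),
            base.layers[1],
            base.layers[2],
            base.layers[3],
        ))
        widened.validate()
        assert count_learnables(widened) >= count_learnables(base)
        assert count_mac(widened) >= count_mac(base)
        assert count_ma(widened) >= count_ma(base)


class TestProfileReport:
    def test_report_totals_are_sums_of_layers(self):
        rep = profile(build_rcnn(10))
        assert rep.lp == sum(l.lp for l in rep.per_layer)
        assert rep.mac == sum(l.mac for l in rep.per_layer)
        assert rep.ma == sum(l.ma for l in rep.per_layer)
        assert rep.memory_mb == memory_mb(rep.lp)
        assert rep.latency_s > 0
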