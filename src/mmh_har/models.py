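"""Architecture builders, trainers, and prediction.

Five networks are covered: the proposed BiLSTM, sparse denoising
autoencoder (Sp-DAE), recurrent Sp-DAE and RCNN, plus the DeepConvLSTM
benchmark. Builders return declarative :class:`ArchitectureSpec` objects;
:func:`train` turns any classifier spec into a fitted model by minimizing
cross-entropy with Adam, a piecewise-constant learning-rate drop schedule
and L2 regularization. The Sp-DAE is pre-trained unsupervised on corrupted
inputs with the sparse MSE objective (reconstruction error + L2 weight
penalty + KL sparsity penalty on mean hidden activations) using scipy's
nonlinear conjugate-gradient optimizer, after which the decoder is
discarded and the encoder feeds a softmax classifier.

Inputs are standardized per channel with statistics estimated on the
training set; the statistics travel with the trained model so prediction
applies the identical transform.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .activities import N_CHANNELS, N_CLASSES, WINDOW_SAMPLES
from .nn import Adam, Model, build_runtime, _sigmoid
from .preprocess import SegmentSet
from .specs import ArchitectureSpec, LayerSpec, SpecError

logger = logging.getLogger(__name__)

_FLAT_INPUT = N_CHANNELS * WINDOW_SAMPLES  # 2400


class ConfigError(ValueError):
    """A training configuration value is out of range."""


class DegenerateLabelsError(ValueError):
    """The training set contains fewer than two classes."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite."""


# ---------------------------------------------------------------------------
# Configs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    """Supervised training hyperparameters.

    The learning rate follows lr_t = initial_lr * lr_drop_factor **
    floor(epoch / lr_drop_period); ``lr_floor`` optionally caps the decay
    from below (the literal schedule underflows for epoch counts in the
    thousands).
    """

    optimizer: str = "adam"
    max_epochs: int = 30
    batch_size: int = 128
    initial_lr: float = 1e-3
    lr_drop_factor: float = 0.1
    lr_drop_period: int = 10
    l2: float = 1e-4
    seed: int = 0
    lr_floor: float | None = None

    def __post_init__(self) -> None:
        if self.max_epochs < 1:
            raise ConfigError(f"max_epochs must be >= 1, got {self.max_epochs}")
        if self.batch_size < 1 or self.initial_lr <= 0 or self.l2 < 0:
            raise ConfigError("batch_size, initial_lr, l2 out of range")
        if not (0.0 < self.lr_drop_factor <= 1.0):
            raise ConfigError("lr_drop_factor must be in (0, 1]")
        if self.lr_drop_period < 1:
            raise ConfigError("lr_drop_period must be >= 1")

    def lr_at(self, epoch: int) -> float:
        lr = self.initial_lr * self.lr_drop_factor ** (
            epoch // self.lr_drop_period
        )
        if self.lr_floor is not None:
            lr = max(lr, self.lr_floor)
        return lr


@dataclass(frozen=True)
class SpDAEConfig:
    """Sparse denoising autoencoder hyperparameters.

    sparsity_proportion is the target mean activation rho of each hidden
    unit, sparsity_regularization the KL penalty weight beta, l2 the weight
    penalty lambda; corruption_sd is the denoising input-noise level on
    standardized inputs. Transfer function is the log-sigmoid.
    """

    hidden_units: int = 100
    max_epochs: int = 50
    sparsity_regularization: float = 1.0
    sparsity_proportion: float = 0.05
    l2: float = 1e-4
    corruption_sd: float = 0.05
    optimizer: str = "cg"

    def __post_init__(self) -> None:
        if not (0.0 < self.sparsity_proportion < 1.0):
            raise ConfigError("sparsity_proportion must be in (0, 1)")
        if self.sparsity_regularization < 0 or self.l2 < 0:
            raise ConfigError("penalty weights must be non-negative")
        if self.hidden_units < 1:
            raise ConfigError("hidden_units must be >= 1")
        if self.optimizer not in ("cg", "adam"):
            raise ConfigError("optimizer must be 'cg' or 'adam'")


# ---------------------------------------------------------------------------
# Builders
# ---------------------------------------------------------------------------

def build_bilstm(
    h: int, n_in: int = N_CHANNELS, n_classes: int = N_CLASSES,
    samples: int = WINDOW_SAMPLES,
) -> ArchitectureSpec:
    """Sequence input -> BiLSTM(h) -> dense(2h -> n_classes) -> softmax.

    The recurrent layer emits its last timestep (per direction)."""
    if h < 1:
        raise ValueError(f"hidden units must be >= 1, got {h}")
    spec = ArchitectureSpec(
        name=f"bilstm_h{h}",
        layers=(
            LayerSpec("sequence_input", {"channels": n_in, "samples": samples}),
            LayerSpec("bilstm", {"units": h}),
            LayerSpec("dense", {"units": n_classes}),
            LayerSpec("softmax"),
        ),
        input_shape=(n_in, samples),
        n_classes=n_classes,
    )
    spec.validate()
    return spec


@dataclass(frozen=True)
class SpDAESpecs:
    """The unsupervised reconstruction spec and the classifier spec that
    shares its encoder."""

    autoencoder: ArchitectureSpec
    classifier: ArchitectureSpec


def build_spdae(cfg: SpDAEConfig, n_in: int = _FLAT_INPUT) -> SpDAESpecs:
    """Autoencoder over the flattened window plus its derived classifier.

    The autoencoder reconstructs the flattened 10 x 240 input through a
    log-sigmoid encoder and a linear decoder; the classifier drops the
    decoder and stacks dense(h -> 7) + softmax on the encoder."""
    h = cfg.hidden_units
    inp = LayerSpec(
        "sequence_input",
        {"channels": N_CHANNELS, "samples": n_in // N_CHANNELS},
    )
    enc = LayerSpec("encoder_dense", {"units": h, "activation": "logsig"})
    auto = ArchitectureSpec(
        name=f"spdae_h{h}_auto",
        layers=(inp, LayerSpec("flatten"), enc,
                LayerSpec("dense", {"units": n_in})),
        input_shape=(N_CHANNELS, n_in // N_CHANNELS),
    )
    auto.validate(classifier=False)
    clf = ArchitectureSpec(
        name=f"spdae_h{h}",
        layers=(inp, LayerSpec("flatten"), enc,
                LayerSpec("dense", {"units": N_CLASSES}),
                LayerSpec("softmax")),
        input_shape=(N_CHANNELS, n_in // N_CHANNELS),
    )
    clf.validate()
    return SpDAESpecs(autoencoder=auto, classifier=clf)


def build_recurrent_spdae(
    encoder_h: int, bilstm_h: int
) -> ArchitectureSpec:
    """BiLSTM stacked on the Sp-DAE encoder.

    The encoder maps each window's flattened input to one feature vector,
    which the BiLSTM consumes as a length-1 sequence (per-window features;
    the alternative per-timestep wiring is not the default)."""
    if encoder_h < 1 or bilstm_h < 1:
        raise ValueError("hidden unit counts must be >= 1")
    spec = ArchitectureSpec(
        name=f"rec_spdae_e{encoder_h}_h{bilstm_h}",
        layers=(
            LayerSpec("sequence_input",
                      {"channels": N_CHANNELS, "samples": WINDOW_SAMPLES}),
            LayerSpec("flatten"),
            LayerSpec("encoder_dense",
                      {"units": encoder_h, "activation": "logsig"}),
            LayerSpec("bilstm", {"units": bilstm_h}),
            LayerSpec("dense", {"units": N_CLASSES}),
            LayerSpec("softmax"),
        ),
    )
    spec.validate()
    return spec


def build_rcnn(h: int, n_classes: int = N_CLASSES) -> ArchitectureSpec:
    """The 14-layer recurrent CNN: two valid 3x3 convolution blocks (32
    maps; the second with stride 1x4 and dilation 2x2) inside a
    fold/unfold pair, flattened into a GRU, then dense + softmax."""
    if h < 1:
        raise ValueError(f"hidden units must be >= 1, got {h}")
    spec = ArchitectureSpec(
        name=f"rcnn_h{h}",
        layers=(
            LayerSpec("sequence_input",
                      {"channels": N_CHANNELS, "samples": WINDOW_SAMPLES}),
            LayerSpec("seq_fold"),
            LayerSpec("conv2d", {"filters": 32, "kernel": (3, 3),
                                 "stride": (1, 1), "dilation": (1, 1)}),
            LayerSpec("instance_norm"),
            LayerSpec("relu"),
            LayerSpec("conv2d", {"filters": 32, "kernel": (3, 3),
                                 "stride": (1, 4), "dilation": (2, 2)}),
            LayerSpec("instance_norm"),
            LayerSpec("relu"),
            LayerSpec("seq_unfold"),
            LayerSpec("flatten"),
            LayerSpec("gru", {"units": h}),
            LayerSpec("dense", {"units": n_classes}),
            LayerSpec("softmax"),
        ),
        n_classes=n_classes,
    )
    spec.validate()
    return spec


def build_deepconvlstm(h: int = 128, n_in: int = N_CHANNELS) -> ArchitectureSpec:
    """The DeepConvLSTM benchmark: four temporal convolutions (64 maps,
    5-wide kernels along the time axis) followed by two stacked LSTM
    layers, dense and softmax. Four valid 5-wide convolutions shrink the
    240-sample axis to 224; per-step features are 64 maps x 10 rows."""
    if h < 1:
        raise ValueError(f"hidden units must be >= 1, got {h}")
    conv = lambda: LayerSpec("conv2d", {"filters": 64, "kernel": (1, 5),
                                        "stride": (1, 1), "dilation": (1, 1)})
    spec = ArchitectureSpec(
        name=f"deepconvlstm_h{h}",
        layers=(
            LayerSpec("sequence_input",
                      {"channels": n_in, "samples": WINDOW_SAMPLES}),
            LayerSpec("seq_fold"),
            conv(), LayerSpec("relu"),
            conv(), LayerSpec("relu"),
            conv(), LayerSpec("relu"),
            conv(), LayerSpec("relu"),
            LayerSpec("seq_unfold", {"mode": "width"}),
            LayerSpec("lstm", {"units": h, "return_sequences": True}),
            LayerSpec("lstm", {"units": h}),
            LayerSpec("dense", {"units": N_CLASSES}),
            LayerSpec("softmax"),
        ),
        input_shape=(n_in, WINDOW_SAMPLES),
    )
    spec.validate()
    return spec


BUILDERS = {
    "bilstm": build_bilstm,
    "rcnn": build_rcnn,
    "deepconvlstm": build_deepconvlstm,
}


# ---------------------------------------------------------------------------
# Trained model container
# ---------------------------------------------------------------------------

@dataclass
class TrainedModel:
    """A fitted network: spec, runtime weights, loss history, and the
    per-channel standardization statistics estimated on the training set."""

    spec: ArchitectureSpec
    model: Model
    history: list[float]
    train_seed: int
    mu: np.ndarray
    sd: np.ndarray

    def standardize(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mu[None, :, None]) / self.sd[None, :, None]


def _channel_stats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = x.mean(axis=(0, 2))
    sd = x.std(axis=(0, 2))
    sd = np.where(sd < 1e-8, 1.0, sd)
    return mu, sd


def train(
    spec: ArchitectureSpec, train_set: SegmentSet, cfg: TrainConfig,
    init_weights: list[np.ndarray] | None = None,
) -> TrainedModel:
    """Minimize cross-entropy on the segment set with Adam.

    Deterministic given ``cfg.seed`` on a fixed device. ``init_weights``
    optionally seeds specific parameter tensors (used to transplant a
    pre-trained encoder); entries that are ``None`` keep the random init.
    """
    if len(train_set) == 0:
        raise ValueError("training set is empty")
    x, y = train_set.xy_arrays()
    if np.unique(y).size < 2:
        raise DegenerateLabelsError(
            "training set must contain at least 2 classes"
        )
    mu, sd = _channel_stats(x)
    xs = (x - mu[None, :, None]) / sd[None, :, None]

    model = build_runtime(spec, seed=cfg.seed)
    if init_weights is not None:
        for prm, w in zip(model.params(), init_weights):
            if w is not None:
                if prm.value.shape != w.shape:
                    raise SpecError(
                        f"init weight shape {w.shape} != {prm.value.shape}"
                    )
                prm.value[...] = w
    opt = Adam(model.params(), lr=cfg.initial_lr)
    rng = np.random.default_rng(cfg.seed + 1)
    n = xs.shape[0]
    history: list[float] = []
    for epoch in range(cfg.max_epochs):
        lr = cfg.lr_at(epoch)
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            model.zero_grad()
            loss = model.loss_and_grad(xs[idx], y[idx], l2=cfg.l2)
            if not np.isfinite(loss):
                raise DivergenceError(
                    f"non-finite training loss at epoch {epoch}"
                )
            opt.step(lr=lr)
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return TrainedModel(
        spec=spec, model=model, history=history, train_seed=cfg.seed,
        mu=mu, sd=sd,
    )


def predict(
    model: TrainedModel, segments: SegmentSet | np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class-probability rows and argmax labels (lowest index on ties)."""
    if isinstance(segments, SegmentSet):
        x, _ = segments.xy_arrays()
    else:
        x = np.asarray(segments)
    expect = model.spec.input_shape
    if x.ndim != 3 or x.shape[1:] != expect:
        raise ValueError(
            f"input shape {x.shape[1:]} does not match spec {expect}"
        )
    xs = model.standardize(x)
    proba = model.model.forward(xs, train=False)
    return proba, np.argmax(proba, axis=1)


# ---------------------------------------------------------------------------
# Sparse denoising autoencoder
# ---------------------------------------------------------------------------

_RHO_EPS = 1e-12


def sparse_mse_loss(
    x: np.ndarray, x_hat: np.ndarray, weights: list[np.ndarray],
    rho_hat: np.ndarray, cfg: SpDAEConfig,
) -> float:
    """Sparse MSE: mean squared reconstruction error + lambda * sum of
    squared weights + beta * sum_i KL(rho || rho_hat_i)."""
    if x.shape != x_hat.shape:
        raise ValueError("x and x_hat shapes disagree")
    rho = cfg.sparsity_proportion
    rh = np.asarray(rho_hat, dtype=float)
    if np.any(rh <= 0.0) or np.any(rh >= 1.0):
        logger.warning("clamping mean activations to [%g, 1-%g]",
                       _RHO_EPS, _RHO_EPS)
        rh = np.clip(rh, _RHO_EPS, 1.0 - _RHO_EPS)
    mse = float(np.mean((x - x_hat) ** 2))
    l2 = sum(float((w ** 2).sum()) for w in weights)
    kl = float(np.sum(
        rho * np.log(rho / rh) + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rh))
    ))
    return mse + cfg.l2 * l2 + cfg.sparsity_regularization * kl


def spdae_pretrain(
    x_flat: np.ndarray, cfg: SpDAEConfig, seed: int = 0,
) -> dict[str, np.ndarray]:
    """Unsupervised sparse denoising pre-training of the encoder.

    Corrupts the (standardized, flattened) inputs with Gaussian noise once,
    then minimizes the sparse MSE objective over encoder and decoder
    weights with nonlinear conjugate gradients (``cfg.max_epochs``
    iterations), or Adam full-batch steps when ``cfg.optimizer == "adam"``.
    Returns the encoder (and decoder) weight arrays.
    """
    n, d = x_flat.shape
    h = cfg.hidden_units
    rng = np.random.default_rng(seed)
    x_noisy = x_flat + cfg.corruption_sd * rng.standard_normal(x_flat.shape)

    limit_e = np.sqrt(6.0 / (d + h))
    limit_d = np.sqrt(6.0 / (h + d))
    w_enc0 = rng.uniform(-limit_e, limit_e, (d, h))
    w_dec0 = rng.uniform(-limit_d, limit_d, (h, d))
    b_enc0 = np.zeros(h)
    b_dec0 = np.zeros(d)
    shapes = [(d, h), (h,), (h, d), (d,)]
    sizes = [int(np.prod(s)) for s in shapes]

    def unpack(theta):
        parts = np.split(theta, np.cumsum(sizes)[:-1])
        return [p.reshape(s) for p, s in zip(parts, shapes)]

    rho = cfg.sparsity_proportion
    beta = cfg.sparsity_regularization

    def objective(theta):
        w_e, b_e, w_d, b_d = unpack(theta)
        a = _sigmoid(x_noisy @ w_e + b_e)          # (n, h)
        x_hat = a @ w_d + b_d                      # (n, d)
        rho_hat = np.clip(a.mean(axis=0), _RHO_EPS, 1.0 - _RHO_EPS)
        err = x_hat - x_flat
        loss = float(np.mean(err ** 2))
        loss += cfg.l2 * (float((w_e ** 2).sum()) + float((w_d ** 2).sum()))
        loss += beta * float(np.sum(
            rho * np.log(rho / rho_hat)
            + (1 - rho) * np.log((1 - rho) / (1 - rho_hat))
        ))
        # gradients
        gerr = 2.0 * err / err.size                # d mse / d x_hat
        gw_d = a.T @ gerr + 2.0 * cfg.l2 * w_d
        gb_d = gerr.sum(axis=0)
        ga = gerr @ w_d.T
        gkl_rho = beta * (-rho / rho_hat + (1 - rho) / (1 - rho_hat))
        ga = ga + gkl_rho[None, :] / n
        gz = ga * a * (1.0 - a)
        gw_e = x_noisy.T @ gz + 2.0 * cfg.l2 * w_e
        gb_e = gz.sum(axis=0)
        grad = np.concatenate(
            [gw_e.ravel(), gb_e.ravel(), gw_d.ravel(), gb_d.ravel()]
        )
        return loss, grad

    theta0 = np.concatenate(
        [w_enc0.ravel(), b_enc0, w_dec0.ravel(), b_dec0]
    )
    if cfg.optimizer == "cg":
        res = optimize.minimize(
            objective, theta0, jac=True, method="CG",
            options={"maxiter": cfg.max_epochs},
        )
        theta = res.x
    else:  # Adam fallback, full batch
        theta = theta0.copy()
        m = np.zeros_like(theta)
        v = np.zeros_like(theta)
        for t in range(1, cfg.max_epochs + 1):
            _, g = objective(theta)
            m = 0.9 * m + 0.1 * g
            v = 0.999 * v + 0.001 * g ** 2
            mhat = m / (1 - 0.9 ** t)
            vhat = v / (1 - 0.999 ** t)
            theta -= 1e-3 * mhat / (np.sqrt(vhat) + 1e-8)
    w_e, b_e, w_d, b_d = unpack(theta)
    return {"w_enc": w_e, "b_enc": b_e, "w_dec": w_d, "b_dec": b_d}


def train_spdae(
    spdae_cfg: SpDAEConfig, train_set: SegmentSet, cfg: TrainConfig,
) -> TrainedModel:
    """Full Sp-DAE pipeline: unsupervised encoder pre-training, decoder
    discarded, classifier trained supervised from the pre-trained encoder."""
    specs = build_spdae(spdae_cfg)
    x, y = train_set.xy_arrays()
    mu, sd = _channel_stats(x)
    xs = (x - mu[None, :, None]) / sd[None, :, None]
    x_flat = xs.transpose(0, 2, 1).reshape(xs.shape[0], -1)
    pre = spdae_pretrain(x_flat, spdae_cfg, seed=cfg.seed)
    # classifier params: [encoder w, encoder b, dense w, dense b]
    init = [pre["w_enc"], pre["b_enc"], None, None]
    return train(specs.classifier, train_set, cfg, init_weights=init)


def train_recurrent_spdae(
    encoder_h: int, bilstm_h: int, spdae_cfg: SpDAEConfig,
    train_set: SegmentSet, cfg: TrainConfig,
) -> TrainedModel:
    """Recurrent Sp-DAE: pre-trained encoder feeding a BiLSTM classifier."""
    spdae_cfg = SpDAEConfig(
        hidden_units=encoder_h, max_epochs=spdae_cfg.max_epochs,
        sparsity_regularization=spdae_cfg.sparsity_regularization,
        sparsity_proportion=spdae_cfg.sparsity_proportion,
        l2=spdae_cfg.l2, corruption_sd=spdae_cfg.corruption_sd,
        optimizer=spdae_cfg.optimizer,
    )
    spec = build_recurrent_spdae(encoder_h, bilstm_h)
    x, y = train_set.xy_arrays()
    mu, sd = _channel_stats(x)
    xs = (x - mu[None, :, None]) / sd[None, :, None]
    x_flat = xs.transpose(0, 2, 1).reshape(xs.shape[0], -1)
    pre = spdae_pretrain(x_flat, spdae_cfg, seed=cfg.seed)
    init = [pre["w_enc"], pre["b_enc"]] + [None] * (
        len(build_runtime(spec, seed=0).params()) - 2
    )
    return train(spec, train_set, cfg, init_weights=init)


# ---------------------------------------------------------------------------
# Reference recurrence (test oracle)
# ---------------------------------------------------------------------------

def rnn_forward_oracle(
    kind: str, weights: dict[str, np.ndarray], x: np.ndarray
) -> np.ndarray:
    """Straight-line per-timestep reference recurrence for tiny layers.

    ``x`` is one unbatched sequence (T, d). For ``lstm``/``gru`` returns
    the (T, h) hidden sequence of a single direction given weights
    ``{"w", "r", "b"}``; for ``bilstm`` returns (T, 2h) given
    ``{"w_f", "r_f", "b_f", "w_b", "r_b", "b_b"}`` with the backward
    direction run over the reversed input and re-reversed.
    """
    def sig(v):
        return 1.0 / (1.0 + np.exp(-v))

    if kind == "bilstm":
        fwd = rnn_forward_oracle(
            "lstm",
            {"w": weights["w_f"], "r": weights["r_f"], "b": weights["b_f"]},
            x,
        )
        bwd = rnn_forward_oracle(
            "lstm",
            {"w": weights["w_b"], "r": weights["r_b"], "b": weights["b_b"]},
            x[::-1],
        )[::-1]
        return np.concatenate([fwd, bwd], axis=1)

    w, r, b = weights["w"], weights["r"], weights["b"]
    t_len, d = x.shape
    if kind == "lstm":
        h = w.shape[1] // 4
        hs = np.zeros((t_len, h))
        h_prev = np.zeros(h)
        c_prev = np.zeros(h)
        for t in range(t_len):
            z = x[t] @ w + h_prev @ r + b
            i = sig(z[:h])
            f = sig(z[h:2 * h])
            g = np.tanh(z[2 * h:3 * h])
            o = sig(z[3 * h:])
            c = f * c_prev + i * g
            h_prev = o * np.tanh(c)
            c_prev = c
            hs[t] = h_prev
        return hs
    if kind == "gru":
        h = w.shape[1] // 3
        hs = np.zeros((t_len, h))
        h_prev = np.zeros(h)
        for t in range(t_len):
            xw = x[t] @ w + b
            rh = h_prev @ r
            rg = sig(xw[:h] + rh[:h])
            zg = sig(xw[h:2 * h] + rh[h:2 * h])
            n = np.tanh(xw[2 * h:] + rg * rh[2 * h:])
            h_prev = (1.0 - zg) * n + zg * h_prev
            hs[t] = h_prev
        return hs
    raise ValueError(f"unsupported oracle kind {kind!r}")


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

def save_model(tm: TrainedModel, path) -> None:
    """Spec JSON + weights + normalizer in one portable npz container."""
    arrays = {
        f"p{i}": p.value for i, p in enumerate(tm.model.params())
    }
    np.savez_compressed(
        path,
        spec_json=np.array(json.dumps(tm.spec.to_dict())),
        history=np.array(tm.history),
        train_seed=np.array(tm.train_seed),
        mu=tm.mu, sd=tm.sd, **arrays,
    )


def load_model(path) -> TrainedModel:
    with np.load(path, allow_pickle=False) as z:
        spec = ArchitectureSpec.from_dict(json.loads(str(z["spec_json"])))
        model = build_runtime(spec, seed=0)
        for i, p in enumerate(model.params()):
            p.value[...] = z[f"p{i}"]
        return TrainedModel(
            spec=spec, model=model,
            history=[float(v) for v in z["history"]],
            train_seed=int(z["train_seed"]), mu=z["mu"], sd=z["sd"],
        )
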