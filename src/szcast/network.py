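"""Mean-field variational convolutional network for seizure forecasting.

Every weight carries a Gaussian posterior N(mu, sigma^2) with sigma =
softplus(rho); the prior is standard normal per weight.  Training minimizes
the negative evidence lower bound: mean cross-entropy plus a down-weighted
closed-form KL term, with reparameterized gradients and one weight
realization per mini-batch.  The whole stack (strided valid convolutions,
2x2 max-pooling, dense layers, Adam) is implemented on NumPy so the package
has no deep-learning framework dependency.

The first convolution's kernels span all input channels (valid padding along
the channel axis collapses it), which is exactly a 2-D convolution with
``n_channels`` input feature maps; subsequent 3x3 convolutions operate on the
resulting feature-map grid.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .preprocess import STFTSegment

# ---------------------------------------------------------------------------
# Architecture description


@dataclass(frozen=True)
class ConvSpec:
    kind: str = field(default="conv", init=False)
    out_channels: int = 16
    kernel: tuple[int, int] = (5, 5)
    stride: tuple[int, int] = (1, 1)


@dataclass(frozen=True)
class PoolSpec:
    kind: str = field(default="pool", init=False)
    size: tuple[int, int] = (2, 2)


@dataclass(frozen=True)
class FlattenSpec:
    kind: str = field(default="flatten", init=False)


@dataclass(frozen=True)
class DenseSpec:
    kind: str = field(default="dense", init=False)
    out_features: int = 2


LayerSpec = ConvSpec | PoolSpec | FlattenSpec | DenseSpec


@dataclass
class NetworkSpec:
    """Ordered layer descriptors applied to (n_channels, *input_shape) inputs.

    ``input_center``/``input_scale`` standardize inputs at the network
    boundary (fitted on the training set, stored with the checkpoint).
    """

    n_channels: int
    layers: list[LayerSpec]
    input_shape: tuple[int, int] = (56, 128)
    input_center: float = 0.0
    input_scale: float = 1.0

    def feature_shapes(self) -> list[tuple[int, ...]]:
        """Output shape after each layer; validates the architecture."""
        shape: tuple[int, ...] = (self.n_channels, *self.input_shape)
        out = []
        for i, layer in enumerate(self.layers):
            if isinstance(layer, ConvSpec):
                c, h, w = shape
                kh, kw = layer.kernel
                sh, sw = layer.stride
                if kh > h or kw > w:
                    raise ValueError(
                        f"layer {i}: kernel {layer.kernel} larger than input {shape}"
                    )
                shape = (
                    layer.out_channels,
                    (h - kh) // sh + 1,
                    (w - kw) // sw + 1,
                )
            elif isinstance(layer, PoolSpec):
                c, h, w = shape
                ph, pw = layer.size
                if h < ph or w < pw:
                    raise ValueError(f"layer {i}: pool {layer.size} larger than {shape}")
                shape = (c, h // ph, w // pw)
            elif isinstance(layer, FlattenSpec):
                shape = (int(np.prod(shape)),)
            elif isinstance(layer, DenseSpec):
                if len(shape) != 1:
                    raise ValueError(f"layer {i}: dense layer needs flattened input")
                shape = (layer.out_features,)
            else:  # pragma: no cover
                raise TypeError(f"unknown layer spec {layer!r}")
            out.append(shape)
        return out


def default_spec(n_channels: int, width_scale: float = 1.0) -> NetworkSpec:
    """The reference architecture: 16/64/128 conv kernels, 256/2 dense units.

    ``width_scale < 1`` shrinks layer widths proportionally for desk-scale
    experiments while preserving the layer pattern.
    """

    def w(k: int) -> int:
        return max(1, int(round(k * width_scale)))

    return NetworkSpec(
        n_channels=n_channels,
        layers=[
            ConvSpec(w(16), (5, 5), (2, 2)),
            PoolSpec((2, 2)),
            ConvSpec(w(64), (3, 3), (1, 1)),
            PoolSpec((2, 2)),
            ConvSpec(w(128), (3, 3), (1, 1)),
            PoolSpec((2, 2)),
            FlattenSpec(),
            DenseSpec(w(256)),
            DenseSpec(2),
        ],
    )


# ---------------------------------------------------------------------------
# Variational parameters


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def softplus_inv(y: float) -> float:
    return float(np.log(np.expm1(y)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class VariationalLayer:
    """Gaussian posterior parameters (mu, rho) for one trainable layer.

    Conv weights have shape (out, in, kh, kw); dense weights (in, out).
    sigma = softplus(rho) elementwise.
    """

    mu_w: np.ndarray
    rho_w: np.ndarray
    mu_b: np.ndarray
    rho_b: np.ndarray
    layer_kind: str

    @property
    def sigma_w(self) -> np.ndarray:
        return softplus(self.rho_w)

    @property
    def sigma_b(self) -> np.ndarray:
        return softplus(self.rho_b)

    def params(self) -> list[np.ndarray]:
        return [self.mu_w, self.rho_w, self.mu_b, self.rho_b]


def init_layers(
    spec: NetworkSpec, seed: int = 0, sigma_init: float = 0.05
) -> list[VariationalLayer]:
    """He-scaled mu initialization; rho set so sigma starts at ``sigma_init``."""
    rng = np.random.default_rng(seed)
    rho0 = softplus_inv(sigma_init)
    shape: tuple[int, ...] = (spec.n_channels, *spec.input_shape)
    out: list[VariationalLayer] = []
    for layer, next_shape in zip(spec.layers, spec.feature_shapes()):
        if isinstance(layer, ConvSpec):
            fan_in = shape[0] * layer.kernel[0] * layer.kernel[1]
            w_shape = (layer.out_channels, shape[0], *layer.kernel)
            mu_w = rng.normal(0.0, np.sqrt(2.0 / fan_in), w_shape)
            out.append(
                VariationalLayer(
                    mu_w,
                    np.full(w_shape, rho0),
                    np.zeros(layer.out_channels),
                    np.full(layer.out_channels, rho0),
                    "conv",
                )
            )
        elif isinstance(layer, DenseSpec):
            fan_in = shape[0]
            w_shape = (fan_in, layer.out_features)
            mu_w = rng.normal(0.0, np.sqrt(2.0 / fan_in), w_shape)
            out.append(
                VariationalLayer(
                    mu_w,
                    np.full(w_shape, rho0),
                    np.zeros(layer.out_features),
                    np.full(layer.out_features, rho0),
                    "dense",
                )
            )
        shape = next_shape
    return out


def kl_gaussian(
    mu: np.ndarray,
    sigma: np.ndarray,
    prior_mu: float = 0.0,
    prior_sigma: float = 1.0,
) -> float:
    """Closed-form sum of elementwise KL(N(mu, sigma^2) || N(prior))."""
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("sigma must be positive")
    if prior_sigma <= 0:
        raise ValueError("prior_sigma must be positive")
    kl = (
        np.log(prior_sigma / sigma)
        + (sigma**2 + (mu - prior_mu) ** 2) / (2.0 * prior_sigma**2)
        - 0.5
    )
    return float(kl.sum())


def total_kl(layers: Sequence[VariationalLayer]) -> float:
    return sum(
        kl_gaussian(v.mu_w, v.sigma_w) + kl_gaussian(v.mu_b, v.sigma_b)
        for v in layers
    )


def sample_weights(
    spec: NetworkSpec,
    layers: Sequence[VariationalLayer],
    seed: int | np.random.Generator = 0,
) -> list[dict[str, np.ndarray]]:
    """Draw one weight realization w = mu + sigma * eps (eps kept for grads)."""
    _check_layer_shapes(spec, layers)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    real = []
    for v in layers:
        eps_w = rng.standard_normal(v.mu_w.shape)
        eps_b = rng.standard_normal(v.mu_b.shape)
        real.append(
            {
                "w": v.mu_w + v.sigma_w * eps_w,
                "b": v.mu_b + v.sigma_b * eps_b,
                "eps_w": eps_w,
                "eps_b": eps_b,
            }
        )
    return real


def mean_weights(
    spec: NetworkSpec, layers: Sequence[VariationalLayer]
) -> list[dict[str, np.ndarray]]:
    """The sigma -> 0 (deterministic CNN) limit: realization equals mu."""
    _check_layer_shapes(spec, layers)
    return [
        {
            "w": v.mu_w.copy(),
            "b": v.mu_b.copy(),
            "eps_w": np.zeros_like(v.mu_w),
            "eps_b": np.zeros_like(v.mu_b),
        }
        for v in layers
    ]


def _check_layer_shapes(spec: NetworkSpec, layers: Sequence[VariationalLayer]) -> None:
    trainable = [l for l in spec.layers if isinstance(l, (ConvSpec, DenseSpec))]
    if len(trainable) != len(layers):
        raise ValueError(
            f"spec has {len(trainable)} trainable layers, got {len(layers)}"
        )
    shape: tuple[int, ...] = (spec.n_channels, *spec.input_shape)
    it = iter(layers)
    for lspec, next_shape in zip(spec.layers, spec.feature_shapes()):
        if isinstance(lspec, ConvSpec):
            v = next(it)
            want = (lspec.out_channels, shape[0], *lspec.kernel)
            if v.mu_w.shape != want:
                raise ValueError(
                    f"conv layer weight shape {v.mu_w.shape} != expected {want}"
                )
        elif isinstance(lspec, DenseSpec):
            v = next(it)
            want = (shape[0], lspec.out_features)
            if v.mu_w.shape != want:
                raise ValueError(
                    f"dense layer weight shape {v.mu_w.shape} != expected {want}"
                )
        shape = next_shape


# ---------------------------------------------------------------------------
# NumPy layer primitives (batched, with caches for backprop)


def conv2d_forward(
    x: np.ndarray, w: np.ndarray, b: np.ndarray, stride: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    """Valid strided convolution: x (B,C,H,W), w (O,C,kh,kw) -> (B,O,oh,ow)."""
    kh, kw = w.shape[2:]
    sh, sw = stride
    patches = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    patches = patches[:, :, ::sh, ::sw]  # (B, C, oh, ow, kh, kw)
    y = np.einsum("bchwij,ocij->bohw", patches, w, optimize=True) + b[:, None, None]
    return y, patches


def conv2d_backward(
    dy: np.ndarray,
    patches: np.ndarray,
    w: np.ndarray,
    x_shape: tuple[int, ...],
    stride: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (dx, dw, db) for conv2d_forward."""
    kh, kw = w.shape[2:]
    sh, sw = stride
    dw = np.einsum("bchwij,bohw->ocij", patches, dy, optimize=True)
    db = dy.sum(axis=(0, 2, 3))
    dp = np.einsum("bohw,ocij->bchwij", dy, w, optimize=True)
    dx = np.zeros(x_shape)
    oh, ow = dy.shape[2], dy.shape[3]
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + oh * sh : sh, j : j + ow * sw : sw] += dp[:, :, :, :, i, j]
    return dx, dw, db


def maxpool_forward(
    x: np.ndarray, size: tuple[int, int]
) -> tuple[np.ndarray, dict]:
    ph, pw = size
    B, C, H, W = x.shape
    oh, ow = H // ph, W // pw
    xc = x[:, :, : oh * ph, : ow * pw]
    xr = xc.reshape(B, C, oh, ph, ow, pw).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(B, C, oh, ow, ph * pw)
    idx = flat.argmax(axis=-1)
    y = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    return y, {"idx": idx, "x_shape": x.shape, "size": size}


def maxpool_backward(dy: np.ndarray, cache: dict) -> np.ndarray:
    ph, pw = cache["size"]
    B, C, H, W = cache["x_shape"]
    oh, ow = H // ph, W // pw
    flat = np.zeros((B, C, oh, ow, ph * pw))
    np.put_along_axis(flat, cache["idx"][..., None], dy[..., None], axis=-1)
    xr = flat.reshape(B, C, oh, ow, ph, pw).transpose(0, 1, 2, 4, 3, 5)
    dx = np.zeros((B, C, H, W))
    dx[:, :, : oh * ph, : ow * pw] = xr.reshape(B, C, oh * ph, ow * pw)
    return dx


def _forward_batch(
    spec: NetworkSpec,
    realization: Sequence[dict[str, np.ndarray]],
    x: np.ndarray,
    with_cache: bool = False,
):
    """Batched forward pass.

    Returns (outputs, first_conv_feature_map, caches).  ReLU follows every
    conv and every dense layer except the final one; the first conv layer's
    post-activation feature map is retained for the attention probe.
    """
    caches: list[tuple] = []
    first_fm = None
    ti = 0
    n_layers = len(spec.layers)
    if spec.input_center != 0.0 or spec.input_scale != 1.0:
        x = (x - spec.input_center) / spec.input_scale
    for i, layer in enumerate(spec.layers):
        if isinstance(layer, ConvSpec):
            r = realization[ti]
            ti += 1
            y, patches = conv2d_forward(x, r["w"], r["b"], layer.stride)
            mask = y > 0
            out = np.where(mask, y, 0.0)
            if with_cache:
                caches.append(("conv", layer, r, patches, x.shape, mask))
            if first_fm is None:
                first_fm = out
            x = out
        elif isinstance(layer, PoolSpec):
            x, cache = maxpool_forward(x, layer.size)
            if with_cache:
                caches.append(("pool", cache))
        elif isinstance(layer, FlattenSpec):
            if with_cache:
                caches.append(("flatten", x.shape))
            x = x.reshape(x.shape[0], -1)
        elif isinstance(layer, DenseSpec):
            r = realization[ti]
            ti += 1
            y = x @ r["w"] + r["b"]
            last = i == n_layers - 1
            if last:
                mask = None
                out = y
            else:
                mask = y > 0
                out = np.where(mask, y, 0.0)
            if with_cache:
                caches.append(("dense", r, x, mask))
            x = out
    return x, first_fm, caches


def _backward_batch(
    spec: NetworkSpec,
    caches: list[tuple],
    d_out: np.ndarray,
) -> list[dict[str, np.ndarray]]:
    """Backprop through _forward_batch caches; returns per-layer (dw, db)."""
    grads: list[dict[str, np.ndarray]] = []
    dy = d_out
    for entry in reversed(caches):
        kind = entry[0]
        if kind == "dense":
            _, r, x_in, mask = entry
            if mask is not None:
                dy = dy * mask
            dw = x_in.T @ dy
            db = dy.sum(axis=0)
            grads.append({"dw": dw, "db": db})
            dy = dy @ r["w"].T
        elif kind == "flatten":
            _, shape = entry
            dy = dy.reshape(shape)
        elif kind == "pool":
            dy = maxpool_backward(dy, entry[1])
        elif kind == "conv":
            _, layer, r, patches, x_shape, mask = entry
            dy = dy * mask
            dy, dw, db = conv2d_backward(dy, patches, r["w"], x_shape, layer.stride)
            grads.append({"dw": dw, "db": db})
    grads.reverse()
    return grads


def forward(
    spec: NetworkSpec,
    realization: Sequence[dict[str, np.ndarray]],
    segment: STFTSegment | np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-input forward pass.

    Returns the pre-softmax output vector of the final layer and the first
    conv layer's post-activation feature map; deterministic given the
    realization.
    """
    x = np.asarray(getattr(segment, "values", segment))
    if x.shape != (spec.n_channels, *spec.input_shape):
        raise ValueError(
            f"segment shape {x.shape} does not match spec input "
            f"{(spec.n_channels, *spec.input_shape)}"
        )
    out, first_fm, _ = _forward_batch(spec, realization, x[None].astype(float))
    return out[0], (first_fm[0] if first_fm is not None else None)


def softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


# ---------------------------------------------------------------------------
# Objective


@dataclass
class TrainingObjective:
    """ELBO-derived loss decomposition: total = nll + kl_weight * kl."""

    nll: float
    kl: float
    kl_weight: float

    def __post_init__(self) -> None:
        if self.kl < -1e-9:
            raise ValueError("kl must be non-negative")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be non-negative")

    @property
    def total(self) -> float:
        return self.nll + self.kl_weight * self.kl


def elbo_loss(
    batch_outputs: np.ndarray,
    labels: np.ndarray,
    kl_total: float,
    kl_weight: float,
) -> TrainingObjective:
    """Mean categorical cross-entropy of softmax(outputs) plus weighted KL."""
    batch_outputs = np.asarray(batch_outputs, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if batch_outputs.ndim != 2 or batch_outputs.shape[1] != 2:
        raise ValueError("batch_outputs must be (B, 2)")
    if len(batch_outputs) != len(labels):
        raise ValueError("outputs and labels must have the same length")
    if len(labels) == 0:
        raise ValueError("empty batch")
    logz = batch_outputs - batch_outputs.max(axis=1, keepdims=True)
    logp = logz - np.log(np.exp(logz).sum(axis=1, keepdims=True))
    nll = float(-logp[np.arange(len(labels)), labels].mean())
    return TrainingObjective(nll, float(kl_total), float(kl_weight))


# ---------------------------------------------------------------------------
# Training


@dataclass
class TrainConfig:
    epochs: int = 10
    batch_size: int = 32
    learning_rate: float = 1e-3
    kl_weight: float | None = None  # None -> 1 / examples per epoch
    oversample: bool = True
    normalize_input: bool = True
    sigma_init: float = 0.05
    seed: int = 0


@dataclass
class PredictionSamples:
    """Monte-Carlo preictal-probability samples for one input."""

    scores: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.size < 2:
            raise ValueError("need at least 2 Monte-Carlo samples")
        if np.any((self.scores < 0) | (self.scores > 1)):
            raise ValueError("scores must lie in [0, 1]")


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.b1, self.b2, self.eps = 0.9, 0.999, 1e-8
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mh = m / (1 - self.b1**self.t)
            vh = v / (1 - self.b2**self.t)
            p -= self.lr * mh / (np.sqrt(vh) + self.eps)


def train(
    spec: NetworkSpec,
    segments: Sequence[STFTSegment],
    config: TrainConfig | None = None,
    fusion_factors: np.ndarray | None = None,
    layers: Sequence[VariationalLayer] | None = None,
) -> tuple[list[VariationalLayer], list[TrainingObjective]]:
    """Mini-batch stochastic-ELBO training of all (mu, rho) parameters.

    ``fusion_factors`` (aligned with ``segments``) multiplies each example's
    preictal pre-softmax output, applying the auxiliary-evidence modulator
    inside the training graph.  Returns the trained layers and a per-epoch
    loss trace.  Deterministic given ``config.seed``.

    The default KL weight is 1 / (examples per epoch): the cross-entropy term
    is a per-example mean, so this makes each epoch's accumulated KL pressure
    equal one full KL(q || p), the standard stochastic-VI scaling.
    """
    config = config or TrainConfig()
    y = np.array(
        [1 if s.label == "preictal" else 0 for s in segments], dtype=int
    )
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    x_all = np.stack([s.values for s in segments]).astype(float)
    factors = (
        np.ones(len(segments))
        if fusion_factors is None
        else np.asarray(fusion_factors, dtype=float)
    )
    if factors.shape != (len(segments),):
        raise ValueError("fusion_factors must align with segments")

    if config.normalize_input and layers is None:
        spec.input_center = float(x_all.mean())
        spec.input_scale = float(max(x_all.std(), 1e-12))

    rng = np.random.default_rng(config.seed)
    layer_list = (
        list(layers)
        if layers is not None
        else init_layers(spec, seed=config.seed, sigma_init=config.sigma_init)
    )
    params: list[np.ndarray] = []
    for v in layer_list:
        params.extend(v.params())
    opt = _Adam(params, config.learning_rate)

    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    trace: list[TrainingObjective] = []
    for _epoch in range(config.epochs):
        if config.oversample:
            n = max(len(idx_pos), len(idx_neg))
            minority, majority = (
                (idx_pos, idx_neg) if len(idx_pos) < len(idx_neg) else (idx_neg, idx_pos)
            )
            epoch_idx = np.concatenate(
                [majority, rng.choice(minority, size=n, replace=True)]
            )
        else:
            epoch_idx = np.arange(len(y))
        rng.shuffle(epoch_idx)
        n_batches = max(1, len(epoch_idx) // config.batch_size)
        kl_w = (
            config.kl_weight
            if config.kl_weight is not None
            else 1.0 / (n_batches * config.batch_size)
        )

        epoch_nll = 0.0
        kl_val = 0.0
        for b in range(n_batches):
            bidx = epoch_idx[b * config.batch_size : (b + 1) * config.batch_size]
            xb, yb, fb = x_all[bidx], y[bidx], factors[bidx]
            real = sample_weights(spec, layer_list, rng)
            logits, _, caches = _forward_batch(spec, real, xb, with_cache=True)
            logits_mod = logits.copy()
            logits_mod[:, 1] *= fb
            probs = softmax(logits_mod)
            kl_val = total_kl(layer_list)
            obj = elbo_loss(logits_mod, yb, kl_val, kl_w)
            if not np.isfinite(obj.total):
                raise RuntimeError(
                    f"training diverged: non-finite loss {obj.total} at epoch "
                    f"{_epoch}, batch {b}; lower the learning rate"
                )
            epoch_nll += obj.nll

            dlogits = probs.copy()
            dlogits[np.arange(len(yb)), yb] -= 1.0
            dlogits /= len(yb)
            dlogits[:, 1] *= fb  # chain through the modulation
            grads = _backward_batch(spec, caches, dlogits)

            flat_grads: list[np.ndarray] = []
            for v, r, g in zip(layer_list, real, grads):
                sig_w, sig_b = _sigmoid(v.rho_w), _sigmoid(v.rho_b)
                sigma_w, sigma_b = v.sigma_w, v.sigma_b
                g_mu_w = g["dw"] + kl_w * v.mu_w
                g_rho_w = (
                    g["dw"] * r["eps_w"] + kl_w * (sigma_w - 1.0 / sigma_w)
                ) * sig_w
                g_mu_b = g["db"] + kl_w * v.mu_b
                g_rho_b = (
                    g["db"] * r["eps_b"] + kl_w * (sigma_b - 1.0 / sigma_b)
                ) * sig_b
                flat_grads.extend([g_mu_w, g_rho_w, g_mu_b, g_rho_b])
            opt.step(params, flat_grads)
        trace.append(
            TrainingObjective(epoch_nll / n_batches, kl_val, kl_w)
        )
    return layer_list, trace


def mc_predict(
    spec: NetworkSpec,
    layers: Sequence[VariationalLayer],
    segment: STFTSegment | np.ndarray,
    S: int = 500,
    seed: int = 0,
    fusion_factor: float = 1.0,
) -> PredictionSamples:
    """S Monte-Carlo forward passes -> S softmax preictal probabilities."""
    if S < 2:
        raise ValueError("S must be >= 2")
    if not np.isfinite(fusion_factor):
        raise ValueError("fusion_factor must be finite")
    x = np.asarray(getattr(segment, "values", segment))
    rng = np.random.default_rng(seed)
    scores = np.empty(S)
    for s in range(S):
        real = sample_weights(spec, layers, rng)
        logits, _ = forward(spec, real, x)
        logits = logits.copy()
        logits[1] *= fusion_factor
        scores[s] = softmax(logits)[1]
    return PredictionSamples(scores)


def mc_predict_batch(
    spec: NetworkSpec,
    layers: Sequence[VariationalLayer],
    segments: Sequence[STFTSegment],
    S: int = 500,
    seed: int = 0,
    fusion_factors: np.ndarray | None = None,
) -> list[PredictionSamples]:
    """Vectorized Monte-Carlo prediction sharing weight draws across a batch."""
    if S < 2:
        raise ValueError("S must be >= 2")
    x = np.stack([s.values for s in segments]).astype(float)
    factors = (
        np.ones(len(segments))
        if fusion_factors is None
        else np.asarray(fusion_factors, dtype=float)
    )
    rng = np.random.default_rng(seed)
    all_scores = np.empty((len(segments), S))
    for s in range(S):
        real = sample_weights(spec, layers, rng)
        logits, _, _ = _forward_batch(spec, real, x)
        logits = logits.copy()
        logits[:, 1] *= factors
        all_scores[:, s] = softmax(logits)[:, 1]
    return [PredictionSamples(row) for row in all_scores]


# ---------------------------------------------------------------------------
# Checkpoints


def _spec_to_dict(spec: NetworkSpec) -> dict:
    return {
        "n_channels": spec.n_channels,
        "input_shape": list(spec.input_shape),
        "layers": [asdict(l) for l in spec.layers],
        "input_center": spec.input_center,
        "input_scale": spec.input_scale,
    }


def _spec_from_dict(d: dict) -> NetworkSpec:
    kinds = {"conv": ConvSpec, "pool": PoolSpec, "flatten": FlattenSpec, "dense": DenseSpec}
    layers = []
    for ld in d["layers"]:
        ld = dict(ld)
        cls = kinds[ld.pop("kind")]
        for key in ("kernel", "stride", "size"):
            if key in ld:
                ld[key] = tuple(ld[key])
        layers.append(cls(**ld))
    return NetworkSpec(
        d["n_channels"],
        layers,
        tuple(d["input_shape"]),
        d.get("input_center", 0.0),
        d.get("input_scale", 1.0),
    )


def save_checkpoint(
    path: str | Path, spec: NetworkSpec, layers: Sequence[VariationalLayer]
) -> Path:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["spec"] = json.dumps(_spec_to_dict(spec))
        for i, v in enumerate(layers):
            g = f.create_group(f"layer{i}")
            g.attrs["kind"] = v.layer_kind
            g.create_dataset("mu_w", data=v.mu_w)
            g.create_dataset("rho_w", data=v.rho_w)
            g.create_dataset("mu_b", data=v.mu_b)
            g.create_dataset("rho_b", data=v.rho_b)
    return Path(path)


def load_checkpoint(path: str | Path) -> tuple[NetworkSpec, list[VariationalLayer]]:
    import h5py

    with h5py.File(path, "r") as f:
        spec = _spec_from_dict(json.loads(f.attrs["spec"]))
        layers = []
        for i in range(len([k for k in f.keys() if k.startswith("layer")])):
            g = f[f"layer{i}"]
            layers.append(
                VariationalLayer(
                    g["mu_w"][:], g["rho_w"][:], g["mu_b"][:], g["rho_b"][:],
                    g.attrs["kind"],
                )
            )
    return spec, layers
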