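"""The two-stream residual network with efficient channel attention.

Each modality (12-channel EMG window, 36-channel accelerometer window) is
presented to its own residual branch as a single-plane image of shape
(signal channels x time samples), so convolutions run both along time and
across electrode channels.  Each branch ends in global average pooling;
the pooled length-C vector is re-weighted by efficient channel attention
(ECA) — a shared 1-D convolution of adaptive odd length k across the
channel axis followed by a sigmoid — and the two attended vectors are
concatenated and classified by a small fully connected head with dropout
and a softmax.

Two branch presets are provided: ``"full"`` follows the ResNet-18 layout
(four stages of two residual blocks, widths 64/128/256/512), with the stem
adapted to signal-shaped inputs (stride and pooling along the time axis
only, so the 12-row electrode axis is not collapsed); ``"small"`` is a
two-stage desk-scale variant (widths 16/32) for CPU experiments and tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from emgfuse import nn


# --------------------------------------------------------------------------
# ECA
# --------------------------------------------------------------------------

def eca_kernel_size(C: int, gamma: int = 2, lam: int = 1) -> int:
    """Adaptive ECA kernel length: nearest odd integer to log2(C)/γ + λ/γ.

    Ties between equidistant odd integers resolve downward; the result is
    clamped to at least 1.  With the default γ=2, λ=1: C=512 -> 5,
    C=64 -> 3 (3.5 ties down), C=1 -> 1.
    """
    if C < 1:
        raise ValueError("C must be >= 1")
    t = math.log2(C) / gamma + lam / gamma
    lower = 2 * math.floor((t - 1) / 2) + 1  # largest odd <= t
    upper = lower + 2
    k = lower if (t - lower) <= (upper - t) else upper
    return max(1, k)


@dataclass(frozen=True)
class EcaSpec:
    """ECA hyperparameters and the shared 1-D kernel (stride fixed at 1)."""

    k: int
    conv_weights: np.ndarray
    gamma: int = 2
    lam: int = 1

    def __post_init__(self) -> None:
        w = np.asarray(self.conv_weights, dtype=float).ravel()
        object.__setattr__(self, "conv_weights", w)
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be odd and >= 1")
        if w.shape[0] != self.k:
            raise ValueError(f"conv_weights must have length k={self.k}, got {w.shape[0]}")


def eca_spec(C: int, gamma: int = 2, lam: int = 1,
             conv_weights: np.ndarray | None = None, seed: int = 0) -> EcaSpec:
    """Build an :class:`EcaSpec` whose kernel length matches C channels."""
    k = eca_kernel_size(C, gamma, lam)
    if conv_weights is None:
        rng = np.random.default_rng(seed)
        conv_weights = rng.normal(0.0, 1.0 / np.sqrt(k), size=k)
    return EcaSpec(k=k, conv_weights=conv_weights, gamma=gamma, lam=lam)


def global_average_pool(fm: np.ndarray) -> np.ndarray:
    """Channel-wise mean of a (W, H, C) feature map -> length-C vector."""
    fm = np.asarray(fm, dtype=float)
    if fm.ndim != 3:
        raise ValueError(f"feature map must be (W, H, C), got shape {fm.shape}")
    if fm.shape[0] * fm.shape[1] < 1:
        raise ValueError("feature map must have non-empty spatial extent")
    return fm.mean(axis=(0, 1))


def eca_attend(pooled: np.ndarray, spec: EcaSpec) -> tuple[np.ndarray, np.ndarray]:
    """Attention weights and attended vector for a pooled channel vector.

    weights = sigmoid(1-D convolution of the pooled vector, kernel length
    k, stride 1, symmetric zero padding); attended = weights * pooled.
    Accepts a single length-C vector or an (N, C) batch.
    """
    pooled = np.asarray(pooled, dtype=float)
    single = pooled.ndim == 1
    p2 = np.atleast_2d(pooled)
    conv = nn.EcaConv1d(spec.k, weights=spec.conv_weights)
    attended = conv.forward(p2)
    weights = conv.attention_weights(p2)
    if single:
        return weights[0], attended[0]
    return weights, attended


# --------------------------------------------------------------------------
# Residual blocks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidualBlockSpec:
    """Two 3x3 conv/batch-norm/ReLU stages plus an additive shortcut.

    The shortcut is the identity when shapes are preserved, otherwise a
    strided 1x1 projection; ``projection`` is derived, not chosen.
    """

    in_channels: int
    out_channels: int
    stride: int = 1

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")
        if min(self.in_channels, self.out_channels) < 1:
            raise ValueError("channel counts must be >= 1")

    @property
    def projection(self) -> bool:
        return self.stride != 1 or self.in_channels != self.out_channels


def init_residual_params(spec: ResidualBlockSpec, seed: int = 0) -> dict[str, np.ndarray]:
    """Random conv kernels + identity batch-norm for a functional block pass.

    Kernels are 4-D (out, in, kh, kw); batch-norm entries default to the
    identity transform (gamma 1, beta 0, running mean 0, running var 1).
    """
    rng = np.random.default_rng(seed)
    ci, co = spec.in_channels, spec.out_channels
    params = {
        "conv1_w": rng.normal(0, np.sqrt(2.0 / (ci * 9)), size=(co, ci, 3, 3)),
        "conv2_w": rng.normal(0, np.sqrt(2.0 / (co * 9)), size=(co, co, 3, 3)),
    }
    if spec.projection:
        params["proj_w"] = rng.normal(0, np.sqrt(2.0 / ci), size=(co, ci, 1, 1))
    return params


def _make_block(spec: ResidualBlockSpec, params: dict[str, np.ndarray]) -> nn.ResidualBlock:
    block = nn.ResidualBlock(spec.in_channels, spec.out_channels, spec.stride)
    block.conv1.params["w"][...] = params["conv1_w"].reshape(spec.out_channels, -1)
    block.conv2.params["w"][...] = params["conv2_w"].reshape(spec.out_channels, -1)
    if spec.projection:
        block.proj.params["w"][...] = params["proj_w"].reshape(spec.out_channels, -1)
    for bn_name, bn in (("bn1", block.bn1), ("bn2", block.bn2)) + (
        (("proj_bn", block.proj_bn),) if spec.projection else ()
    ):
        for part, target in (("gamma", "gamma"), ("beta", "beta")):
            key = f"{bn_name}_{part}"
            if key in params:
                bn.params[target][...] = params[key]
        for part, target in (("mean", "running_mean"), ("var", "running_var")):
            key = f"{bn_name}_{part}"
            if key in params:
                bn.buffers[target][...] = params[key]
    return block


def residual_block_forward(
    x: np.ndarray, spec: ResidualBlockSpec, params: dict[str, np.ndarray]
) -> np.ndarray:
    """Functional inference-mode pass of one residual block.

    ``x`` is (N, H, W, C_in) or (H, W, C_in); batch norm runs with the
    running statistics in ``params`` (identity by default), so with all
    residual-path weights at zero and no projection the block reduces to
    ReLU(x) — the identity on nonnegative inputs.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 3
    x4 = x[None] if single else x
    if x4.ndim != 4 or x4.shape[3] != spec.in_channels:
        raise ValueError(
            f"input must be (N, H, W, {spec.in_channels}), got shape {x.shape}"
        )
    block = _make_block(spec, params)
    y = block.forward(x4.transpose(0, 3, 1, 2), train=False)
    y = y.transpose(0, 2, 3, 1)
    return y[0] if single else y


# --------------------------------------------------------------------------
# Branches
# --------------------------------------------------------------------------

_PRESETS = {
    "full": dict(stage_widths=(64, 128, 256, 512), blocks_per_stage=(2, 2, 2, 2),
                 stem_kernel=7, stem_pool=True),
    "small": dict(stage_widths=(16, 32), blocks_per_stage=(2, 2),
                  stem_kernel=3, stem_pool=False),
}


@dataclass(frozen=True)
class BranchSpec:
    """One modality branch: stem, residual stages, global average pooling.

    ``input_shape`` is (signal channels, window length L) — (12, L) for
    EMG, (36, L) for ACC; the output vector length equals the last stage
    width.  An input height of at least 64 (e.g. a square image probe) is
    treated in image mode with the classic stride-2 stem; signal-shaped
    inputs stride and pool along the time axis only.
    """

    input_shape: tuple[int, int]
    preset: str = "full"
    stage_widths: tuple[int, ...] = (64, 128, 256, 512)
    blocks_per_stage: tuple[int, ...] = (2, 2, 2, 2)
    stem_kernel: int = 7
    stem_pool: bool = True

    def __post_init__(self) -> None:
        if len(self.stage_widths) != len(self.blocks_per_stage):
            raise ValueError("stage_widths and blocks_per_stage must align")
        if any(b < 1 for b in self.blocks_per_stage):
            raise ValueError("every stage needs at least one block")
        h, w = self.input_shape
        if h < 1 or w < self.stem_kernel:
            raise ValueError(
                f"input shape {self.input_shape} is thinner than the stem's "
                f"receptive field ({self.stem_kernel}); use a longer window "
                "or the 'small' preset"
            )

    @property
    def output_length(self) -> int:
        return self.stage_widths[-1]


def branch_spec(preset: str, input_shape: tuple[int, int]) -> BranchSpec:
    """Preset branch layout ('full' = ResNet-18-style, 'small' = 16/32)."""
    if preset not in _PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
    return BranchSpec(input_shape=tuple(input_shape), preset=preset, **_PRESETS[preset])


class Branch(nn.Module):
    """Stem -> residual stages -> global average pooling."""

    def __init__(self, spec: BranchSpec, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.spec = spec
        h, w = spec.input_shape
        image_mode = h >= 64
        w0 = spec.stage_widths[0]

        stem_stride = (2, 2) if image_mode else (1, 2)
        layers: list[tuple[str, nn.Module]] = [
            ("stem_conv", nn.Conv2d(1, w0, spec.stem_kernel, stem_stride, rng, bias=False)),
            ("stem_bn", nn.BatchNorm2d(w0)),
            ("stem_relu", nn.ReLU()),
        ]
        h = -(-h // stem_stride[0])
        w = -(-w // stem_stride[1])
        if spec.stem_pool:
            pool_k = (3, 3) if image_mode else (1, 3)
            pool_s = (2, 2) if image_mode else (1, 2)
            layers.append(("stem_pool", nn.MaxPool2d(pool_k, pool_s)))
            h = -(-h // pool_s[0])
            w = -(-w // pool_s[1])
        self.stem = nn.Sequential(layers)

        self.stages: list[nn.Sequential] = []
        in_ch = w0
        for si, (width, n_blocks) in enumerate(zip(spec.stage_widths, spec.blocks_per_stage)):
            blocks = []
            for bi in range(n_blocks):
                if bi == 0 and si > 0:
                    sh = 2 if (image_mode or h >= 4) else 1
                    stride = (sh, 2 if w >= 4 else 1)
                else:
                    stride = (1, 1)
                blocks.append((f"block{bi}", nn.ResidualBlock(in_ch, width, stride, rng)))
                h = -(-h // stride[0])
                w = -(-w // stride[1])
                in_ch = width
            self.stages.append(nn.Sequential(blocks))
        self.gap = nn.GlobalAvgPool()
        self.stage_output_sizes: list[tuple[int, int]] = []

    def children(self):
        return [("stem", self.stem)] + [
            (f"stage{i}", s) for i, s in enumerate(self.stages)
        ] + [("gap", self.gap)]

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        """(N, 1, signal_channels, L) -> (N, C) pooled features."""
        x = self.stem.forward(x, train)
        self.stage_output_sizes = []
        for stage in self.stages:
            x = stage.forward(x, train)
            self.stage_output_sizes.append(x.shape[2:])
        return self.gap.forward(x, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.gap.backward(dy)
        for stage in reversed(self.stages):
            dy = stage.backward(dy)
        return self.stem.backward(dy)

    @property
    def output_length(self) -> int:
        return self.spec.output_length


def build_branch(spec: BranchSpec, seed: int = 0) -> Branch:
    """Instantiate one branch with seeded He initialization."""
    return Branch(spec, np.random.default_rng([seed % (2**31), 0xB4A]))


# --------------------------------------------------------------------------
# Two-stream model
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TwoStreamSpec:
    """Full architecture: two branches, per-branch ECA, fusion, head.

    Fusion is concatenation of the two attended pooled vectors, followed
    by one fully connected hidden layer with dropout between the fully
    connected layers and a softmax output of ``n_classes``.
    ``use_attention=False`` fuses the raw pooled vectors (the
    no-attention ablation).
    """

    emg_branch: BranchSpec
    acc_branch: BranchSpec
    n_classes: int
    eca_gamma: int = 2
    eca_lam: int = 1
    use_attention: bool = True
    dropout_rate: float = 0.5
    hidden_units: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @property
    def fused_length(self) -> int:
        return self.emg_branch.output_length + self.acc_branch.output_length

    @property
    def resolved_hidden_units(self) -> int:
        if self.hidden_units is not None:
            return self.hidden_units
        return max(64, self.fused_length // 4)


def two_stream_spec(
    window_length: int,
    n_classes: int,
    preset: str = "full",
    use_attention: bool = True,
    dropout_rate: float = 0.5,
    seed: int = 0,
    hidden_units: int | None = None,
) -> TwoStreamSpec:
    """Convenience constructor for paired (12, L) EMG / (36, L) ACC branches."""
    return TwoStreamSpec(
        emg_branch=branch_spec(preset, (12, window_length)),
        acc_branch=branch_spec(preset, (36, window_length)),
        n_classes=n_classes,
        use_attention=use_attention,
        dropout_rate=dropout_rate,
        seed=seed,
        hidden_units=hidden_units,
    )


class _Head(nn.Module):
    """Fused vector -> hidden dense + ReLU + dropout -> class logits."""

    def __init__(self, n_in, hidden, n_classes, dropout_rate, rng):
        super().__init__()
        self.fc1 = nn.Dense(n_in, hidden, rng)
        self.relu = nn.ReLU()
        self.drop = nn.Dropout(dropout_rate, rng)
        self.fc2 = nn.Dense(hidden, n_classes, rng)

    def children(self):
        return [("fc1", self.fc1), ("relu", self.relu), ("drop", self.drop), ("fc2", self.fc2)]

    def forward(self, x, train=False):
        h = self.drop.forward(self.relu.forward(self.fc1.forward(x, train), train), train)
        return self.fc2.forward(h, train)

    def backward(self, dy):
        return self.fc1.backward(self.relu.backward(self.drop.backward(self.fc2.backward(dy))))


class TwoStream(nn.Module):
    """The trainable two-stream classifier."""

    def __init__(self, spec: TwoStreamSpec):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng([spec.seed % (2**31), 0x75])
        self.emg_branch = Branch(spec.emg_branch, rng)
        self.acc_branch = Branch(spec.acc_branch, rng)
        if spec.use_attention:
            ke = eca_kernel_size(spec.emg_branch.output_length, spec.eca_gamma, spec.eca_lam)
            ka = eca_kernel_size(spec.acc_branch.output_length, spec.eca_gamma, spec.eca_lam)
            self.eca_emg = nn.EcaConv1d(ke, rng)
            self.eca_acc = nn.EcaConv1d(ka, rng)
        self.head = _Head(
            spec.fused_length, spec.resolved_hidden_units, spec.n_classes,
            spec.dropout_rate, rng,
        )
        self.loss_fn = nn.SoftmaxCrossEntropy()
        self.to_dtype(np.float32)  # single precision is ample for training

    def children(self):
        out = [("emg_branch", self.emg_branch), ("acc_branch", self.acc_branch)]
        if self.spec.use_attention:
            out += [("eca_emg", self.eca_emg), ("eca_acc", self.eca_acc)]
        return out + [("head", self.head)]

    @staticmethod
    def _as_plane(x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if x.ndim == 2:
            x = x[None]
        return x[:, None, :, :]  # (N, 1, signal_channels, L)

    def forward_logits(self, emg: np.ndarray, acc: np.ndarray, train: bool = False) -> np.ndarray:
        emg, acc = self._as_plane(emg), self._as_plane(acc)
        if emg.shape[0] != acc.shape[0]:
            raise ValueError(
                f"EMG batch of {emg.shape[0]} windows paired with ACC batch of "
                f"{acc.shape[0]}"
            )
        ve = self.emg_branch.forward(emg, train)
        va = self.acc_branch.forward(acc, train)
        if self.spec.use_attention:
            ve = self.eca_emg.forward(ve, train)
            va = self.eca_acc.forward(va, train)
        self._ne = ve.shape[1]
        return self.head.forward(np.concatenate([ve, va], axis=1), train)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        dfused = self.head.backward(dlogits)
        dve, dva = dfused[:, : self._ne], dfused[:, self._ne :]
        if self.spec.use_attention:
            dve = self.eca_emg.backward(dve)
            dva = self.eca_acc.backward(dva)
        self.emg_branch.backward(dve)
        self.acc_branch.backward(dva)

    def predict_proba(self, emg: np.ndarray, acc: np.ndarray, batch_size: int = 32) -> np.ndarray:
        emg3 = np.asarray(emg, dtype=float)
        single = emg3.ndim == 2
        emg3 = emg3[None] if single else emg3
        acc3 = np.asarray(acc, dtype=float)
        acc3 = acc3[None] if acc3.ndim == 2 else acc3
        outs = []
        for i in range(0, emg3.shape[0], batch_size):
            logits = self.forward_logits(emg3[i : i + batch_size], acc3[i : i + batch_size])
            outs.append(self.loss_fn.probs(logits))
        p = np.concatenate(outs)
        return p[0] if single else p

    def predict(self, emg: np.ndarray, acc: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(emg, acc, batch_size).argmax(axis=-1)


class SingleStream(nn.Module):
    """One branch + ECA + head, for the single-modality ablations."""

    def __init__(self, spec: BranchSpec, n_classes: int, use_attention: bool = True,
                 dropout_rate: float = 0.5, seed: int = 0, hidden_units: int | None = None):
        super().__init__()
        rng = np.random.default_rng([seed % (2**31), 0x51])
        self.branch = Branch(spec, rng)
        self.use_attention = use_attention
        if use_attention:
            self.eca = nn.EcaConv1d(eca_kernel_size(spec.output_length), rng)
        hidden = hidden_units if hidden_units is not None else max(64, spec.output_length // 4)
        self.head = _Head(spec.output_length, hidden, n_classes, dropout_rate, rng)
        self.loss_fn = nn.SoftmaxCrossEntropy()
        self.n_classes = n_classes
        self.to_dtype(np.float32)

    def children(self):
        out = [("branch", self.branch)]
        if self.use_attention:
            out.append(("eca", self.eca))
        return out + [("head", self.head)]

    def forward_logits(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        v = self.branch.forward(TwoStream._as_plane(x), train)
        if self.use_attention:
            v = self.eca.forward(v, train)
        return self.head.forward(v, train)

    def backward_from_logits(self, dlogits: np.ndarray) -> None:
        dv = self.head.backward(dlogits)
        if self.use_attention:
            dv = self.eca.backward(dv)
        self.branch.backward(dv)

    def predict_proba(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        x3 = np.asarray(x, dtype=float)
        x3 = x3[None] if x3.ndim == 2 else x3
        outs = []
        for i in range(0, x3.shape[0], batch_size):
            outs.append(self.loss_fn.probs(self.forward_logits(x3[i : i + batch_size])))
        return np.concatenate(outs)

    def predict(self, x: np.ndarray, batch_size: int = 32) -> np.ndarray:
        return self.predict_proba(x, batch_size).argmax(axis=-1)


def build_two_stream(spec: TwoStreamSpec) -> TwoStream:
    """Instantiate the two-stream classifier from its spec."""
    return TwoStream(spec)


def forward(model: TwoStream, emg_window: np.ndarray, acc_window: np.ndarray) -> np.ndarray:
    """Class-probability vector(s) for one window pair or an aligned batch."""
    return model.predict_proba(emg_window, acc_window)
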