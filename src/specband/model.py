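"""Band-attention classifier: spectral channel attention in front of an
18-layer residual CNN ending in a sigmoid probability.

The attention block computes two per-channel spatial statistics of the input
sample h ∈ R^{C×H×W} — the global average z_avg and the global maximum z_max —
passes each through one *shared* two-layer bottleneck MLP (C → ⌊C/2⌋ → C, ReLU
then sigmoid), and sums the two sigmoid outputs into the spectral attention
map m = s_max + s_avg ∈ (0, 2)^C. The rescaled sample h_l = m ⊗ h (channel-wise
multiplication) is fed to the backbone. Because each branch is squashed before
the summation, zero-initialised attention parameters give s ≡ 0.5 and m ≡ 1,
i.e. the attention block starts as an exact identity.

The backbone is the standard 18-layer residual design: a 7×7 stride-2 stem,
3×3 max pooling, four stages of two basic blocks (3×3 convolutions, batch
normalisation, ReLU, identity shortcuts; 1×1 projection when the width or
resolution changes), global average pooling and a single-logit head.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field

import numpy as np

from .nn import (BatchNorm2d, Conv2d, Linear, Module, Tensor, maxpool2d,
                 mean_spatial, relu, sigmoid)
from .nn.autograd import add, amax_spatial, mul, reshape

#: Stage widths of the full-size backbone and the small preset used for
#: desk-scale experiments and tests.
DEFAULT_WIDTHS = (64, 128, 256, 512)
TINY_WIDTHS = (8, 16, 32, 64)

#: Spatial input size expected by the network (samples are cropped 64 -> 50).
INPUT_SIZE = 50


def bottleneck_width(n_channels: int) -> int:
    """Hidden width of the shared attention MLP: half the channel count
    (floor for odd C); 428 channels give 214."""
    return n_channels // 2


@dataclass
class AttentionParams:
    """Weights of the shared two-layer attention MLP (both branches use the
    same parameters). ``w1``: (C/2, C); ``w2``: (C, C/2); biases included."""

    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray

    @classmethod
    def zeros(cls, n_channels: int) -> "AttentionParams":
        h = bottleneck_width(n_channels)
        return cls(np.zeros((h, n_channels), np.float32), np.zeros(h, np.float32),
                   np.zeros((n_channels, h), np.float32),
                   np.zeros(n_channels, np.float32))

    @property
    def n_channels(self) -> int:
        return self.w1.shape[1]


@dataclass
class AttentionMaps:
    """All intermediate attention quantities for one sample."""

    z_avg: np.ndarray
    z_max: np.ndarray
    s_avg: np.ndarray
    s_max: np.ndarray
    m: np.ndarray
    h_l: np.ndarray


def _as_chw(h: np.ndarray) -> np.ndarray:
    h = np.asarray(h)
    if h.ndim != 3:
        raise ValueError(f"sample must be rank-3 (C,H,W), got shape {h.shape}")
    if h.shape[1] < 1 or h.shape[2] < 1:
        raise ValueError("sample has empty spatial extent")
    return h


def spectral_pool_avg(h: np.ndarray) -> np.ndarray:
    """Global average pooling over the spatial plane: z_avg[c] = mean_ij h[c,i,j]."""
    return _as_chw(h).mean(axis=(1, 2))


def spectral_pool_max(h: np.ndarray) -> np.ndarray:
    """Global maximum pooling over the spatial plane."""
    return _as_chw(h).max(axis=(1, 2))


def shared_mlp(z: np.ndarray, params: AttentionParams) -> np.ndarray:
    """s = sigmoid(w2 · relu(w1 · z)); output strictly inside (0, 1)."""
    z = np.asarray(z, dtype=np.float64).ravel()
    if z.shape[0] != params.n_channels:
        raise ValueError(f"z has length {z.shape[0]}, expected {params.n_channels}")
    hidden = np.maximum(params.w1 @ z + params.b1, 0.0)
    logits = params.w2 @ hidden + params.b2
    return 1.0 / (1.0 + np.exp(-logits))


def attention_forward(h: np.ndarray, params: AttentionParams) -> AttentionMaps:
    """Compute all attention maps and the rescaled sample for one sample."""
    h = _as_chw(h)
    z_avg = spectral_pool_avg(h)
    z_max = spectral_pool_max(h)
    s_avg = shared_mlp(z_avg, params)
    s_max = shared_mlp(z_max, params)
    m = s_max + s_avg
    h_l = (m[:, None, None] * h).astype(h.dtype)
    return AttentionMaps(z_avg, z_max, s_avg, s_max, m, h_l)


class BandAttention(Module):
    """Trainable channel-attention block operating on (N, C, H, W) batches."""

    def __init__(self, n_channels: int, rng: np.random.Generator | None = None):
        self.n_channels = n_channels
        self.fc1 = Linear(n_channels, bottleneck_width(n_channels), rng=rng)
        self.fc2 = Linear(bottleneck_width(n_channels), n_channels, rng=rng)
        # gating starts as an exact identity (s = 0.5, m = 1): the second FC
        # layer is zero-initialised, so the band ranking that develops during
        # training reflects learned structure, not initialisation noise
        self.fc2.weight.data[...] = 0.0
        self.fc2.bias.data[...] = 0.0

    def _branch(self, z: Tensor) -> Tensor:
        return sigmoid(self.fc2(relu(self.fc1(z))))

    def __call__(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Return the rescaled batch and the s_avg branch output (N, C)."""
        s_avg = self._branch(mean_spatial(x))
        s_max = self._branch(amax_spatial(x))
        m = add(s_max, s_avg)
        n, c = m.shape
        h_l = mul(reshape(m, (n, c, 1, 1)), x)
        return h_l, s_avg

    def export_params(self) -> AttentionParams:
        return AttentionParams(self.fc1.weight.data.copy(), self.fc1.bias.data.copy(),
                               self.fc2.weight.data.copy(), self.fc2.bias.data.copy())


class BasicBlock(Module):
    """Two 3×3 conv/BN/ReLU layers with an identity (or 1×1 projection)
    shortcut: out = relu(f(x) + shortcut(x))."""

    def __init__(self, c_in: int, c_out: int, stride: int,
                 rng: np.random.Generator):
        self.conv1 = Conv2d(c_in, c_out, 3, stride=stride, pad=1, rng=rng)
        self.bn1 = BatchNorm2d(c_out)
        self.conv2 = Conv2d(c_out, c_out, 3, stride=1, pad=1, rng=rng)
        self.bn2 = BatchNorm2d(c_out)
        if stride != 1 or c_in != c_out:
            self.proj = Conv2d(c_in, c_out, 1, stride=stride, pad=0, rng=rng)
            self.proj_bn = BatchNorm2d(c_out)
        else:
            self.proj = None
            self.proj_bn = None

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        out = relu(self.bn1(self.conv1(x), train))
        out = self.bn2(self.conv2(out), train)
        short = x if self.proj is None else self.proj_bn(self.proj(x), train)
        return relu(add(out, short))


@dataclass
class BackboneConfig:
    """Layout of the 18-layer residual backbone (widths scalable for tests)."""

    n_input_channels: int
    widths: tuple = DEFAULT_WIDTHS
    blocks_per_stage: tuple = (2, 2, 2, 2)
    input_size: int = INPUT_SIZE

    def __post_init__(self) -> None:
        if len(self.widths) != 4 or tuple(self.blocks_per_stage) != (2, 2, 2, 2):
            raise ValueError("backbone must keep the 18-layer layout: "
                             "4 stages of 2 basic blocks")


class ResNet18(Module):
    """18-layer residual backbone: 7×7 stem + 4×2 basic blocks + FC head."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator):
        w = cfg.widths
        self.cfg = cfg
        self.conv1 = Conv2d(cfg.n_input_channels, w[0], 7, stride=2, pad=3, rng=rng)
        self.bn1 = BatchNorm2d(w[0])
        stages = []
        c_in = w[0]
        for i, width in enumerate(w):
            stride = 1 if i == 0 else 2
            stages.append([BasicBlock(c_in, width, stride, rng),
                           BasicBlock(width, width, 1, rng)])
            c_in = width
        self.stages = [b for stage in stages for b in stage]
        self.fc = Linear(w[-1], 1, rng=rng)

    def __call__(self, x: Tensor, train: bool) -> Tensor:
        out = relu(self.bn1(self.conv1(x), train))
        out = maxpool2d(out, k=3, stride=2, pad=1)
        for block in self.stages:
            out = block(out, train)
        out = mean_spatial(out)
        return sigmoid(self.fc(out))


class WaterDeficitClassifier(Module):
    """End-to-end model: band attention, channel rescaling, residual backbone,
    sigmoid probability of the water-deficient class."""

    def __init__(self, n_channels: int, widths: tuple = DEFAULT_WIDTHS,
                 seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence(seed))
        self.n_channels = n_channels
        self.widths = tuple(widths)
        self.attention = BandAttention(n_channels, rng=rng)
        self.backbone = ResNet18(BackboneConfig(n_channels, tuple(widths)), rng)

    def __call__(self, x, train: bool = False,
                 return_attention: bool = False):
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.data.ndim != 4:
            raise ValueError(f"expected batch (N,C,H,W), got shape {x.shape}")
        n, c, h, w = x.shape
        exp = (self.n_channels, self.backbone.cfg.input_size,
               self.backbone.cfg.input_size)
        if (c, h, w) != exp:
            raise ValueError(f"expected samples of shape {exp}, got {(c, h, w)}")
        h_l, s_avg = self.attention(x)
        p = self.backbone(h_l, train)
        if return_attention:
            return p, s_avg
        return p

    def predict_proba(self, batch: np.ndarray) -> np.ndarray:
        """Inference-mode probabilities for a (N, C, 50, 50) array."""
        return self(batch, train=False).data.ravel()


def model_forward(h: np.ndarray, model: WaterDeficitClassifier) -> float:
    """Probability of water deficiency for a single C×50×50 sample
    (inference mode, deterministic)."""
    h = _as_chw(h)
    return float(model.predict_proba(h[None])[0])


def classify(p: float, threshold: float = 0.5) -> int:
    """Binarise a probability: 1 (water-deficient) iff p >= threshold."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability outside [0, 1]: {p}")
    return int(p >= threshold)


def save_checkpoint(model: WaterDeficitClassifier, path: str | os.PathLike) -> None:
    """Single-file archive of all parameters plus the architecture config."""
    meta = {"n_channels": model.n_channels, "widths": list(model.widths)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path: str | os.PathLike) -> WaterDeficitClassifier:
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    model = WaterDeficitClassifier(meta["n_channels"], tuple(meta["widths"]))
    model.load_state_dict(state)
    return model
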