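"""Modality-specific encoders.

* CTG branch: per-channel instance normalization, overlapping patch
  embedding with a learnable positional embedding, a Transformer encoder
  shared across channels (channel-independent processing), mean pooling
  over patches, and FHR‖UC concatenation.
* Image branch: residual-network encoder over the GADF image (classification
  layer removed), with full or partial (two deepest stages) fine-tuning.
* Metadata branch: training-split standardization plus a small autoencoder
  whose latent vector feeds fusion and whose reconstruction regularizes
  training.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from . import nn
from .gadf import GADFImage
from .records import CTGRecord, MaternalMetadata

__all__ = [
    "CTGEncoderConfig", "ImageEncoderConfig", "MetadataEncoderConfig",
    "MetadataStats", "instance_normalize", "patchify", "patch_count",
    "CTGEncoder", "encode_ctg", "ResNetEncoder", "encode_image",
    "prepare_gadf_input",
    "fit_metadata_stats", "standardize_metadata", "MetadataAutoencoder",
    "encode_metadata", "decode_metadata",
]


# --------------------------------------------------------------------------- #
# CTG branch
# --------------------------------------------------------------------------- #

@dataclass
class CTGEncoderConfig:
    patch_length: int = 64
    stride: int = 32
    d_model: int = 128
    n_layers: int = 3
    n_heads: int = 4
    ffn_width: int = 256
    dropout: float = 0.1
    eps: float = 1e-5

    def __post_init__(self):
        if not 1 <= self.stride <= self.patch_length:
            raise ValueError("require 1 <= stride <= patch_length")
        if self.d_model % self.n_heads:
            raise ValueError("d_model must be divisible by n_heads")


def instance_normalize(x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Per-sequence z-scoring with an eps guard (constant input -> zeros).
    Population standard deviation."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sequence")
    mu = x.mean(axis=-1, keepdims=True)
    var = x.var(axis=-1, keepdims=True)
    return (x - mu) / np.sqrt(var + eps)


def patch_count(L: int, P: int, S: int) -> int:
    """N = ceil((L − P) / S) + 1 (zero padding covers the remainder)."""
    if P > L:
        raise ValueError(f"patch length {P} exceeds series length {L}")
    return int(np.ceil((L - P) / S)) + 1


def patchify(x: np.ndarray, P: int, S: int) -> np.ndarray:
    """Split a 1-D series into overlapping length-P patches at stride S,
    zero-padding the tail so the last patch is full.  Returns (N, P)."""
    x = np.asarray(x, dtype=float)
    L = x.size
    N = patch_count(L, P, S)
    padded_len = (N - 1) * S + P
    padded = np.zeros(padded_len, dtype=x.dtype)
    padded[:L] = x
    idx = np.arange(P)[None, :] + S * np.arange(N)[:, None]
    return padded[idx]


class CTGEncoder(nn.Module):
    """Channel-independent patch Transformer over (FHR, UC); the Transformer
    parameters are shared across channels.  Output width is 2 * d_model."""

    def __init__(self, series_length: int, config: CTGEncoderConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.series_length = series_length
        self.n_patches = patch_count(series_length, config.patch_length,
                                     config.stride)
        self.embed = nn.Linear(config.patch_length, config.d_model, rng)
        self.pos = nn.Parameter(rng.normal(0.0, 0.02,
                                           (self.n_patches, config.d_model)))
        self.blocks = nn.Sequential(*[
            nn.TransformerEncoderLayer(config.d_model, config.n_heads,
                                       config.ffn_width, config.dropout, rng)
            for _ in range(config.n_layers)
        ])

    @property
    def out_dim(self) -> int:
        return 2 * self.config.d_model

    def forward(self, signal: nn.Tensor) -> nn.Tensor:
        """signal: (B, K, N, P) patch tensor -> (B, K * d_model)."""
        B, K, N, P = signal.shape
        x = signal.reshape(B * K, N, P)
        h = self.embed(x) + self.pos
        h = self.blocks(h)
        pooled = h.mean(axis=1)                      # (B*K, d)
        return pooled.reshape(B, K * self.config.d_model)

    def prepare(self, fhr: np.ndarray, uc: np.ndarray) -> np.ndarray:
        """Instance-normalize and patchify one record -> (2, N, P)."""
        if len(fhr) != len(uc):
            raise ValueError("channel length mismatch")
        cfg = self.config
        out = np.stack([
            patchify(instance_normalize(ch, cfg.eps), cfg.patch_length, cfg.stride)
            for ch in (fhr, uc)
        ])
        return out.astype(np.float32)


def encode_ctg(fhr: np.ndarray, uc: np.ndarray, encoder: CTGEncoder) -> np.ndarray:
    """Single-record convenience wrapper; returns the 2*d_model vector
    (FHR half first, then UC)."""
    batch = encoder.prepare(fhr, uc)[None]
    with nn.no_grad():
        return encoder(nn.Tensor(batch)).data[0]


# --------------------------------------------------------------------------- #
# Image branch (residual network)
# --------------------------------------------------------------------------- #

_RESNET_SPECS = {
    10: ("basic", (1, 1, 1, 1)),
    18: ("basic", (2, 2, 2, 2)),
    50: ("bottleneck", (3, 4, 6, 3)),
    101: ("bottleneck", (3, 4, 23, 3)),
    152: ("bottleneck", (3, 8, 36, 3)),
}

#: standard channel statistics applied when normalize_input is on
_CHANNEL_MEAN = np.array([0.485, 0.456, 0.406], dtype=np.float32)
_CHANNEL_STD = np.array([0.229, 0.224, 0.225], dtype=np.float32)


@dataclass
class ImageEncoderConfig:
    depth: int = 101
    pretrained: bool = True
    fine_tune: str = "full"        # "full" or "partial" (two deepest stages)
    base_width: int = 64
    small_input: bool = False      # 3x3/1 stem, no pool (for tiny test images)
    normalize_input: bool = True
    weights_path: str | None = None

    def __post_init__(self):
        if self.depth not in _RESNET_SPECS:
            raise ValueError(f"unsupported depth {self.depth}; "
                             f"choose from {sorted(_RESNET_SPECS)}")
        if self.fine_tune not in ("full", "partial"):
            raise ValueError("fine_tune must be 'full' or 'partial'")

    @property
    def out_dim(self) -> int:
        block, _ = _RESNET_SPECS[self.depth]
        factor = 4 if block == "bottleneck" else 1
        return 8 * self.base_width * factor


class _BasicBlock(nn.Module):
    expansion = 1

    def __init__(self, in_ch, ch, stride, rng):
        super().__init__()
        self.conv1 = nn.Conv2d(in_ch, ch, 3, rng, stride=stride, padding=1)
        self.bn1 = nn.BatchNorm2d(ch)
        self.conv2 = nn.Conv2d(ch, ch, 3, rng, padding=1)
        self.bn2 = nn.BatchNorm2d(ch)
        if stride != 1 or in_ch != ch:
            self.down = nn.Sequential(nn.Conv2d(in_ch, ch, 1, rng, stride=stride),
                                      nn.BatchNorm2d(ch))
        else:
            self.down = nn.Identity()

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out))
        return (out + self.down(x)).relu()


class _Bottleneck(nn.Module):
    expansion = 4

    def __init__(self, in_ch, ch, stride, rng):
        super().__init__()
        out_ch = ch * self.expansion
        self.conv1 = nn.Conv2d(in_ch, ch, 1, rng)
        self.bn1 = nn.BatchNorm2d(ch)
        self.conv2 = nn.Conv2d(ch, ch, 3, rng, stride=stride, padding=1)
        self.bn2 = nn.BatchNorm2d(ch)
        self.conv3 = nn.Conv2d(ch, out_ch, 1, rng)
        self.bn3 = nn.BatchNorm2d(out_ch)
        if stride != 1 or in_ch != out_ch:
            self.down = nn.Sequential(nn.Conv2d(in_ch, out_ch, 1, rng, stride=stride),
                                      nn.BatchNorm2d(out_ch))
        else:
            self.down = nn.Identity()

    def forward(self, x):
        out = self.bn1(self.conv1(x)).relu()
        out = self.bn2(self.conv2(out)).relu()
        out = self.bn3(self.conv3(out))
        return (out + self.down(x)).relu()


class ResNetEncoder(nn.Module):
    """Residual network with the classification layer removed; forward maps a
    (B, 3, H, W) image batch to (B, out_dim) features via global average
    pooling over the last stage."""

    def __init__(self, config: ImageEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        block_name, counts = _RESNET_SPECS[config.depth]
        block = _Bottleneck if block_name == "bottleneck" else _BasicBlock
        w = config.base_width
        if config.small_input:
            self.stem = nn.Sequential(nn.Conv2d(3, w, 3, rng, padding=1),
                                      nn.BatchNorm2d(w), nn.ReLU())
        else:
            self.stem = nn.Sequential(nn.Conv2d(3, w, 7, rng, stride=2, padding=3),
                                      nn.BatchNorm2d(w), nn.ReLU(),
                                      nn.MaxPool2d(3, 2, 1))
        chans = [w, 2 * w, 4 * w, 8 * w]
        in_ch = w
        for s, (ch, n_blocks) in enumerate(zip(chans, counts)):
            stride = 1 if s == 0 else 2
            blocks = []
            for b in range(n_blocks):
                blocks.append(block(in_ch, ch, stride if b == 0 else 1, rng))
                in_ch = ch * block.expansion
            setattr(self, f"stage{s + 1}", nn.Sequential(*blocks))
        self.out_dim = in_ch

        if config.pretrained:
            if config.weights_path:
                self.load_state_dict(dict(np.load(config.weights_path)))
            else:
                warnings.warn("pretrained weights unavailable offline; "
                              "falling back to random initialization")
        if config.fine_tune == "partial":
            for name, p in self.named_parameters():
                if not (name.startswith("stage3") or name.startswith("stage4")):
                    p.requires_grad = False

    def trainable_parameters(self) -> list[nn.Parameter]:
        return [p for p in self.parameters() if p.requires_grad]

    def forward(self, x: nn.Tensor) -> nn.Tensor:
        h = self.stem(x)
        for s in range(1, 5):
            h = getattr(self, f"stage{s}")(h)
        return h.mean(axis=(2, 3))                   # global average pool

    def prepare(self, image: GADFImage, expected_size: int | None = None) -> np.ndarray:
        return prepare_gadf_input(image, self.config, expected_size)


def prepare_gadf_input(image: GADFImage, config: ImageEncoderConfig,
                       expected_size: int | None = None) -> np.ndarray:
    """Replicate the single GADF channel to 3 and normalize -> (3, H, W):
    affine [−1,1] → [0,1], then optional backbone channel statistics."""
    px = image.pixels
    if expected_size is not None and px.shape[0] != expected_size:
        raise ValueError(f"expected {expected_size}x{expected_size} image, "
                         f"got {px.shape[0]}x{px.shape[1]}")
    x = ((px + 1.0) / 2.0).astype(np.float32)
    x = np.repeat(x[None], 3, axis=0)
    if config.normalize_input:
        x = (x - _CHANNEL_MEAN[:, None, None]) / _CHANNEL_STD[:, None, None]
    return x


def encode_image(image: GADFImage, encoder: ResNetEncoder,
                 expected_size: int | None = None) -> np.ndarray:
    """Single-image convenience wrapper; deterministic in eval mode."""
    was_training = encoder.training
    encoder.eval()
    try:
        batch = encoder.prepare(image, expected_size)[None]
        with nn.no_grad():
            out = encoder(nn.Tensor(batch)).data[0]
    finally:
        encoder.train(was_training)
    return out


# --------------------------------------------------------------------------- #
# Metadata branch
# --------------------------------------------------------------------------- #

@dataclass
class MetadataEncoderConfig:
    input_dim: int = 4
    hidden: int = 64
    latent_dim: int = 32

    def __post_init__(self):
        if min(self.input_dim, self.hidden, self.latent_dim) <= 0:
            raise ValueError("all dimensions must be positive")


@dataclass
class MetadataStats:
    """Standardization statistics fitted on the training split only."""

    means: dict[str, float]
    sds: dict[str, float]

    NUMERIC = ("age", "gravidity", "parity")


def fit_metadata_stats(train_records: Sequence[CTGRecord] | Iterable[MaternalMetadata]
                       ) -> MetadataStats:
    """Sample (n−1) mean/sd of age, gravidity and parity over the training
    split; missing values are excluded from the statistics they are later
    imputed with.  Zero or undefined variance is guarded to sd = 1."""
    metas = [r.metadata if isinstance(r, CTGRecord) else r for r in train_records]
    if len(metas) < 2:
        raise ValueError("need at least 2 training records to fit statistics")
    means, sds = {}, {}
    for name in MetadataStats.NUMERIC:
        vals = np.array([getattr(m, name) for m in metas
                         if getattr(m, name) is not None], dtype=float)
        means[name] = float(vals.mean()) if vals.size else 0.0
        sd = float(vals.std(ddof=1)) if vals.size >= 2 else 0.0
        if sd <= 0.0:
            warnings.warn(f"zero variance for metadata field {name!r}; "
                          "using sd = 1")
            sd = 1.0
        sds[name] = sd
    return MetadataStats(means=means, sds=sds)


def standardize_metadata(raw: MaternalMetadata, stats: MetadataStats) -> np.ndarray:
    """[z(age), z(gravidity), z(parity), diabetes]; missing numerics are
    mean-imputed before z-scoring (so they standardize to 0); missing
    diabetes defaults to 0."""
    out = np.empty(4, dtype=float)
    for i, name in enumerate(MetadataStats.NUMERIC):
        v = getattr(raw, name)
        if v is None:
            v = stats.means[name]
        out[i] = (v - stats.means[name]) / stats.sds[name]
    out[3] = float(raw.diabetes) if raw.diabetes is not None else 0.0
    return out


class MetadataAutoencoder(nn.Module):
    """4 → 64(ReLU) → latent encoder with a symmetric decoder; downstream
    fusion consumes only the latent vector, the reconstruction is a
    training-time regularizer."""

    def __init__(self, config: MetadataEncoderConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.enc1 = nn.Linear(config.input_dim, config.hidden, rng)
        self.enc2 = nn.Linear(config.hidden, config.latent_dim, rng)
        self.dec1 = nn.Linear(config.latent_dim, config.hidden, rng)
        self.dec2 = nn.Linear(config.hidden, config.input_dim, rng)

    @property
    def out_dim(self) -> int:
        return self.config.latent_dim

    def encode(self, x: nn.Tensor) -> nn.Tensor:
        return self.enc2(self.enc1(x).relu())

    def decode(self, z: nn.Tensor) -> nn.Tensor:
        return self.dec2(self.dec1(z).relu())

    def forward(self, x: nn.Tensor) -> tuple[nn.Tensor, nn.Tensor]:
        z = self.encode(x)
        return z, self.decode(z)


def encode_metadata(x_tilde: np.ndarray, ae: MetadataAutoencoder) -> np.ndarray:
    with nn.no_grad():
        return ae.encode(nn.Tensor(np.asarray(x_tilde, np.float32)[None])).data[0]


def decode_metadata(z: np.ndarray, ae: MetadataAutoencoder) -> np.ndarray:
    with nn.no_grad():
        return ae.decode(nn.Tensor(np.asarray(z, np.float32)[None])).data[0]
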