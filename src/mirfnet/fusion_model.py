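"""Token projection, the multimodal fusion Transformer, the classification
head, the composite loss, and the ablation fusion strategies.

Modality embeddings are projected to a common width d, stacked in the fixed
order (signal, image, metadata), offset by a learnable modality embedding, and
run through post-norm residual blocks (LayerNorm applied AFTER each residual
sum); the mean of the output tokens feeds a 2-logit softmax head.  Masked
modalities are omitted from the token sequence entirely rather than
zero-filled, so attention never sees a fake modality.

The training objective is label-smoothing cross-entropy plus a weighted
metadata-reconstruction MSE; at inference only the classification pathway is
used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .config import MODALITIES, FusionConfig, LossConfig, ModelConfig
from .encoders import CTGEncoder, MetadataAutoencoder, ResNetEncoder

__all__ = [
    "FusionConfig", "LossConfig", "ModelOutput", "ModalityProjector",
    "FusionTransformer", "BaselineFusion", "project_tokens", "fuse",
    "fuse_baseline", "classify", "smooth_labels", "label_smoothing_ce",
    "composite_loss", "MIRFNet",
]


@dataclass
class ModelOutput:
    logits: np.ndarray          # (C,)
    probability: float          # abnormal-class probability
    reconstruction: np.ndarray | None
    h_fuse: np.ndarray


class ModalityProjector(nn.Module):
    """Independent linear maps taking each present modality embedding into the
    shared d-dimensional token space."""

    def __init__(self, in_dims: dict[str, int], d: int, rng: np.random.Generator):
        super().__init__()
        self.order = tuple(m for m in MODALITIES if m in in_dims)
        for name in self.order:
            setattr(self, f"proj_{name}", nn.Linear(in_dims[name], d, rng))

    def forward(self, embeddings: dict[str, nn.Tensor]) -> nn.Tensor:
        """dict of (B, d_mod) -> (B, T, d) tokens in fixed modality order."""
        toks = [getattr(self, f"proj_{name}")(embeddings[name])
                for name in self.order]
        return nn.concat([t.reshape(t.shape[0], 1, t.shape[1]) for t in toks],
                         axis=1)


class FusionTransformer(nn.Module):
    """Learnable modality embedding + L post-norm blocks + token-mean pool."""

    def __init__(self, config: FusionConfig, n_tokens: int,
                 rng: np.random.Generator):
        super().__init__()
        d = config.d_common
        self.modality_embedding = nn.Parameter(rng.normal(0.0, 0.02, (n_tokens, d)))
        self.blocks = nn.Sequential(*[
            nn.TransformerEncoderLayer(d, config.n_heads, config.ffn_width,
                                       config.dropout, rng)
            for _ in range(config.n_layers)
        ])
        self.out_dim = d

    def forward(self, tokens: nn.Tensor) -> nn.Tensor:
        h = tokens + self.modality_embedding
        h = self.blocks(h)
        return h.mean(axis=1)


class BaselineFusion(nn.Module):
    """Concat / add / MLP fusion baselines over the projected tokens."""

    def __init__(self, strategy: str, d: int, n_tokens: int,
                 rng: np.random.Generator):
        super().__init__()
        self.strategy = strategy
        if strategy == "concat":
            self.out_dim = n_tokens * d
        elif strategy == "add":
            self.out_dim = d
        elif strategy == "mlp":
            self.fc1 = nn.Linear(n_tokens * d, d, rng)
            self.fc2 = nn.Linear(d, d, rng)
            self.out_dim = d
        else:
            raise ValueError(f"unknown fusion strategy {strategy!r}")

    def forward(self, tokens: nn.Tensor) -> nn.Tensor:
        B, T, d = tokens.shape
        if self.strategy == "add":
            return tokens.sum(axis=1)
        flat = tokens.reshape(B, T * d)
        if self.strategy == "concat":
            return flat
        return self.fc2(self.fc1(flat).relu())


# --------------------------------------------------------------------------- #
# functional surface
# --------------------------------------------------------------------------- #

def project_tokens(g_ctg: np.ndarray, f_img: np.ndarray, z_m: np.ndarray,
                   projector: ModalityProjector) -> np.ndarray:
    """Project the three modality vectors into the shared space and stack them
    in fixed (signal, image, metadata) order -> (3, d)."""
    embeddings = {
        "signal": nn.Tensor(np.asarray(g_ctg, np.float32)[None]),
        "image": nn.Tensor(np.asarray(f_img, np.float32)[None]),
        "metadata": nn.Tensor(np.asarray(z_m, np.float32)[None]),
    }
    with nn.no_grad():
        return projector(embeddings).data[0]


def fuse(x0: np.ndarray, fusion: FusionTransformer) -> np.ndarray:
    """Run the fusion Transformer on a single (T, d) token matrix."""
    was_training = fusion.training
    fusion.eval()
    try:
        with nn.no_grad():
            return fusion(nn.Tensor(np.asarray(x0, np.float32)[None])).data[0]
    finally:
        fusion.train(was_training)


def fuse_baseline(x0: np.ndarray, strategy: str,
                  module: BaselineFusion | None = None,
                  rng: np.random.Generator | None = None) -> np.ndarray:
    """Apply a baseline fusion strategy to a single (T, d) token matrix."""
    x0 = np.asarray(x0, np.float32)
    T, d = x0.shape
    if module is None:
        module = BaselineFusion(strategy, d, T, rng or np.random.default_rng(0))
    with nn.no_grad():
        return module(nn.Tensor(x0[None])).data[0]


def classify(h_fuse: np.ndarray, head: nn.Linear) -> tuple[np.ndarray, float]:
    """2-logit softmax head; the reported probability is the abnormal class."""
    with nn.no_grad():
        logits = head(nn.Tensor(np.asarray(h_fuse, np.float32)[None])).data[0]
    probs = _softmax_np(logits)
    return logits, float(probs[1])


def _softmax_np(logits: np.ndarray) -> np.ndarray:
    e = np.exp(logits - logits.max(axis=-1, keepdims=True))
    return e / e.sum(axis=-1, keepdims=True)


def smooth_labels(y: np.ndarray | int, eps: float, n_classes: int = 2) -> np.ndarray:
    """True class 1−ε, every other class ε/(C−1)."""
    y = np.atleast_1d(np.asarray(y, dtype=int))
    if np.any((y < 0) | (y >= n_classes)):
        raise ValueError(f"labels must be in [0, {n_classes})")
    out = np.full((y.size, n_classes), eps / (n_classes - 1))
    out[np.arange(y.size), y] = 1.0 - eps
    return out.squeeze() if out.shape[0] == 1 else out


def label_smoothing_ce(logits: nn.Tensor, labels: np.ndarray,
                       config: LossConfig) -> nn.Tensor:
    """−(1/M) Σ_m Σ_c ỹ_c log p_c with softmax probabilities."""
    targets = np.atleast_2d(smooth_labels(labels, config.smoothing,
                                          config.n_classes)).astype(np.float32)
    logp = logits.log_softmax(axis=-1)
    return -(nn.Tensor(targets) * logp).sum(axis=-1).mean()


def composite_loss(logits: nn.Tensor, reconstruction: nn.Tensor | None,
                   labels: np.ndarray, meta_targets: np.ndarray | None,
                   config: LossConfig) -> tuple[nn.Tensor, dict[str, float]]:
    """L = Lcls + λ·Lrec; Lrec is the batch-mean squared L2 reconstruction
    error of the standardized metadata vector (0 when the metadata branch is
    masked)."""
    l_cls = label_smoothing_ce(logits, labels, config)
    if reconstruction is not None and meta_targets is not None:
        diff = reconstruction - nn.Tensor(np.asarray(meta_targets, np.float32))
        l_rec = (diff * diff).sum(axis=-1).mean()
        total = l_cls + config.recon_weight * l_rec
        rec_val = float(l_rec.data)
    else:
        total = l_cls
        rec_val = 0.0
    return total, {"cls": float(l_cls.data), "rec": rec_val,
                   "total": float(total.data)}


# --------------------------------------------------------------------------- #
# full model
# --------------------------------------------------------------------------- #

class MIRFNet(nn.Module):
    """End-to-end tri-modal classifier.

    Batch keys (only those for unmasked modalities are read):
      ``signal``  (B, K, N, P) prepared patches,
      ``image``   (B, 3, H, W) prepared images,
      ``meta``    (B, 4) standardized metadata.
    """

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        mask = config.fusion.modality_mask
        in_dims: dict[str, int] = {}
        if "signal" in mask:
            self.ctg_encoder = CTGEncoder(config.segment_length, config.ctg, rng)
            in_dims["signal"] = len(config.signals) * config.ctg.d_model
        if "image" in mask:
            self.image_encoder = ResNetEncoder(config.image, rng)
            in_dims["image"] = self.image_encoder.out_dim
        if "metadata" in mask:
            self.metadata_ae = MetadataAutoencoder(config.metadata, rng)
            in_dims["metadata"] = config.metadata.latent_dim
        self.projector = ModalityProjector(in_dims, config.fusion.d_common, rng)
        n_tokens = len(in_dims)
        if config.fusion.strategy == "transformer":
            self.fusion = FusionTransformer(config.fusion, n_tokens, rng)
        else:
            self.fusion = BaselineFusion(config.fusion.strategy,
                                         config.fusion.d_common, n_tokens, rng)
        self.head = nn.Linear(self.fusion.out_dim, config.loss.n_classes, rng)

    @property
    def modality_mask(self) -> tuple:
        return self.config.fusion.modality_mask

    def forward(self, batch: dict) -> tuple[nn.Tensor, nn.Tensor | None, nn.Tensor]:
        mask = self.modality_mask
        embeddings: dict[str, nn.Tensor] = {}
        recon = None
        if "signal" in mask:
            embeddings["signal"] = self.ctg_encoder(_as_tensor(batch["signal"]))
        if "image" in mask:
            embeddings["image"] = self.image_encoder(_as_tensor(batch["image"]))
        if "metadata" in mask:
            z, recon = self.metadata_ae(_as_tensor(batch["meta"]))
            embeddings["metadata"] = z
        tokens = self.projector(embeddings)
        h_fuse = self.fusion(tokens)
        logits = self.head(h_fuse)
        return logits, recon, h_fuse

    def predict(self, batch: dict) -> list[ModelOutput]:
        """Inference: eval mode, no graph; reconstruction pathway retained in
        the output object for inspection but unused downstream."""
        was_training = self.training
        self.eval()
        try:
            with nn.no_grad():
                logits, recon, h_fuse = self.forward(batch)
        finally:
            self.train(was_training)
        probs = _softmax_np(logits.data)
        outs = []
        for i in range(logits.shape[0]):
            outs.append(ModelOutput(
                logits=logits.data[i],
                probability=float(probs[i, 1]),
                reconstruction=None if recon is None else recon.data[i],
                h_fuse=h_fuse.data[i],
            ))
        return outs

    def predict_proba(self, batch: dict) -> np.ndarray:
        return np.array([o.probability for o in self.predict(batch)])


def _as_tensor(x) -> nn.Tensor:
    return x if isinstance(x, nn.Tensor) else nn.Tensor(np.asarray(x, np.float32))
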