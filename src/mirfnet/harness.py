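"""Stratified splitting, the training loop, multi-seed experiments, and
ablation sweeps.

Splits are stratified per class with floor rounding for train/validation and
the remainder assigned to test (the unique convention reproducing the
published 331/110/111 cohort sizes).  Each seed drives an independent split,
model initialization, and training run; run metrics are aggregated as
mean ± sample sd.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .config import ModelConfig
from .encoders import (fit_metadata_stats, instance_normalize, patchify,
                       prepare_gadf_input, standardize_metadata, MetadataStats)
from .fixtures import CTGRecord
from .fusion_model import MIRFNet, composite_loss
from .gadf import fhr_to_gadf
from .metrics import MetricSet, aggregate_runs, evaluate_predictions
from .preprocess import PreprocessConfig, preprocess_record

__all__ = [
    "SplitSpec", "TrainConfig", "stratified_split", "featurize",
    "train_model", "run_experiment", "ablation_sweep", "EvalReport",
    "TrainResult", "save_checkpoint", "load_checkpoint",
]


@dataclass
class SplitSpec:
    ratios: tuple = (0.6, 0.2, 0.2)
    seed: int = 0

    def __post_init__(self):
        self.ratios = tuple(float(r) for r in self.ratios)
        if len(self.ratios) != 3 or any(r <= 0 for r in self.ratios):
            raise ValueError("need three positive ratios")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("ratios must sum to 1")


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    max_epochs: int = 100
    selection_metric: str = "qi"       # validation qi | auc | loss
    seeds: tuple = (0, 42, 3407)
    log_every: int = 0

    def __post_init__(self):
        if self.learning_rate <= 0 or self.batch_size <= 0 or self.max_epochs <= 0:
            raise ValueError("rates and sizes must be positive")
        if self.selection_metric not in ("qi", "auc", "loss"):
            raise ValueError("selection_metric must be qi, auc or loss")


class SplitError(ValueError):
    pass


def stratified_split(labels, spec: SplitSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per class: seeded shuffle, floor(n_c*r_train) to train, floor(n_c*r_val)
    to validation, remainder to test.  Returns (train, val, test) index arrays."""
    labels = np.asarray(labels, dtype=int)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise SplitError("both classes must be present")
    rng = np.random.default_rng(spec.seed)
    r_train, r_val, _ = spec.ratios
    parts: list[list[np.ndarray]] = [[], [], []]
    for c in classes:
        idx = np.flatnonzero(labels == c)
        if idx.size < 3:
            raise SplitError(f"class {c} has fewer than 3 members")
        idx = rng.permutation(idx)
        n_train = int(np.floor(idx.size * r_train))
        n_val = int(np.floor(idx.size * r_val))
        parts[0].append(idx[:n_train])
        parts[1].append(idx[n_train:n_train + n_val])
        parts[2].append(idx[n_train + n_val:])
    return tuple(np.sort(np.concatenate(p)) for p in parts)


# --------------------------------------------------------------------------- #
# feature preparation
# --------------------------------------------------------------------------- #

def featurize(records: list[CTGRecord], config: ModelConfig,
              preprocess: PreprocessConfig | None = None,
              clean: bool = True) -> dict:
    """Deterministic per-record feature arrays for every unmasked modality.

    Metadata standardization is split-dependent, so the raw metadata objects
    are kept and standardized later with training-split statistics.
    """
    preprocess = preprocess or PreprocessConfig()
    mask = config.fusion.modality_mask
    cleaned = [preprocess_record(r, preprocess)[0] if clean else r
               for r in records]
    feats: dict = {
        "labels": np.array([r.label for r in records], dtype=int),
        "metadata": [r.metadata for r in records],
        "record_ids": [r.record_id for r in records],
    }
    if "signal" in mask:
        chans = config.signals
        sig = np.stack([
            np.stack([
                patchify(instance_normalize(getattr(r, ch), config.ctg.eps),
                         config.ctg.patch_length, config.ctg.stride)
                for ch in chans])
            for r in cleaned]).astype(np.float32)
        feats["signal"] = sig
    if "image" in mask:
        feats["image"] = np.stack([
            prepare_gadf_input(fhr_to_gadf(r.fhr, config.gadf), config.image)
            for r in cleaned]).astype(np.float32)
    return feats


def _standardized_meta(feats: dict, stats: MetadataStats) -> np.ndarray:
    return np.stack([standardize_metadata(m, stats)
                     for m in feats["metadata"]]).astype(np.float32)


def _batch(feats: dict, meta_std: np.ndarray, idx: np.ndarray,
           mask: tuple) -> dict:
    batch = {}
    if "signal" in mask:
        batch["signal"] = feats["signal"][idx]
    if "image" in mask:
        batch["image"] = feats["image"][idx]
    if "metadata" in mask:
        batch["meta"] = meta_std[idx]
    return batch


# --------------------------------------------------------------------------- #
# training
# --------------------------------------------------------------------------- #

@dataclass
class TrainResult:
    model: MIRFNet
    best_state: dict
    best_epoch: int
    log: list = field(default_factory=list)
    stats: MetadataStats | None = None
    split: tuple | None = None


def _predict_probs(model: MIRFNet, feats: dict, meta_std: np.ndarray,
                   idx: np.ndarray, batch_size: int) -> np.ndarray:
    probs = []
    for lo in range(0, idx.size, batch_size):
        sub = idx[lo:lo + batch_size]
        probs.append(model.predict_proba(
            _batch(feats, meta_std, sub, model.modality_mask)))
    return np.concatenate(probs)


def train_model(records: list[CTGRecord], model_config: ModelConfig,
                train_config: TrainConfig, seed: int,
                split: tuple | None = None,
                features: dict | None = None) -> TrainResult:
    """Train one model: seeds initialization and shuffling, selects the
    checkpoint with the best validation metric, returns it plus the per-epoch
    log.  Aborts on a non-finite loss."""
    rng = np.random.default_rng(seed)
    labels = np.array([r.label for r in records], dtype=int)
    if split is None:
        split = stratified_split(labels, SplitSpec(seed=seed))
    train_idx, val_idx, _ = split
    for name, idx in zip(("train", "validation"), (train_idx, val_idx)):
        if len(np.unique(labels[idx])) < 2:
            raise SplitError(f"{name} split lacks one of the classes")

    feats = features if features is not None else featurize(records, model_config)
    stats = fit_metadata_stats([records[i].metadata for i in train_idx])
    meta_std = _standardized_meta(feats, stats)
    mask = model_config.fusion.modality_mask

    model = MIRFNet(model_config, rng)
    params = [p for p in model.parameters() if p.requires_grad]
    opt = nn.Adam(params, lr=train_config.learning_rate,
                  weight_decay=train_config.weight_decay)

    sign = -1.0 if train_config.selection_metric == "loss" else 1.0
    best_score, best_state, best_epoch = -np.inf, model.state_dict(), -1
    best_state = {k: v.copy() for k, v in best_state.items()}
    log: list[dict] = []

    for epoch in range(train_config.max_epochs):
        model.train()
        order = rng.permutation(train_idx)
        epoch_losses = []
        for lo in range(0, order.size, train_config.batch_size):
            sub = order[lo:lo + train_config.batch_size]
            batch = _batch(feats, meta_std, sub, mask)
            logits, recon, _ = model(batch)
            loss, parts = composite_loss(
                logits, recon if "metadata" in mask else None,
                labels[sub], meta_std[sub] if "metadata" in mask else None,
                model_config.loss)
            if not np.isfinite(parts["total"]):
                raise RuntimeError(
                    f"training diverged at epoch {epoch}: loss={parts}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(parts)

        val_probs = _predict_probs(model, feats, meta_std, val_idx,
                                   train_config.batch_size)
        val_metrics = evaluate_predictions(labels[val_idx], val_probs)
        mean_loss = float(np.mean([p["total"] for p in epoch_losses]))
        if train_config.selection_metric == "loss":
            score = sign * mean_loss
        else:
            score = getattr(val_metrics, train_config.selection_metric)
        entry = {"epoch": epoch, "train_loss": mean_loss,
                 "train_loss_cls": float(np.mean([p["cls"] for p in epoch_losses])),
                 "train_loss_rec": float(np.mean([p["rec"] for p in epoch_losses])),
                 **{f"val_{k}": v for k, v in val_metrics.to_dict().items()}}
        log.append(entry)
        if train_config.log_every and epoch % train_config.log_every == 0:
            print(f"epoch {epoch}: loss {mean_loss:.4f} "
                  f"val qi {val_metrics.qi:.4f}")
        if score > best_score:
            best_score = score
            best_epoch = epoch
            best_state = {k: v.copy() for k, v in model.state_dict().items()}

    model.load_state_dict(best_state)
    return TrainResult(model=model, best_state=best_state, best_epoch=best_epoch,
                       log=log, stats=stats, split=split)


# --------------------------------------------------------------------------- #
# experiments
# --------------------------------------------------------------------------- #

@dataclass
class EvalReport:
    runs: list                       # [{"seed": s, "metrics": {...}}]
    aggregate: dict                  # {metric: {"mean": m, "sd": s}}
    config: dict = field(default_factory=dict)

    def to_json(self, path: str | None = None) -> str:
        payload = json.dumps(
            {"runs": self.runs, "aggregate": self.aggregate,
             "config": self.config}, indent=2, default=float)
        if path:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    @classmethod
    def from_json(cls, text_or_path: str) -> "EvalReport":
        try:
            data = json.loads(text_or_path)
        except (json.JSONDecodeError, ValueError):
            with open(text_or_path) as fh:
                data = json.load(fh)
        return cls(runs=data["runs"], aggregate=data["aggregate"],
                   config=data.get("config", {}))


def run_experiment(records: list[CTGRecord], model_config: ModelConfig,
                   train_config: TrainConfig,
                   features: dict | None = None) -> EvalReport:
    """For each seed: fresh stratified split, training, test-set metrics;
    aggregate over seeds."""
    labels = np.array([r.label for r in records], dtype=int)
    feats = features if features is not None else featurize(records, model_config)
    runs, metric_sets = [], []
    for seed in train_config.seeds:
        split = stratified_split(labels, SplitSpec(seed=seed))
        result = train_model(records, model_config, train_config, seed,
                             split=split, features=feats)
        _, _, test_idx = split
        meta_std = _standardized_meta(feats, result.stats)
        probs = _predict_probs(result.model, feats, meta_std, test_idx,
                               train_config.batch_size)
        ms = evaluate_predictions(labels[test_idx], probs)
        metric_sets.append(ms)
        runs.append({"seed": int(seed), "metrics": ms.to_dict(),
                     "best_epoch": result.best_epoch})
    return EvalReport(runs=runs, aggregate=aggregate_runs(metric_sets),
                      config=model_config.to_dict())


_SWEEP_AXES = ("modality_mask", "signals", "strategy", "patch_stride",
               "heads", "layers", "smoothing", "recon_weight")


def _apply_axis(config: ModelConfig, axis: str, value) -> ModelConfig:
    cfg = copy.deepcopy(config)
    if axis == "modality_mask":
        cfg.fusion.modality_mask = tuple(value)
    elif axis == "signals":
        cfg.signals = tuple(value)
    elif axis == "strategy":
        cfg.fusion.strategy = value
    elif axis == "patch_stride":
        cfg.ctg.patch_length, cfg.ctg.stride = value
    elif axis == "heads":
        cfg.fusion.n_heads = value
    elif axis == "layers":
        cfg.fusion.n_layers = value
    elif axis == "smoothing":
        cfg.loss.smoothing = value
    elif axis == "recon_weight":
        cfg.loss.recon_weight = value
    else:
        raise ValueError(f"unknown sweep axis {axis!r}; "
                         f"choose from {_SWEEP_AXES}")
    cfg.fusion.__post_init__()
    cfg.ctg.__post_init__()
    cfg.loss.__post_init__()
    return cfg


def ablation_sweep(records: list[CTGRecord], base_config: ModelConfig,
                   train_config: TrainConfig,
                   axes: dict[str, list]) -> list[tuple[str, EvalReport]]:
    """One EvalReport per configuration along each requested axis."""
    rows: list[tuple[str, EvalReport]] = []
    for axis, values in axes.items():
        for value in values:
            cfg = _apply_axis(base_config, axis, value)
            report = run_experiment(records, cfg, train_config)
            rows.append((f"{axis}={value}", report))
    return rows


def sweep_table(rows: list[tuple[str, EvalReport]]):
    """Comparison table (pandas DataFrame) of aggregate means per config."""
    import pandas as pd
    data = []
    for label, report in rows:
        entry = {"config": label}
        for metric, agg in report.aggregate.items():
            entry[metric] = agg["mean"]
            entry[metric + "_sd"] = agg["sd"]
        data.append(entry)
    return pd.DataFrame(data)


# --------------------------------------------------------------------------- #
# checkpoints
# --------------------------------------------------------------------------- #

def save_checkpoint(path: str, model: MIRFNet) -> None:
    """npz container holding all submodule weights plus the resolved config."""
    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8)
    np.savez(path, **state)


def load_checkpoint(path: str, rng: np.random.Generator | None = None) -> MIRFNet:
    blob = dict(np.load(path))
    config = ModelConfig.from_dict(
        json.loads(blob.pop("__config__").tobytes().decode()))
    model = MIRFNet(config, rng or np.random.default_rng(0))
    model.load_state_dict(blob)
    return model
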