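"""Deterministic synthetic CTG dataset generator.

Produces records with the statistical structure the classifier assumes so the
whole pipeline is testable without any download: a plausible FHR baseline with
short-term variability, periodic uterine contractions, label-dependent late
decelerations time-locked ~30 s after contraction peaks, label-correlated
maternal metadata (higher diabetes prevalence and age in the abnormal class),
and injected invalid points (out-of-range dropouts, spikes, baseline jumps)
with ground-truth masks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CTGRecord, MaternalMetadata
from .preprocess import ValidityMask, REASON_INJECTED, REASON_NONE

__all__ = [
    "SyntheticConfig", "CTGRecord", "MaternalMetadata",
    "generate_dataset", "inject_artifacts",
]


@dataclass
class SyntheticConfig:
    n_records: int = 10
    abnormal_fraction: float = 0.5
    seed: int = 0
    segment_length: int = 7200
    sample_rate: float = 4.0
    baseline_mean: float = 135.0
    baseline_sd: float = 10.0
    variability_amplitude: float = 5.0
    contraction_period: float = 300.0  # seconds between contraction peaks
    contraction_amplitude: float = 50.0
    decel_depth: float = 30.0          # bpm; abnormal-class effect size
    decel_lag: float = 30.0            # seconds after the contraction peak
    decel_width: float = 15.0          # seconds (Gaussian sd)
    artifact_rates: dict = field(default_factory=lambda: {
        "dropout": 0.002, "spike": 0.002, "jump": 0.0005})
    gravidity_missing_rate: float = 0.007
    diabetes_prob_normal: float = 0.08
    diabetes_prob_abnormal: float = 0.45
    age_mean_normal: float = 28.0
    age_mean_abnormal: float = 32.0
    age_sd: float = 4.0

    def __post_init__(self):
        if self.n_records <= 0:
            raise ValueError("n_records must be positive")
        if not 0.0 <= self.abnormal_fraction <= 1.0:
            raise ValueError("abnormal_fraction must be in [0, 1]")
        if self.segment_length <= 0:
            raise ValueError("segment_length must be positive")
        for name, rate in self.artifact_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"artifact rate {name!r} must be in [0, 1]")
        if not 0.0 <= self.gravidity_missing_rate <= 1.0:
            raise ValueError("gravidity_missing_rate must be in [0, 1]")


def inject_artifacts(signal: np.ndarray, rates: dict, seed: int,
                     dropout_value: float = 0.0,
                     spike_height: float = 40.0,
                     jump_height: float = 35.0,
                     jump_run: int = 8) -> tuple[np.ndarray, ValidityMask]:
    """Corrupt `signal` at randomly chosen positions and return the corrupted
    copy plus the ground-truth mask of exactly the injected samples.

    dropout: sample replaced by an out-of-range constant.
    spike:   +/- spike_height added at a single sample.
    jump:    +/- jump_height persistent offset over a short run of samples.
    """
    rng = np.random.default_rng(seed)
    x = np.asarray(signal, dtype=float).copy()
    n = x.size
    flags = np.zeros(n, dtype=bool)

    drop = rng.random(n) < rates.get("dropout", 0.0)
    x[drop] = dropout_value
    flags |= drop

    spikes = rng.random(n) < rates.get("spike", 0.0)
    signs = rng.choice([-1.0, 1.0], size=n)
    spikes &= ~flags
    x[spikes] += signs[spikes] * spike_height
    flags |= spikes

    jump_starts = np.flatnonzero(rng.random(n) < rates.get("jump", 0.0))
    for s in jump_starts:
        run = slice(s, min(s + jump_run, n))
        sub = ~flags[run]
        x[run][sub] += float(rng.choice([-1.0, 1.0])) * jump_height
        flags[run] |= sub

    reasons = np.where(flags, REASON_INJECTED, REASON_NONE)
    return x, ValidityMask(flags, reasons)


def _band_limited_noise(rng: np.random.Generator, n: int, sd: float,
                        width: int = 9) -> np.ndarray:
    white = rng.normal(0.0, sd, n + width)
    kernel = np.ones(width) / width
    return np.convolve(white, kernel, mode="same")[:n] * np.sqrt(width)


def _contraction_peaks(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    duration = config.segment_length / config.sample_rate
    first = config.contraction_period / 2.0
    peaks = np.arange(first, duration, config.contraction_period)
    jitter = rng.normal(0.0, config.contraction_period * 0.03, peaks.size)
    return np.clip(peaks + jitter, 0.0, duration)


def _synthesize_uc(config: SyntheticConfig, rng: np.random.Generator,
                   peaks: np.ndarray) -> np.ndarray:
    t = np.arange(config.segment_length) / config.sample_rate
    uc = np.full(t.size, 10.0) + _band_limited_noise(rng, t.size, 0.8)
    width = config.contraction_period / 8.0
    for p in peaks:
        amp = config.contraction_amplitude * rng.uniform(0.8, 1.2)
        uc += amp * np.exp(-0.5 * ((t - p) / width) ** 2)
    return uc


def _synthesize_fhr(config: SyntheticConfig, rng: np.random.Generator,
                    peaks: np.ndarray, label: int) -> np.ndarray:
    t = np.arange(config.segment_length) / config.sample_rate
    baseline = float(np.clip(rng.normal(config.baseline_mean, config.baseline_sd),
                             115.0, 155.0))
    phase = rng.uniform(0, 2 * np.pi)
    fhr = baseline \
        + config.variability_amplitude * np.sin(2 * np.pi * 0.05 * t + phase) \
        + _band_limited_noise(rng, t.size, config.variability_amplitude / 3.0)
    if label == 1 and config.decel_depth > 0 and peaks.size:
        # late decelerations lagged after contraction peaks; at least one
        keep = rng.random(peaks.size) < 0.8
        if not keep.any():
            keep[0] = True
        for p in peaks[keep]:
            depth = config.decel_depth * rng.uniform(0.8, 1.2)
            fhr -= depth * np.exp(
                -0.5 * ((t - (p + config.decel_lag)) / config.decel_width) ** 2)
    return fhr


def _synthesize_metadata(config: SyntheticConfig, rng: np.random.Generator,
                         label: int) -> MaternalMetadata:
    age_mean = config.age_mean_abnormal if label else config.age_mean_normal
    dia_p = config.diabetes_prob_abnormal if label else config.diabetes_prob_normal
    gravidity: float | None = float(1 + rng.poisson(1.0))
    if rng.random() < config.gravidity_missing_rate:
        gravidity = None
    parity = float(rng.poisson(0.8))
    if gravidity is not None:
        parity = min(parity, gravidity - 1 if gravidity > 0 else 0)
    return MaternalMetadata(
        age=float(np.clip(rng.normal(age_mean, config.age_sd), 16, 48)),
        gravidity=gravidity,
        parity=parity,
        diabetes=int(rng.random() < dia_p),
    )


def generate_dataset(config: SyntheticConfig, return_masks: bool = False):
    """Generate ``config.n_records`` seeded records.

    Exactly ``round(n_records * abnormal_fraction)`` records carry label 1;
    abnormal records contain at least one late deceleration time-locked to a
    contraction.  With ``return_masks=True`` also returns the per-record
    ground-truth artifact masks ``{"fhr": ..., "uc": ...}``.
    """
    if not isinstance(config, SyntheticConfig):
        raise TypeError("config must be a SyntheticConfig")
    rng = np.random.default_rng(config.seed)
    n_abnormal = int(np.floor(config.n_records * config.abnormal_fraction + 0.5))
    labels = np.zeros(config.n_records, dtype=int)
    labels[rng.permutation(config.n_records)[:n_abnormal]] = 1

    records, masks = [], []
    for i, label in enumerate(labels):
        rec_rng = np.random.default_rng(rng.integers(0, 2 ** 63))
        peaks = _contraction_peaks(config, rec_rng)
        uc = _synthesize_uc(config, rec_rng, peaks)
        fhr = _synthesize_fhr(config, rec_rng, peaks, int(label))
        fhr_seed = int(rec_rng.integers(0, 2 ** 31))
        uc_seed = int(rec_rng.integers(0, 2 ** 31))
        fhr, fhr_mask = inject_artifacts(fhr, config.artifact_rates, fhr_seed)
        uc, uc_mask = inject_artifacts(
            uc, {"spike": config.artifact_rates.get("spike", 0.0)},
            uc_seed, spike_height=60.0)
        rec = CTGRecord(
            record_id=f"syn{i:04d}",
            fhr=fhr, uc=uc,
            metadata=_synthesize_metadata(config, rec_rng, int(label)),
            label=int(label),
            sample_rate=config.sample_rate,
            provenance={"source": "synthetic", "seed": config.seed},
        )
        records.append(rec)
        masks.append({"fhr": fhr_mask, "uc": uc_mask})
    if return_masks:
        return records, masks
    return records
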