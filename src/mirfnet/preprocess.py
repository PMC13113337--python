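"""CTG signal cleaning: invalid-point detection, linear interpolation,
smoothing, and signal-loss eligibility.

FHR invalidity combines a physiological range rule (outside 50-220 bpm) with
an adjacent-jump rule (more than 25 bpm relative to the most recent
still-valid sample; the later sample of the pair is the one flagged).  UC
invalidity uses the 3-sigma (Pauta) rule against local statistics over a
centered sliding window, truncated at the boundaries.  Invalid samples are
treated as missing and rebuilt by linear interpolation between valid
neighbours, then a centered moving average improves signal quality.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .records import CTGRecord

__all__ = [
    "PreprocessConfig", "ValidityMask", "detect_invalid_fhr",
    "detect_invalid_uc", "interpolate_invalid", "smooth",
    "signal_loss_rate", "preprocess_record",
    "UnrecoverableRecordError",
]

#: reason codes carried alongside the boolean flags
REASON_NONE = "none"
REASON_RANGE = "range"
REASON_JUMP = "jump"
REASON_SIGMA = "sigma"
REASON_INJECTED = "injected"
REASONS = (REASON_RANGE, REASON_JUMP, REASON_SIGMA, REASON_INJECTED, REASON_NONE)


class UnrecoverableRecordError(ValueError):
    """Raised when every sample of a channel is invalid."""


@dataclass
class PreprocessConfig:
    fhr_min: float = 50.0
    fhr_max: float = 220.0
    fhr_jump: float = 25.0
    uc_window: int = 500
    uc_sigma_k: float = 3.0
    smooth_window: int = 5
    max_loss_rate: float = 0.5

    def __post_init__(self):
        if not self.fhr_min < self.fhr_max:
            raise ValueError("fhr_min must be < fhr_max")
        if self.uc_window < 2:
            raise ValueError("uc_window must be >= 2")
        if self.uc_sigma_k <= 0:
            raise ValueError("uc_sigma_k must be > 0")
        if self.smooth_window < 1 or self.smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd and >= 1")


@dataclass
class ValidityMask:
    """Per-sample invalidity flags plus a reason code per sample."""

    flags: np.ndarray
    reasons: np.ndarray = None

    def __post_init__(self):
        self.flags = np.asarray(self.flags, dtype=bool)
        if self.reasons is None:
            self.reasons = np.where(self.flags, REASON_INJECTED, REASON_NONE)
        self.reasons = np.asarray(self.reasons, dtype="U8")
        if self.reasons.shape != self.flags.shape:
            raise ValueError("flags and reasons must have the same length")

    def __len__(self) -> int:
        return self.flags.size

    @property
    def n_invalid(self) -> int:
        return int(self.flags.sum())


def detect_invalid_fhr(fhr: np.ndarray, config: PreprocessConfig | None = None) -> ValidityMask:
    """Flag FHR samples outside [fhr_min, fhr_max] or jumping by more than
    fhr_jump relative to the most recent still-valid sample."""
    config = config or PreprocessConfig()
    fhr = np.asarray(fhr, dtype=float)
    if fhr.size == 0:
        raise ValueError("empty FHR sequence")
    flags = np.zeros(fhr.size, dtype=bool)
    reasons = np.full(fhr.size, REASON_NONE, dtype="U8")

    out_of_range = (fhr < config.fhr_min) | (fhr > config.fhr_max) | ~np.isfinite(fhr)
    flags[out_of_range] = True
    reasons[out_of_range] = REASON_RANGE

    # jump rule: compare against the most recent unflagged sample so a lone
    # spike does not invalidate the tail
    last_valid = None
    for i in range(fhr.size):
        if flags[i]:
            continue
        if last_valid is not None and abs(fhr[i] - last_valid) > config.fhr_jump:
            flags[i] = True
            reasons[i] = REASON_JUMP
        else:
            last_valid = fhr[i]
    return ValidityMask(flags, reasons)


def _windowed_stats(x: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Mean/sd over a centered window of `window` samples, truncated at the
    boundaries, computed for every position via cumulative sums."""
    n = x.size
    half_lo = (window - 1) // 2
    half_hi = window // 2
    idx = np.arange(n)
    lo = np.maximum(idx - half_lo, 0)
    hi = np.minimum(idx + half_hi, n - 1) + 1  # exclusive
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    cnt = (hi - lo).astype(float)
    mean = (cs[hi] - cs[lo]) / cnt
    var = (cs2[hi] - cs2[lo]) / cnt - mean ** 2
    sd = np.sqrt(np.maximum(var, 0.0))
    return mean, sd


def detect_invalid_uc(uc: np.ndarray, config: PreprocessConfig | None = None) -> ValidityMask:
    """Pauta (3-sigma) rule over a centered sliding window of uc_window
    samples; windows with zero local sd flag nothing."""
    config = config or PreprocessConfig()
    uc = np.asarray(uc, dtype=float)
    if uc.size == 0:
        raise ValueError("empty UC sequence")
    mean, sd = _windowed_stats(uc, min(config.uc_window, uc.size))
    with np.errstate(invalid="ignore"):
        flags = (sd > 0) & (np.abs(uc - mean) > config.uc_sigma_k * sd)
    flags |= ~np.isfinite(uc)
    reasons = np.where(flags, REASON_SIGMA, REASON_NONE)
    return ValidityMask(flags, reasons)


def interpolate_invalid(signal: np.ndarray, mask: ValidityMask) -> np.ndarray:
    """Replace invalid runs by the straight line between the nearest valid
    neighbours; leading/trailing runs take the nearest valid value."""
    signal = np.asarray(signal, dtype=float)
    flags = mask.flags
    if flags.shape != signal.shape:
        raise ValueError("mask length does not match signal length")
    if flags.all():
        raise UnrecoverableRecordError("all samples invalid; cannot interpolate")
    if not flags.any():
        return signal.copy()
    idx = np.arange(signal.size)
    valid = ~flags
    return np.interp(idx, idx[valid], signal[valid])


def smooth(signal: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Centered moving average of width smooth_window; boundary windows are
    truncated so the output has the input's length."""
    config = config or PreprocessConfig()
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValueError("empty signal")
    w = config.smooth_window
    if w == 1:
        return signal.copy()
    kernel = np.ones(w)
    sums = np.convolve(signal, kernel, mode="same")
    counts = np.convolve(np.ones_like(signal), kernel, mode="same")
    return sums / counts


def signal_loss_rate(mask: ValidityMask) -> float:
    """Fraction of flagged samples."""
    if len(mask) == 0:
        raise ValueError("empty mask")
    return float(mask.flags.mean())


def is_eligible(mask: ValidityMask, config: PreprocessConfig | None = None) -> bool:
    """Strict ``rate < max_loss_rate`` eligibility predicate."""
    config = config or PreprocessConfig()
    return signal_loss_rate(mask) < config.max_loss_rate


def preprocess_record(record: CTGRecord,
                      config: PreprocessConfig | None = None
                      ) -> tuple[CTGRecord, dict[str, ValidityMask]]:
    """detect -> interpolate -> smooth, independently per channel.

    FHR uses the range+jump rules; UC uses the Pauta rule.  Returns the
    cleaned record and the per-channel masks computed on the raw signals.
    """
    config = config or PreprocessConfig()
    fhr_mask = detect_invalid_fhr(record.fhr, config)
    uc_mask = detect_invalid_uc(record.uc, config)
    fhr = smooth(interpolate_invalid(record.fhr, fhr_mask), config)
    uc = smooth(interpolate_invalid(record.uc, uc_mask), config)
    return record.with_signals(fhr, uc), {"fhr": fhr_mask, "uc": uc_mask}
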