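"""Core record types shared across the package."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

__all__ = ["MaternalMetadata", "CTGRecord"]

#: numeric metadata field order used everywhere a 4-vector is built
METADATA_FIELDS = ("age", "gravidity", "parity", "diabetes")


@dataclass
class MaternalMetadata:
    """Structured maternal features; ``None`` marks a missing value."""

    age: Optional[float] = None
    gravidity: Optional[float] = None
    parity: Optional[float] = None
    diabetes: Optional[int] = None

    def __post_init__(self):
        if self.diabetes is not None and self.diabetes not in (0, 1):
            raise ValueError(f"diabetes must be 0/1 or missing, got {self.diabetes}")
        for name in ("gravidity", "parity"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in METADATA_FIELDS}

    @classmethod
    def from_dict(cls, d: dict) -> "MaternalMetadata":
        return cls(**{k: d.get(k) for k in METADATA_FIELDS})


@dataclass
class CTGRecord:
    """One 4 Hz cardiotocography segment: aligned FHR/UC channels plus
    maternal metadata, the binary outcome label, and provenance."""

    record_id: str
    fhr: np.ndarray
    uc: np.ndarray
    metadata: MaternalMetadata
    label: int
    sample_rate: float = 4.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.fhr = np.asarray(self.fhr, dtype=float)
        self.uc = np.asarray(self.uc, dtype=float)
        if self.fhr.shape != self.uc.shape or self.fhr.ndim != 1:
            raise ValueError("fhr and uc must be 1-D arrays of identical length")
        if self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.fhr.size

    def with_signals(self, fhr: np.ndarray, uc: np.ndarray) -> "CTGRecord":
        return replace(self, fhr=np.asarray(fhr, float), uc=np.asarray(uc, float))
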