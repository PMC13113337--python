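"""Gramian-angular-field imaging of FHR series.

Pipeline: min-max rescale into [a, b] ⊆ [−1, 1], arccos polar mapping, the
pairwise angular Gramian G[i, j] = cos(φ_i − φ_j) (the printed form; the
antisymmetric sin variant is available via ``variant="sin"``), and bilinear
resizing to a square image.  A fast path piecewise-aggregates the series down
to the output size first so no L×L matrix is ever materialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = ["GADFConfig", "GADFImage", "rescale", "to_polar", "gadf_matrix",
           "render", "fhr_to_gadf", "paa"]


@dataclass
class GADFConfig:
    range_low: float = -1.0
    range_high: float = 1.0
    out_size: int = 224
    fast_path: bool = False
    variant: str = "cos"  # "cos" (as printed) or "sin" (classical difference field)

    def __post_init__(self):
        if not (-1.0 <= self.range_low < self.range_high <= 1.0):
            raise ValueError("require -1 <= range_low < range_high <= 1")
        if self.out_size < 2:
            raise ValueError("out_size must be >= 2")
        if self.variant not in ("cos", "sin"):
            raise ValueError("variant must be 'cos' or 'sin'")


@dataclass
class GADFImage:
    pixels: np.ndarray
    source_length: int

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float32)
        if self.pixels.ndim != 2 or self.pixels.shape[0] != self.pixels.shape[1]:
            raise ValueError("pixels must be a square matrix")

    @property
    def size(self) -> int:
        return self.pixels.shape[0]

    def to_uint8(self) -> np.ndarray:
        """Affine [−1,1] → [0,255] export for visual inspection only."""
        return np.clip((self.pixels + 1.0) * 127.5, 0, 255).astype(np.uint8)


def rescale(x: np.ndarray, config: GADFConfig | None = None) -> np.ndarray:
    """Min-max rescale into [a, b]; a constant series maps to the midpoint."""
    config = config or GADFConfig()
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sequence")
    a, b = config.range_low, config.range_high
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.full(x.shape, (a + b) / 2.0)
    return a + (b - a) * (x - lo) / (hi - lo)


def to_polar(x_tilde: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """arccos mapping to angles in [0, π]; tiny numeric overshoot is clamped,
    anything beyond `tol` outside [−1, 1] raises."""
    x_tilde = np.asarray(x_tilde, dtype=float)
    if np.any(x_tilde > 1.0 + tol) or np.any(x_tilde < -1.0 - tol):
        raise ValueError("values outside [-1, 1] cannot be mapped to angles")
    return np.arccos(np.clip(x_tilde, -1.0, 1.0))


def gadf_matrix(phi: np.ndarray, variant: str = "cos") -> np.ndarray:
    """Pairwise angular field G[i, j] = cos(φ_i − φ_j) (or sin for the
    classical variant).  Computed via outer products in float32 so the
    full-length path stays within memory."""
    phi = np.asarray(phi, dtype=np.float32)
    if phi.size == 0:
        raise ValueError("empty angle sequence")
    c, s = np.cos(phi), np.sin(phi)
    if variant == "cos":
        # cos(a−b) = cos a cos b + sin a sin b
        g = np.outer(c, c)
        g += np.outer(s, s)
    elif variant == "sin":
        # sin(a−b) = sin a cos b − cos a sin b
        g = np.outer(s, c)
        g -= np.outer(c, s)
    else:
        raise ValueError("variant must be 'cos' or 'sin'")
    return np.clip(g, -1.0, 1.0)


def render(g: np.ndarray, config: GADFConfig | None = None) -> GADFImage:
    """Bilinear resize of the Gramian to out_size × out_size."""
    config = config or GADFConfig()
    g = np.asarray(g, dtype=np.float32)
    if g.ndim != 2 or g.shape[0] != g.shape[1]:
        raise ValueError("input must be a square matrix")
    n = config.out_size
    if g.shape == (n, n):
        pixels = g.copy()
    else:
        img = Image.fromarray(g, mode="F")
        pixels = np.asarray(img.resize((n, n), resample=Image.BILINEAR),
                            dtype=np.float32)
    lo, hi = float(g.min()), float(g.max())
    return GADFImage(np.clip(pixels, lo, hi), source_length=g.shape[0])


def paa(x: np.ndarray, n_bins: int) -> np.ndarray:
    """Piecewise-aggregate approximation: mean over n_bins near-equal bins."""
    x = np.asarray(x, dtype=float)
    if x.size <= n_bins:
        return x.copy()
    edges = np.linspace(0, x.size, n_bins + 1).astype(int)
    return np.array([x[lo:hi].mean() for lo, hi in zip(edges[:-1], edges[1:])])


def fhr_to_gadf(fhr: np.ndarray, config: GADFConfig | None = None) -> GADFImage:
    """rescale → polar → Gramian → resize.

    With ``fast_path`` the rescaled series is piecewise-aggregated down to
    out_size points first and the resize is skipped (approximate for large L).
    """
    config = config or GADFConfig()
    fhr = np.asarray(fhr, dtype=float)
    if not np.all(np.isfinite(fhr)):
        raise ValueError("fhr must be preprocessed (finite) before imaging")
    L = fhr.size
    scaled = rescale(fhr, config)
    if config.fast_path:
        scaled = np.clip(paa(scaled, config.out_size),
                         config.range_low, config.range_high)
        g = gadf_matrix(to_polar(scaled), config.variant)
        img = render(g, config)
    else:
        g = gadf_matrix(to_polar(scaled), config.variant)
        img = render(g, config)
    return GADFImage(img.pixels, source_length=L)
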