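"""Multifractal alpha images and alpha-histogram texture features.

The local regularity of the intensity surface around a pixel ``p`` is
summarized by its Hölder exponent α_p: a local measure µ_w(p), evaluated
over square windows of growing odd width w, is assumed to scale as

    µ_w(p) = C · w^{α_p}

so α_p is the slope of an ordinary least-squares fit of log µ_w against
log w.  Four classical local measures are provided:

* ``maximum``          µ_w(p) = max of the window,
* ``inverse_minimum``  µ_w(p) = 1 − min of the window,
* ``summation``        µ_w(p) = sum of the window,
* ``iso``              µ_w(p) = number of window pixels whose intensity is
  within a tolerance τ of the center pixel.

Intensities are min-max normalized to [0, 1] first; the non-linearity of
the logarithm then amplifies subtle structure.  Replacing each intensity
by α_p yields the alpha image, and the proportion-normalized histogram of
alpha values over the breast region (100 bins spanning the per-image
[α_min, α_max] range) is the multifractal texture descriptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InvalidConfigError, InvalidInputError
from .io_preprocess import GrayImage, normalize_intensity

MEASURES = ("maximum", "inverse_minimum", "summation", "iso")

#: Floor applied to normalized intensities and to measure values before
#: logarithms, so that alpha is finite everywhere (the inverse-minimum
#: measure can reach exactly 0, and a constant image normalizes to zeros).
LOG_FLOOR = 1e-12


@dataclass(frozen=True)
class MultifractalConfig:
    """Configuration of the alpha-image computation."""

    measure: str = "iso"
    window_sizes: tuple[int, ...] = (1, 3, 5)
    iso_tolerance: float = 1.0 / 255.0  # 8-bit-equivalent equality
    log_floor: float = LOG_FLOOR
    n_bins: int = 100

    def __post_init__(self) -> None:
        if self.measure not in MEASURES:
            raise InvalidConfigError(f"unknown measure {self.measure!r}")
        ws = self.window_sizes
        if len(ws) < 2:
            raise InvalidConfigError("at least two window sizes required")
        if any(w < 1 or w % 2 == 0 for w in ws):
            raise InvalidConfigError("window sizes must be odd and >= 1")
        if list(ws) != sorted(set(ws)):
            raise InvalidConfigError("window sizes must be strictly increasing")
        if self.iso_tolerance < 0:
            raise InvalidConfigError("iso tolerance must be non-negative")
        if self.log_floor <= 0:
            raise InvalidConfigError("log floor must be positive")
        if self.n_bins < 2:
            raise InvalidConfigError("n_bins must be at least 2")


@dataclass
class AlphaImage:
    """Per-pixel Hölder exponents and regression intercepts."""

    alpha: np.ndarray
    intercept: np.ndarray  # log C of the per-pixel fit
    measure: str
    window_sizes: tuple[int, ...]


@dataclass
class AlphaHistogram:
    """Proportion-normalized alpha histogram over the region of interest."""

    heights: np.ndarray
    alpha_range: tuple[float, float]
    roi_pixel_count: int


def compute_measure_map(img: GrayImage | np.ndarray, w: int,
                        cfg: MultifractalConfig) -> np.ndarray:
    """Evaluate µ_w at every pixel over reflect-padded w×w windows.

    ``w = 1`` reduces the window to the pixel itself.  Normalized
    intensities are floored at ``cfg.log_floor`` so every measure stays
    strictly positive (the scaling law is read in log space).
    """
    if w < 1 or w % 2 == 0:
        raise InvalidConfigError(f"window size must be odd and >= 1, got {w}")
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    g = np.maximum(px.astype(np.float64), cfg.log_floor)

    if cfg.measure == "maximum":
        return ndimage.maximum_filter(g, size=w, mode="reflect")
    if cfg.measure == "inverse_minimum":
        return 1.0 - ndimage.minimum_filter(g, size=w, mode="reflect")
    if cfg.measure == "summation":
        kernel = np.ones((w, w))
        return ndimage.convolve(g, kernel, mode="reflect")
    # iso: count window pixels within tolerance of the center (center included)
    half = w // 2
    padded = np.pad(g, half, mode="symmetric")
    counts = np.zeros_like(g)
    for dr in range(w):
        for dc in range(w):
            shifted = padded[dr:dr + g.shape[0], dc:dc + g.shape[1]]
            counts += np.abs(shifted - g) <= cfg.iso_tolerance
    return counts


def estimate_alpha(measure_maps: dict[int, np.ndarray],
                   window_sizes: tuple[int, ...] | None = None,
                   log_floor: float = LOG_FLOOR) -> AlphaImage:
    """Per-pixel OLS slope of log µ_w versus log w.

    ``measure_maps`` maps window size → µ_w array.  Measure values are
    floored at ``log_floor`` before taking logarithms.
    """
    ws = tuple(sorted(measure_maps)) if window_sizes is None else tuple(window_sizes)
    if len(ws) < 2:
        raise InvalidConfigError("alpha estimation needs at least two windows")
    x = np.log(np.asarray(ws, dtype=np.float64))
    y = np.stack([np.log(np.maximum(measure_maps[w], log_floor)) for w in ws])
    x_mean = x.mean()
    y_mean = y.mean(axis=0)
    x_dev = x - x_mean
    slope = np.tensordot(x_dev, y, axes=(0, 0)) / (x_dev**2).sum()
    intercept = y_mean - slope * x_mean
    return AlphaImage(alpha=slope, intercept=intercept, measure="",
                      window_sizes=ws)


def alpha_image(img: GrayImage, cfg: MultifractalConfig,
                mask: np.ndarray | None = None) -> AlphaImage:
    """Normalize, evaluate µ_w for every window size, and fit α per pixel.

    Alpha is computed over the full image; the region-of-interest mask
    only restricts the histogram (see :func:`alpha_histogram`), so ``mask``
    is accepted for interface symmetry but not needed here.
    """
    if mask is not None and mask.shape != img.shape:
        raise InvalidInputError("mask and image shapes differ")
    norm = normalize_intensity(img)
    maps = {w: compute_measure_map(norm, w, cfg) for w in cfg.window_sizes}
    ai = estimate_alpha(maps, cfg.window_sizes, cfg.log_floor)
    ai.measure = cfg.measure
    return ai


def alpha_histogram(ai: AlphaImage, mask: np.ndarray,
                    n_bins: int = 100) -> AlphaHistogram:
    """100-bin proportion histogram of α over the region of interest.

    The bin range is the per-image [α_min, α_max] over ROI pixels; the
    last bin is right-closed.  Heights are proportions of ROI pixels so
    that breasts of different areas yield comparable features.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise InvalidInputError("empty region-of-interest mask")
    values = ai.alpha[mask]
    lo, hi = float(values.min()), float(values.max())
    if lo == hi:
        heights = np.zeros(n_bins)
        heights[0] = 1.0
    else:
        counts, _ = np.histogram(values, bins=n_bins, range=(lo, hi))
        heights = counts / values.size
    return AlphaHistogram(heights=heights, alpha_range=(lo, hi),
                          roi_pixel_count=int(values.size))


def multifractal_descriptor(img: GrayImage, mask: np.ndarray,
                            cfg: MultifractalConfig) -> np.ndarray:
    """Alpha-histogram feature vector (length ``cfg.n_bins``) for one image."""
    ai = alpha_image(img, cfg)
    return alpha_histogram(ai, mask, cfg.n_bins).heights
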