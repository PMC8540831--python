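"""Synthetic mammogram phantoms and calibration textures.

Every downstream stage of the package (segmentation, multifractal alpha
images, LBP descriptors, classification) can be exercised on phantoms
generated here, without access to any clinical dataset.

A phantom emulates the gross appearance of a digitized mammogram:

* near-zero background,
* a half-elliptical "breast" of fatty tissue against the left edge
  (chest-wall-left orientation),
* for MLO views, a bright pectoral-muscle triangle in the upper chest-wall
  corner,
* Gaussian "dense tissue" blobs added inside the breast until the fraction
  of dense pixels falls inside the BI-RADS band of the requested class
  (I: 0-25%, II: 26-50%, III: 51-75%, IV: >75% dense tissue),
* a faint smooth fibrous texture field and additive Gaussian noise.

Images are written as 16-bit PNGs to mirror the dynamic range of full-field
digital mammography detectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import InvalidSpecError

BIRADS_CLASSES = ("I", "II", "III", "IV")

#: Dense-fraction band per BI-RADS class, on the unit scale.  Lower edge is
#: exclusive except for class I (a breast with no dense pixels is class I).
DENSITY_BANDS: dict[str, tuple[float, float]] = {
    "I": (0.0, 0.25),
    "II": (0.25, 0.50),
    "III": (0.50, 0.75),
    "IV": (0.75, 1.0),
}

#: A pixel counts as "dense" when its noise-free normalized intensity
#: exceeds this constant.  Density is an area proportion, so the threshold
#: is a fixed property of the generator, not of any analysis step.
DENSE_THRESHOLD = 0.60

# Noise-free intensity levels (unit scale, quantized to 16 bits on output).
_BACKGROUND_LEVEL = 0.02
_FAT_LEVEL = 0.35
_PECTORAL_LEVEL = 0.85
_BLOB_AMPLITUDE = 0.45
_FIBROUS_AMPLITUDE = 0.04


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of one synthetic mammogram.

    ``blob_count`` caps the number of dense blobs the generator may place
    while driving the dense-pixel fraction into the class band.
    """

    class_label: str = "I"
    image_size: tuple[int, int] = (256, 256)
    view: str = "MLO"
    blob_count: int = 3000
    blob_scale: float = 7.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_label not in BIRADS_CLASSES:
            raise InvalidSpecError(f"unknown BI-RADS class {self.class_label!r}")
        if self.view not in ("MLO", "CC"):
            raise InvalidSpecError(f"view must be MLO or CC, got {self.view!r}")
        h, w = self.image_size
        if h < 64 or w < 64:
            raise InvalidSpecError("image_size must be at least 64x64")
        if self.blob_count < 1:
            raise InvalidSpecError("blob_count must be positive")
        if self.blob_scale <= 0:
            raise InvalidSpecError("blob_scale must be positive")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")

    @property
    def dense_fraction_band(self) -> tuple[float, float]:
        return DENSITY_BANDS[self.class_label]


@dataclass
class SyntheticSample:
    """A phantom image with its ground-truth masks and label."""

    image: np.ndarray  # uint16, (H, W)
    breast_mask: np.ndarray  # bool, dense-tissue carrier, excludes pectoral
    pectoral_mask: np.ndarray  # bool, empty for CC views
    label: str
    realized_dense_fraction: float
    spec: PhantomSpec


def _breast_geometry(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray]:
    """Half-ellipse breast and (for MLO) pectoral triangle, chest wall left."""
    h, w = spec.image_size
    rr, cc = np.mgrid[0:h, 0:w]
    cy, ar, ac = 0.55 * h, 0.38 * h, 0.55 * w
    ellipse = ((rr - cy) / ar) ** 2 + (cc / ac) ** 2 <= 1.0

    if spec.view == "MLO":
        # triangle with legs along the top edge (0.35 W) and chest wall (0.45 H)
        pectoral = (rr / (0.45 * h) + cc / (0.35 * w)) <= 1.0
    else:
        pectoral = np.zeros((h, w), dtype=bool)

    breast = ellipse & ~pectoral
    if not breast.any():
        raise InvalidSpecError("image too small to place a breast region")
    return breast, pectoral


def _add_blob(field: np.ndarray, r0: float, c0: float, sigma: float,
              amplitude: float, support: np.ndarray) -> None:
    """Add a Gaussian bump in-place, restricted to ``support`` pixels."""
    h, w = field.shape
    reach = int(np.ceil(4 * sigma))
    r_lo, r_hi = max(0, int(r0) - reach), min(h, int(r0) + reach + 1)
    c_lo, c_hi = max(0, int(c0) - reach), min(w, int(c0) + reach + 1)
    rr, cc = np.mgrid[r_lo:r_hi, c_lo:c_hi]
    bump = amplitude * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2) / (2 * sigma**2))
    field[r_lo:r_hi, c_lo:c_hi] += bump * support[r_lo:r_hi, c_lo:c_hi]


def generate_phantom(spec: PhantomSpec) -> SyntheticSample:
    """Generate one phantom mammogram; deterministic per ``spec.seed``.

    Dense blobs are added one at a time (rejection-sampled centers inside
    the breast, kept clear of the pectoral edge) until the dense-pixel
    fraction reaches a target drawn inside the class band.  Raises
    :class:`InvalidSpecError` if the band is unreachable within
    ``spec.blob_count`` blobs.
    """
    rng = np.random.default_rng(spec.seed)
    breast, pectoral = _breast_geometry(spec)
    h, w = spec.image_size

    clean = np.full((h, w), _BACKGROUND_LEVEL)
    clean[breast] = _FAT_LEVEL
    clean[pectoral] = _PECTORAL_LEVEL

    # faint smooth fibrous texture so even fatty breasts carry structure
    fib = ndimage.gaussian_filter(rng.standard_normal((h, w)), 3.0)
    fib /= max(np.abs(fib).max(), 1e-12)
    clean[breast] += _FIBROUS_AMPLITUDE * fib[breast]

    # keep dense tissue clear of the pectoral boundary (retroglandular fat)
    if pectoral.any():
        gap = ndimage.distance_transform_edt(~pectoral) > 3 * spec.blob_scale
    else:
        gap = np.ones((h, w), dtype=bool)
    allowed = breast & gap
    centers = np.argwhere(allowed)
    if centers.size == 0:
        raise InvalidSpecError("no room for dense tissue inside the breast")

    lo, hi = spec.dense_fraction_band
    width = hi - lo
    target = lo + (0.25 + 0.45 * rng.random()) * width
    n_breast = int(breast.sum())

    def fraction() -> float:
        return float((clean[breast] > DENSE_THRESHOLD).sum()) / n_breast

    blobs = 0
    while fraction() < target:
        if blobs >= spec.blob_count:
            raise InvalidSpecError(
                f"dense band {spec.dense_fraction_band} unreachable within "
                f"{spec.blob_count} blobs"
            )
        r0, c0 = centers[rng.integers(len(centers))]
        sigma = spec.blob_scale * (0.6 + 0.8 * rng.random())
        _add_blob(clean, float(r0), float(c0), sigma, _BLOB_AMPLITUDE, breast)
        blobs += 1

    realized = fraction()
    if not (lo <= realized <= hi):
        raise InvalidSpecError(
            f"realized dense fraction {realized:.3f} overshot band {lo, hi}"
        )

    noisy = clean + rng.normal(0.0, spec.noise_sd, size=clean.shape)
    image = (np.clip(noisy, 0.0, 1.0) * 65535.0).round().astype(np.uint16)

    return SyntheticSample(
        image=image,
        breast_mask=breast,
        pectoral_mask=pectoral,
        label=spec.class_label,
        realized_dense_fraction=realized,
        spec=spec,
    )


def generate_fbm_texture(hurst: float, size: tuple[int, int] | int,
                         seed: int = 0) -> np.ndarray:
    """Fractional-Brownian surface by spectral synthesis, min-max scaled.

    The power spectrum follows ``f^-(2H+2)``; low Hurst exponents give
    rough surfaces with large short-range increments, which makes the
    texture a useful calibration input for Hölder-exponent estimation.
    """
    if not 0.0 < hurst < 1.0:
        raise InvalidSpecError("hurst must lie strictly inside (0, 1)")
    if isinstance(size, int):
        size = (size, size)
    h, w = size
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    radius = np.sqrt(fy**2 + fx**2)
    with np.errstate(divide="ignore"):
        amplitude = np.where(radius > 0, radius ** (-(hurst + 1.0)), 0.0)
    phase = rng.standard_normal((h, w)) + 1j * rng.standard_normal((h, w))
    surface = np.fft.ifft2(phase * amplitude).real
    lo, hi = surface.min(), surface.max()
    if hi == lo:
        return np.zeros_like(surface)
    return (surface - lo) / (hi - lo)


def generate_dataset(
    n_per_class: int,
    base_seed: int = 0,
    spec_defaults: PhantomSpec | None = None,
) -> tuple[list[SyntheticSample], pd.DataFrame]:
    """Generate ``4 * n_per_class`` phantoms with a per-sample manifest.

    Seeds are derived deterministically from ``base_seed`` so the full
    dataset is reproducible from a single integer.
    """
    if n_per_class < 1:
        raise InvalidSpecError("n_per_class must be at least 1")
    defaults = spec_defaults or PhantomSpec()
    samples: list[SyntheticSample] = []
    rows = []
    for ci, label in enumerate(BIRADS_CLASSES):
        for j in range(n_per_class):
            seed = (base_seed * 100003 + ci * 1009 + j) % (2**31 - 1)
            spec = replace(defaults, class_label=label, seed=seed)
            sample = generate_phantom(spec)
            samples.append(sample)
            rows.append(
                {
                    "file": f"phantom_{label}_{j:03d}.png",
                    "mask": f"phantom_{label}_{j:03d}_mask.png",
                    "label": label,
                    "dense_fraction": sample.realized_dense_fraction,
                    "seed": seed,
                }
            )
    return samples, pd.DataFrame(rows)


def save_dataset(samples: list[SyntheticSample], manifest: pd.DataFrame,
                 out_dir: str | Path) -> Path:
    """Write 16-bit image PNGs, 8-bit mask PNGs, and the CSV manifest."""
    from .io_preprocess import write_png

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sample, row in zip(samples, manifest.itertuples()):
        write_png(sample.image, out / row.file)
        mask = (sample.breast_mask | sample.pectoral_mask).astype(np.uint8) * 255
        write_png(mask, out / row.mask)
    manifest_path = out / "manifest.csv"
    manifest.to_csv(manifest_path, index=False)
    return manifest_path
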