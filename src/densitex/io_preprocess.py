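"""Image I/O and breast-region pre-processing.

Pipeline: read → 3×3 median filter → intensity normalization → breast
segmentation (thresholding + morphology) → pectoral-muscle removal for MLO
views (2-cluster intensity K-means + quadratic boundary fit).  The result
is a binary region-of-interest mask covering the breast tissue only, which
downstream texture descriptors use to restrict their histograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage import morphology
from skimage.filters import threshold_multiotsu, threshold_otsu
from sklearn.cluster import KMeans

from .errors import FormatError, InvalidInputError, SegmentationError


@dataclass
class GrayImage:
    """A 2-D grayscale intensity grid with acquisition metadata."""

    pixels: np.ndarray
    bit_depth: int = 16
    view: str = "unknown"  # MLO | CC | unknown
    laterality: str = "unknown"  # L | R | unknown

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise FormatError("grayscale 2-D image required")
        if not np.all(np.isfinite(self.pixels)) or self.pixels.min() < 0:
            raise InvalidInputError("intensities must be finite and non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


_PIL_DEPTH = {"L": 8, "I;16": 16, "I": 32, "F": 32}


def read_image(path: str | Path) -> GrayImage:
    """Read a DICOM, PNG, or TIFF grayscale image losslessly.

    View and laterality are taken from DICOM tags when present; color
    images are rejected because the texture measures are defined on a
    single intensity channel.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    suffix = path.suffix.lower()
    if suffix in (".dcm", ".dicom"):
        import pydicom

        try:
            ds = pydicom.dcmread(path)
            pixels = ds.pixel_array
        except Exception as exc:  # pragma: no cover - malformed DICOM
            raise FormatError(f"unreadable DICOM: {path}") from exc
        if pixels.ndim != 2:
            raise FormatError("color/multi-frame DICOM not supported")
        return GrayImage(
            pixels=pixels,
            bit_depth=int(getattr(ds, "BitsStored", 16)),
            view=str(getattr(ds, "ViewPosition", "unknown") or "unknown"),
            laterality=str(getattr(ds, "ImageLaterality", "unknown") or "unknown"),
        )
    if suffix in (".png", ".tif", ".tiff"):
        try:
            with Image.open(path) as im:
                mode = im.mode
                if mode not in _PIL_DEPTH:
                    raise FormatError(f"color image not supported (mode {mode})")
                pixels = np.asarray(im)
        except FormatError:
            raise
        except Exception as exc:
            raise FormatError(f"unreadable image: {path}") from exc
        return GrayImage(pixels=pixels, bit_depth=_PIL_DEPTH[mode])
    raise FormatError(f"unsupported format: {path.suffix}")


def write_png(pixels: np.ndarray, path: str | Path) -> None:
    """Write a uint8 or uint16 array as a PNG (lossless)."""
    pixels = np.asarray(pixels)
    if pixels.dtype in (np.uint16, np.uint8):
        im = Image.fromarray(pixels)  # infers I;16 / L
    else:
        raise FormatError(f"write_png expects uint8/uint16, got {pixels.dtype}")
    im.save(Path(path))


def normalize_intensity(img: GrayImage) -> GrayImage:
    """Min-max rescale intensities to [0, 1]; a constant image maps to zeros."""
    px = img.pixels.astype(np.float64)
    lo, hi = px.min(), px.max()
    if hi == lo:
        out = np.zeros_like(px)
    else:
        out = (px - lo) / (hi - lo)
    return GrayImage(out, bit_depth=img.bit_depth, view=img.view,
                     laterality=img.laterality)


def median_filter3(img: GrayImage) -> GrayImage:
    """3×3 median filter with reflect (edge-inclusive) padding."""
    out = ndimage.median_filter(img.pixels.astype(np.float64), size=3,
                                mode="reflect")
    return GrayImage(out, bit_depth=img.bit_depth, view=img.view,
                     laterality=img.laterality)


def _largest_component(binary: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(binary)  # default structure = 4-connectivity
    if n == 0:
        raise SegmentationError("no foreground component found")
    sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
    return labels == (1 + int(np.argmax(sizes)))


def segment_breast(img: GrayImage) -> np.ndarray:
    """Segment the breast (plus pectoral, for MLO) from the background.

    Otsu-family thresholding on intensity, morphological opening, hole
    filling, then the largest 4-connected component.  A 3-class multi-Otsu
    threshold is tried first and its lowest cut used, so that a bright
    dense-tissue mode does not pull the background/tissue boundary upward;
    plain Otsu is the fallback.  When thresholding on raw intensity
    degenerates (constant image or empty foreground), the inverse-minimum
    alpha image — which enhances the background/tissue transition — is
    thresholded instead.  Returns a boolean mask.
    """
    px = img.pixels.astype(np.float64)

    def otsu_foreground(values: np.ndarray) -> np.ndarray | None:
        if values.min() == values.max():
            return None
        try:
            t = threshold_multiotsu(values, classes=3)[0]
        except ValueError:  # too few distinct values for 3 classes
            t = threshold_otsu(values)
        fg = values > t
        if not fg.any() or fg.all():
            fg = values > threshold_otsu(values)
        return fg if fg.any() and not fg.all() else None

    binary = otsu_foreground(px)
    if binary is None:
        from .multifractal import MultifractalConfig, alpha_image

        cfg = MultifractalConfig(measure="inverse_minimum")
        alpha = alpha_image(img, cfg).alpha
        binary = otsu_foreground(alpha)
        if binary is None:
            raise SegmentationError("image has no separable foreground")

    radius = max(1, round(5 * img.shape[1] / 512))
    binary = ndimage.binary_opening(binary, structure=morphology.disk(radius))
    binary = ndimage.binary_fill_holes(binary)
    if not binary.any():
        raise SegmentationError("foreground vanished under morphology")
    return _largest_component(binary)


def _needs_flip(mask: np.ndarray) -> bool:
    """Chest wall is taken as the heavier side; True if it is on the right."""
    col_mass = mask.sum(axis=0)
    half = mask.shape[1] // 2
    return col_mass[half:].sum() > col_mass[:half].sum()


def remove_pectoral(img: GrayImage, mask: np.ndarray,
                    view: str | None = None) -> np.ndarray:
    """Remove the pectoral-muscle region from an MLO breast mask.

    The mask intensities are split by 2-cluster K-means; the bright cluster
    component touching the chest-wall upper corner is taken as pectoral,
    its per-row boundary is smoothed with a quadratic fit, and everything
    above/left of the fitted curve is cleared.  CC views are returned
    unchanged.  Never adds pixels; idempotent on its own output.
    """
    if not mask.any():
        raise InvalidInputError("empty mask")
    view = view or img.view
    if view != "MLO":
        return mask.copy()

    flipped = _needs_flip(mask)
    px = img.pixels.astype(np.float64)
    if flipped:
        px, mask = px[:, ::-1], mask[:, ::-1]

    values = px[mask].reshape(-1, 1)
    km = KMeans(n_clusters=2, n_init=4, random_state=0).fit(values)
    bright = int(np.argmax(km.cluster_centers_.ravel()))
    bright_mask = np.zeros_like(mask)
    bright_mask[mask] = km.labels_ == bright

    labels, n = ndimage.label(bright_mask)
    h, w = mask.shape
    corner = np.zeros_like(mask)
    corner[: max(1, int(0.15 * h)), : max(1, int(0.15 * w))] = True
    corner_labels = np.unique(labels[corner & (labels > 0)])

    out = mask.copy()
    if corner_labels.size:
        pect = np.isin(labels, corner_labels)
        rows = np.nonzero(pect.any(axis=1))[0]
        boundary = np.array([pect[r].nonzero()[0].max() + 1 for r in rows],
                            dtype=float)
        if rows.size >= 3:
            coeffs = np.polyfit(rows, boundary, deg=2)
            fitted = np.polyval(coeffs, np.arange(rows.max() + 1))
        else:
            fitted = np.zeros(rows.max() + 1)
            fitted[rows] = boundary
        for r, b in enumerate(fitted):
            cut = min(w, int(np.ceil(b)))
            if cut > 0:
                out[r, :cut] = False

    if flipped:
        out = out[:, ::-1]
    return out


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 when both masks are empty."""
    a, b = a.astype(bool), b.astype(bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * (a & b).sum() / denom


def preprocess(img: GrayImage, view: str | None = None
               ) -> tuple[GrayImage, np.ndarray]:
    """Full pre-processing: median filter, normalize, segment, de-pectoral.

    Returns the normalized image and the final region-of-interest mask.
    """
    norm = normalize_intensity(median_filter3(img))
    mask = segment_breast(norm)
    roi = remove_pectoral(norm, mask, view=view or img.view)
    if not roi.any():
        raise SegmentationError("pectoral removal cleared the whole mask")
    return norm, roi
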