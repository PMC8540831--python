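"""Local binary pattern descriptors: circular, elliptical, multi-resolution.

For a center pixel ``c`` with intensity g_c, P neighbors are sampled at
equal angles on a circle of radius R (or an ellipse with semi-axes R1, R2)
by bilinear interpolation, and the P-bit code

    LBP_{P,R}(c) = Σ_i s(g_i − g_c) · 2^i,   s(x) = 1 if x ≥ 0 else 0

is assigned.  Sampling starts due east (i = 0) and proceeds
counter-clockwise; the border is reflect-padded.  The ROI-restricted,
proportion-normalized histogram of codes (256 bins for P = 8) is the
texture feature.  The multi-resolution descriptor (MLBP) concatenates the
histograms of two radii — {2, 4} by default — into a 512-length vector;
the elliptical variant (ELBP) uses one (R1 = 1, R2 = 4) ellipse with its
semi-major axis along image rows.

Bilinear sampling is done with an explicit vectorized gather on a
symmetric-padded array: codes depend on the *sign* of g_i − g_c, and
quantized inputs can place that difference exactly at zero, so the
arithmetic must be reproducible term-for-term by a per-pixel oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, InvalidInputError
from .io_preprocess import GrayImage

DEFAULT_P = 8
DEFAULT_LBP_RADIUS = 2.0  # circular LBP radius of the experiment of record
DEFAULT_ELBP_AXES = (1.0, 4.0)  # (semi-minor R1, semi-major R2)
DEFAULT_MLBP_RADII = (2.0, 4.0)


@dataclass
class CodeMap:
    """Per-pixel LBP codes in [0, 2^P - 1]."""

    codes: np.ndarray
    P: int
    radii: tuple[float, float]  # (row radius, column radius)


def _as_array(img: GrayImage | np.ndarray) -> np.ndarray:
    px = img.pixels if isinstance(img, GrayImage) else np.asarray(img)
    return px.astype(np.float64)


def bilinear_sample(padded: np.ndarray, rows: np.ndarray,
                    cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at fractional (row, col) positions.

    The exact expression (four corner terms summed in fixed order) is the
    contract shared with the brute-force test oracle.
    """
    r0 = np.floor(rows).astype(np.intp)
    c0 = np.floor(cols).astype(np.intp)
    fr = rows - r0
    fc = cols - c0
    a = padded[r0, c0]
    b = padded[r0, c0 + 1]
    c = padded[r0 + 1, c0]
    d = padded[r0 + 1, c0 + 1]
    # interpolate along columns, then rows; each step is an exact convex
    # pair mix, so four equal corners reproduce their value bit-exactly
    # (the sign of g_i - g_c decides a code bit and must not wobble at ties)
    top = a + fc * (b - a)
    bottom = c + fc * (d - c)
    return top + fr * (bottom - top)


def neighbor_offsets(P: int, r_row: float, r_col: float) -> np.ndarray:
    """(row, col) offsets of the P samples, starting east, counter-clockwise."""
    theta = 2.0 * np.pi * np.arange(P) / P
    return np.stack([-r_row * np.sin(theta), r_col * np.cos(theta)], axis=1)


def _code_map(px: np.ndarray, P: int, r_row: float, r_col: float) -> CodeMap:
    if P < 4:
        raise InvalidConfigError("P must be at least 4")
    if r_row <= 0 or r_col <= 0:
        raise InvalidConfigError("radii must be positive")
    h, w = px.shape
    pad = int(np.ceil(max(r_row, r_col))) + 1
    padded = np.pad(px, pad, mode="symmetric")
    rr, cc = np.mgrid[0:h, 0:w]
    codes = np.zeros((h, w), dtype=np.int64)
    for i, (dr, dc) in enumerate(neighbor_offsets(P, r_row, r_col)):
        sampled = bilinear_sample(padded, rr + pad + dr, cc + pad + dc)
        codes += (sampled - px >= 0).astype(np.int64) << i
    return CodeMap(codes=codes, P=P, radii=(r_row, r_col))


def lbp_code_map(img: GrayImage | np.ndarray, P: int = DEFAULT_P,
                 R: float = DEFAULT_LBP_RADIUS) -> CodeMap:
    """Circular LBP code map with radius R."""
    return _code_map(_as_array(img), P, R, R)


def elbp_code_map(img: GrayImage | np.ndarray, P: int = DEFAULT_P,
                  R1: float = DEFAULT_ELBP_AXES[0],
                  R2: float = DEFAULT_ELBP_AXES[1]) -> CodeMap:
    """Elliptical LBP code map; semi-minor R1, semi-major R2 (along rows)."""
    return _code_map(_as_array(img), P, R2, R1)


def code_histogram(cm: CodeMap, mask: np.ndarray) -> np.ndarray:
    """Proportion-normalized code histogram over the ROI (length 2^P)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != cm.codes.shape:
        raise InvalidInputError("mask and code map shapes differ")
    if not mask.any():
        raise InvalidInputError("empty region-of-interest mask")
    codes = cm.codes[mask]
    counts = np.bincount(codes, minlength=2**cm.P).astype(np.float64)
    return counts / codes.size


def lbp_descriptor(img: GrayImage | np.ndarray, mask: np.ndarray,
                   P: int = DEFAULT_P,
                   R: float = DEFAULT_LBP_RADIUS) -> np.ndarray:
    """Circular-LBP histogram feature vector (256 bins for P = 8)."""
    return code_histogram(lbp_code_map(img, P, R), mask)


def elbp_descriptor(img: GrayImage | np.ndarray, mask: np.ndarray,
                    P: int = DEFAULT_P,
                    R1: float = DEFAULT_ELBP_AXES[0],
                    R2: float = DEFAULT_ELBP_AXES[1]) -> np.ndarray:
    """Elliptical-LBP histogram feature vector."""
    return code_histogram(elbp_code_map(img, P, R1, R2), mask)


def mlbp_descriptor(img: GrayImage | np.ndarray, mask: np.ndarray,
                    radii: tuple[float, ...] = DEFAULT_MLBP_RADII,
                    P: int = DEFAULT_P) -> np.ndarray:
    """Multi-resolution LBP: per-radius histograms concatenated.

    Each half is normalized to sum 1 on its own; with two radii and P = 8
    the descriptor has length 512.
    """
    radii = tuple(radii)
    if len(radii) < 2 or list(radii) != sorted(set(radii)):
        raise InvalidConfigError("radii must be strictly increasing, >= 2 of them")
    parts = [code_histogram(lbp_code_map(img, P, r), mask) for r in radii]
    return np.concatenate(parts)
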