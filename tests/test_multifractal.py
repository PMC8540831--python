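"""Multifractal measures, Hölder-exponent estimation, alpha histograms."""

import numpy as np
import pytest

import densitex as dx
from densitex.multifractal import MEASURES


def brute_force_measure(img, w, cfg):
    """Per-pixel window scan implementing each local measure directly."""
    half = w // 2
    g = np.maximum(np.asarray(img, dtype=float), cfg.log_floor)
    padded = np.pad(g, half, mode="symmetric")
    out = np.empty_like(g)
    for r in range(g.shape[0]):
        for c in range(g.shape[1]):
            window = padded[r:r + w, c:c + w]
            if cfg.measure == "maximum":
                out[r, c] = window.max()
            elif cfg.measure == "inverse_minimum":
                out[r, c] = 1.0 - window.min()
            elif cfg.measure == "summation":
                out[r, c] = window.sum()
            else:
                out[r, c] = (np.abs(window - g[r, c])
                             <= cfg.iso_tolerance).sum()
    return out


def test_measure_closed_forms_on_constant_image():
    const = np.full((9, 9), 0.4)
    cfg = dx.MultifractalConfig(measure="maximum")
    assert np.allclose(dx.compute_measure_map(const, 3, cfg), 0.4)
    cfg = dx.MultifractalConfig(measure="inverse_minimum")
    for w in (1, 3, 5):
        assert np.allclose(dx.compute_measure_map(const, w, cfg), 0.6)
    cfg = dx.MultifractalConfig(measure="iso")
    assert np.allclose(dx.compute_measure_map(const, 5, cfg), 25)
    cfg = dx.MultifractalConfig(measure="summation")
    assert np.allclose(dx.compute_measure_map(const, 3, cfg), 3.6)


@pytest.mark.parametrize("measure", MEASURES)
@pytest.mark.parametrize("w", [1, 3, 5])
def test_measure_maps_match_brute_force(rng, measure, w):
    img = rng.integers(0, 256, size=(9, 9)) / 255.0
    cfg = dx.MultifractalConfig(measure=measure)
    np.testing.assert_allclose(dx.compute_measure_map(img, w, cfg),
                               brute_force_measure(img, w, cfg), atol=1e-9)


def test_even_window_rejected():
    cfg = dx.MultifractalConfig(measure="maximum")
    with pytest.raises(dx.InvalidConfigError):
        dx.compute_measure_map(np.ones((4, 4)), 4, cfg)
    with pytest.raises(dx.InvalidConfigError):
        dx.MultifractalConfig(window_sizes=(1,))


def test_alpha_estimation_exact_cases():
    shape = (4, 4)
    flat = {w: np.full(shape, 2.7) for w in (1, 3, 5)}
    assert np.allclose(dx.estimate_alpha(flat).alpha, 0.0, atol=1e-12)
    square = {1: np.full(shape, 1.0), 3: np.full(shape, 9.0),
              5: np.full(shape, 25.0)}
    assert np.allclose(dx.estimate_alpha(square).alpha, 2.0, atol=1e-12)


def test_alpha_estimation_matches_regression_oracle():
    maps = {1: np.full((2, 2), 2.0), 3: np.full((2, 2), 5.0),
            5: np.full((2, 2), 11.0)}
    ai = dx.estimate_alpha(maps)
    slope, intercept = np.polyfit(np.log([1, 3, 5]),
                                  np.log([2.0, 5.0, 11.0]), 1)
    np.testing.assert_allclose(ai.alpha, slope, atol=1e-12)
    np.testing.assert_allclose(ai.intercept, intercept, atol=1e-12)


@pytest.mark.parametrize("measure,expected", [
    ("maximum", 0.0), ("inverse_minimum", 0.0),
    ("iso", 2.0), ("summation", 2.0),
])
def test_constant_image_alpha_limits(measure, expected):
    img = dx.GrayImage(np.full((16, 16), 500.0))
    ai = dx.alpha_image(img, dx.MultifractalConfig(measure=measure))
    np.testing.assert_allclose(ai.alpha, expected, atol=1e-9)


def test_alpha_separates_fbm_roughness():
    """Mean alpha under the maximum measure orders fBm surfaces by Hurst."""
    cfg = dx.MultifractalConfig(measure="maximum")
    mask = np.ones((64, 64), dtype=bool)
    diffs = []
    for seed in range(10):
        rough = dx.alpha_image(dx.GrayImage(
            dx.generate_fbm_texture(0.2, 64, seed)), cfg).alpha.mean()
        smooth = dx.alpha_image(dx.GrayImage(
            dx.generate_fbm_texture(0.8, 64, seed)), cfg).alpha.mean()
        diffs.append(rough - smooth)
    signs = np.sign(diffs)
    assert (signs == signs[0]).all() and signs[0] != 0


def test_alpha_histogram_contracts(rng):
    const = dx.AlphaImage(alpha=np.full((8, 8), 1.5),
                          intercept=np.zeros((8, 8)),
                          measure="iso", window_sizes=(1, 3, 5))
    mask = np.ones((8, 8), dtype=bool)
    hist = dx.alpha_histogram(const, mask, n_bins=100)
    assert hist.heights[0] == 1.0 and hist.heights[1:].sum() == 0.0

    random_ai = dx.AlphaImage(alpha=rng.normal(size=(20, 20)),
                              intercept=np.zeros((20, 20)),
                              measure="iso", window_sizes=(1, 3, 5))
    mask = rng.random((20, 20)) > 0.4
    hist = dx.alpha_histogram(random_ai, mask, n_bins=100)
    assert hist.heights.sum() == pytest.approx(1.0, abs=1e-9)
    assert (hist.heights >= 0).all()
    with pytest.raises(dx.InvalidInputError):
        dx.alpha_histogram(random_ai, np.zeros((20, 20), dtype=bool))


def test_alpha_histogram_matches_counting_oracle():
    """Linear alpha ramp over a rectangular ROI, counted bin by bin."""
    alpha = np.tile(np.linspace(0.0, 3.0, 24), (10, 1))
    ai = dx.AlphaImage(alpha=alpha, intercept=np.zeros_like(alpha),
                       measure="iso", window_sizes=(1, 3, 5))
    mask = np.zeros_like(alpha, dtype=bool)
    mask[2:8, 4:20] = True
    n_bins = 10
    hist = dx.alpha_histogram(ai, mask, n_bins=n_bins)
    values = alpha[mask]
    lo, hi = values.min(), values.max()
    edges = np.linspace(lo, hi, n_bins + 1)
    oracle = np.zeros(n_bins)
    for v in values:
        b = min(int((v - lo) / (hi - lo) * n_bins), n_bins - 1)
        # replicate half-open bins with a right-closed last bin
        while b > 0 and v < edges[b]:
            b -= 1
        oracle[b] += 1
    oracle /= values.size
    np.testing.assert_allclose(hist.heights, oracle, atol=1e-12)


def test_histogram_locality_outside_max_window():
    """Edits farther than max(w)/2 from the ROI leave the histogram alone."""
    rng = np.random.default_rng(7)
    base = rng.random((24, 24))
    # keep global min/max pinned so normalization is unaffected by the edit
    base[0, 0], base[0, 1] = 0.0, 1.0
    mask = np.zeros((24, 24), dtype=bool)
    mask[10:14, 10:14] = True
    cfg = dx.MultifractalConfig(measure="iso")
    h0 = dx.alpha_histogram(dx.alpha_image(dx.GrayImage(base), cfg), mask)
    edited = base.copy()
    edited[22, 22] = 0.5  # distance from ROI far exceeds max(w)//2 = 2
    h1 = dx.alpha_histogram(dx.alpha_image(dx.GrayImage(edited), cfg), mask)
    np.testing.assert_array_equal(h0.heights, h1.heights)
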