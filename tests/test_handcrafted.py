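"""Handcrafted feature families and the KNN/SVM baseline score tables."""

import numpy as np
import pytest
from skimage.color import rgb2hsv

from otolookup import (
    HandcraftedConfig,
    HandcraftedScaler,
    baseline_score_table,
    color_autocorrelogram,
    color_moments,
    compose_f1,
    compose_f1_matrix,
    gabor_features,
    hsv_histogram,
    retrieve,
)
from otolookup.handcrafted import gabor_bank, gabor_frequencies, quantize_colors
from otolookup.images import LabeledImage

from conftest import random_image


def _const_image(rgb, size=(16, 16)):
    return np.full((*size, 3), 0, np.uint8) + np.array(rgb, np.uint8)


# -- HSV histogram ------------------------------------------------------------


def test_hsv_histogram_constant_image_single_bin():
    h = hsv_histogram(_const_image((200, 40, 40)), bins=(8, 2, 2))
    assert h.shape == (32,)
    assert np.count_nonzero(h) == 1
    assert h.max() == 1.0


def test_hsv_histogram_sums_to_one():
    img = random_image(np.random.default_rng(0), size=(24, 24))
    h = hsv_histogram(img, bins=(8, 2, 2))
    assert h.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.all(h >= 0)


def test_hsv_histogram_two_color_image_half_masses():
    """4x4 image, half pure red / half pure green: two bins of mass 0.5."""
    px = np.zeros((4, 4, 3), np.uint8)
    px[:2, :, 0] = 255  # red
    px[2:, :, 1] = 255  # green
    bins = (8, 2, 2)
    h = hsv_histogram(px, bins=bins)
    # oracle: locate each color's joint bin via the same color conversion
    edges = [np.linspace(0, 1, b + 1) for b in bins]

    def bin_of(rgb):
        hsv = rgb2hsv(np.array(rgb, np.uint8).reshape(1, 1, 3))[0, 0]
        idx = [min(np.searchsorted(e, v, "right") - 1, b - 1)
               for e, v, b in zip(edges, hsv, bins)]
        return np.ravel_multi_index(idx, bins)

    expected = np.zeros(32)
    expected[bin_of((255, 0, 0))] += 0.5
    expected[bin_of((0, 255, 0))] += 0.5
    assert np.allclose(h, expected)


# -- color autocorrelogram ----------------------------------------------------


def brute_force_correlogram(pixels, distances, levels):
    """All-pairs neighbor counting, O(N * d): the independent oracle."""
    q = quantize_colors(pixels, levels)
    h, w = q.shape
    out = np.zeros((levels, len(distances)))
    for di, d in enumerate(distances):
        same = np.zeros(levels)
        total = np.zeros(levels)
        for y in range(h):
            for x in range(w):
                c = q[y, x]
                for dy in range(-d, d + 1):
                    for dx in range(-d, d + 1):
                        if max(abs(dy), abs(dx)) != d:
                            continue
                        yy, xx = y + dy, x + dx
                        if 0 <= yy < h and 0 <= xx < w:
                            total[c] += 1
                            if q[yy, xx] == c:
                                same[c] += 1
        nz = total > 0
        out[nz, di] = same[nz] / total[nz]
    return out.ravel()


def test_correlogram_uniform_image_is_one_everywhere_it_occurs():
    img = _const_image((100, 100, 100), size=(12, 12))
    v = color_autocorrelogram(img, distances=(1, 3, 5), levels=8)
    c = quantize_colors(img, 8)[0, 0]
    v = v.reshape(8, 3)
    assert np.all(v[c] == 1.0)
    other = np.delete(v, c, axis=0)
    assert np.all(other == 0.0)


def test_correlogram_checkerboard_distance_one_closed_form():
    """1-pixel checkerboard at chessboard distance 1.

    Under the L-infinity ring, the 4 diagonal neighbors share the pixel's
    color while the 4 axis neighbors differ.  On an 8x8 board, counting
    boundary truncation by hand: 98 same-color pairs out of 210 neighbor
    pairs per color = 7/15.
    """
    px = np.zeros((8, 8, 3), np.uint8)
    px[(np.indices((8, 8)).sum(axis=0) % 2) == 1] = 255
    v = color_autocorrelogram(px, distances=(1,), levels=8).reshape(8, 1)
    occupied = np.unique(quantize_colors(px, 8))
    assert len(occupied) == 2
    assert np.allclose(v[occupied], 7 / 15)
    unoccupied = np.setdiff1d(np.arange(8), occupied)
    assert np.all(v[unoccupied] == 0.0)


def test_correlogram_isolated_pixels_have_zero_autocorrelation():
    """A color whose pixels are farther apart than d never self-co-occurs."""
    px = np.zeros((9, 9, 3), np.uint8)
    px[::4, ::4] = 255  # bright pixels spaced 4 apart
    v = color_autocorrelogram(px, distances=(1, 2, 3), levels=8).reshape(8, 3)
    bright = int(quantize_colors(px, 8)[0, 0])
    assert np.all(v[bright] == 0.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_correlogram_matches_brute_force_on_random_images(seed):
    rng = np.random.default_rng(seed)
    px = rng.integers(0, 256, size=(8, 8, 3), dtype=np.uint8)
    fast = color_autocorrelogram(px, distances=(1, 2, 3), levels=8)
    slow = brute_force_correlogram(px, (1, 2, 3), 8)
    assert np.array_equal(fast, slow)
    assert np.all((0.0 <= fast) & (fast <= 1.0))


def test_correlogram_levels_must_be_cube():
    img = _const_image((1, 2, 3))
    with pytest.raises(ValueError):
        color_autocorrelogram(img, distances=(1,), levels=10)


# -- color moments ------------------------------------------------------------


def test_color_moments_closed_forms():
    m = color_moments(_const_image((10, 20, 30)))
    assert np.array_equal(m, [10, 0, 20, 0, 30, 0])
    two = np.zeros((1, 2, 3), np.uint8)
    two[0, 1] = 2
    img = LabeledImage(np.tile(two, (8, 4, 1)), "normal", "two")
    m = color_moments(img)
    assert np.allclose(m, [1, 1, 1, 1, 1, 1])  # mean 1, population std 1


def test_color_moments_match_direct_computation():
    rng = np.random.default_rng(3)
    px = rng.integers(0, 256, size=(9, 7, 3), dtype=np.uint8)
    m = color_moments(px)
    for ch in range(3):
        vals = px[:, :, ch].astype(float).ravel()
        assert m[2 * ch] == pytest.approx(vals.mean())
        assert m[2 * ch + 1] == pytest.approx(vals.std())  # population std


# -- Gabor features -----------------------------------------------------------


def test_gabor_constant_image_zero_response():
    v = gabor_features(_const_image((80, 80, 80), size=(48, 48)), scales=2, orientations=3)
    means = v[0::2]
    assert np.all(means < 1e-6)


def test_gabor_vector_length_contract():
    img = random_image(np.random.default_rng(4), size=(48, 48))
    assert gabor_features(img, 2, 3).shape == (12,)
    assert gabor_features(img, 3, 4).shape == (24,)


def test_gabor_grating_peaks_at_matching_kernel():
    """A sinusoidal grating at a bank frequency/orientation maximizes that kernel."""
    scales, orients = 3, 4
    freqs = gabor_frequencies(scales)
    target_s, target_o = 1, 0  # horizontal-axis grating at freqs[1]
    f = freqs[target_s]
    x = np.arange(64)
    grating = 0.5 + 0.5 * np.cos(2 * np.pi * f * x)[None, :] * np.ones((64, 1))
    px = np.clip(np.round(grating * 255), 0, 255).astype(np.uint8)
    px = np.stack([px] * 3, axis=-1)
    v = gabor_features(px, scales, orients)
    energies = v[0::2]  # mean response magnitude per kernel
    assert int(np.argmax(energies)) == target_s * orients + target_o


def test_gabor_kernel_larger_than_image_raises():
    img = random_image(np.random.default_rng(5), size=(8, 8))
    with pytest.raises(ValueError, match="larger than image"):
        gabor_features(img, 4, 6)


def test_gabor_kernels_are_dc_corrected():
    for k in gabor_bank(3, 2):
        assert abs(k.mean()) < 1e-12


# -- compose_f1 ---------------------------------------------------------------


def test_compose_f1_layout_and_length():
    config = HandcraftedConfig(
        hsv_bins=(4, 2, 2), correlogram_distances=(1, 3), correlogram_levels=8,
        gabor_scales=2, gabor_orientations=3,
    )
    img = random_image(np.random.default_rng(6), size=(48, 48))
    vec = compose_f1(img, config)
    expected_len = 16 + 8 * 2 + 6 + 2 * 2 * 3
    assert config.total_length == expected_len
    assert vec.values.shape == (expected_len,)
    # segments are contiguous, non-overlapping, in the stated order, covering all
    order = ["hsv_histogram", "autocorrelogram", "color_moments", "gabor"]
    pos = 0
    for name in order:
        a, b = vec.segments[name]
        assert a == pos and b > a
        pos = b
    assert pos == expected_len
    # pure function of pixels: identical on a second call
    vec2 = compose_f1(img, config)
    assert np.array_equal(vec.values, vec2.values)


def test_scaler_zscores_training_matrix():
    rng = np.random.default_rng(7)
    m = rng.normal(5, 3, size=(20, 11))
    scaler = HandcraftedScaler()
    z = scaler.fit_transform(m)
    assert np.allclose(z.mean(axis=0), 0, atol=1e-12)
    assert np.allclose(z.std(axis=0), 1, atol=1e-12)
    with pytest.raises(ValueError):
        HandcraftedScaler().transform(m)


# -- baseline score tables ----------------------------------------------------


def test_knn_k1_self_scores_are_one_hot():
    rng = np.random.default_rng(8)
    X = rng.normal(size=(12, 4))
    labels = ["effusion", "normal", "tube"] * 4
    table, _ = baseline_score_table(X, labels, method="knn", params={"k": 1})
    assert table.rows.shape == (12, 3)
    for i, lab in enumerate(labels):
        expected = np.zeros(3)
        expected[table.class_order.index(lab)] = 1.0
        assert np.array_equal(table.rows[i], expected)


def test_svm_separable_blobs_perfect_top1_retrieval():
    rng = np.random.default_rng(9)
    centers = np.array([[0, 0], [10, 0], [0, 10]])
    labels_all = ["effusion", "normal", "tube"]
    X_train = np.concatenate([c + rng.normal(0, 0.5, size=(20, 2)) for c in centers])
    y_train = [lab for lab in labels_all for _ in range(20)]
    X_test = np.concatenate([c + rng.normal(0, 0.5, size=(5, 2)) for c in centers])
    y_test = [lab for lab in labels_all for _ in range(5)]
    table, score_fn = baseline_score_table(X_train, y_train, method="svm")
    hits = 0
    for x, lab in zip(score_fn(X_test), y_test):
        res = retrieve(x, table, 1, "cosine")
        hits += res.items[0].label == lab
    assert hits == len(y_test)


def test_baseline_rejects_single_class_and_unknown_method():
    X = np.zeros((4, 2))
    with pytest.raises(ValueError):
        baseline_score_table(X, ["normal"] * 4, method="knn")
    with pytest.raises(ValueError):
        baseline_score_table(X, ["normal", "tube"] * 2, method="forest")


def test_compose_f1_matrix_stacks_raw_vectors():
    rng = np.random.default_rng(10)
    config = HandcraftedConfig(
        hsv_bins=(4, 2, 2), correlogram_distances=(1,), correlogram_levels=8,
        gabor_scales=2, gabor_orientations=2,
    )
    imgs = [random_image(rng, id_=f"i{i}", size=(48, 48)) for i in range(3)]
    m = compose_f1_matrix(imgs, config)
    assert m.shape == (3, config.total_length)
    assert np.array_equal(m[1], compose_f1(imgs[1], config).values)
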