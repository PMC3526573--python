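"""Derivative-of-Gaussian jets, seven-class BIF labelling, local histograms."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from colonyscan.bif import (
    DEFAULT_EPSILON,
    DEFAULT_SCALES,
    bif_stack,
    classify_bif,
    compute_features,
    feature_stack,
    jet,
)
from helpers_oracles import direct_jet_component

FLAT, SLOPE, DARK_BLOB = 1, 2, 3


# --- jets ----------------------------------------------------------------


def test_jet_of_constant_image_is_pure_zeroth_order():
    j = jet(np.full((32, 32), 7.5), sigma=1.4)
    np.testing.assert_allclose(j.c00, 7.5, atol=1e-12)
    for resp in (j.c10, j.c01, j.c20, j.c11, j.c02):
        np.testing.assert_allclose(resp, 0.0, atol=1e-12)


@pytest.mark.parametrize("sigma", [0.7, 1.5, 2.8])
def test_jet_of_unit_ramp_gives_scale_normalised_gradient(sigma):
    # I(x, y) = x: first x-derivative is 1, so c10 = sigma; all second
    # derivatives vanish away from the borders.
    img = np.tile(np.arange(64, dtype=float), (64, 1))
    j = jet(img, sigma)
    interior = (slice(16, -16),) * 2
    np.testing.assert_allclose(j.c10[interior], sigma, rtol=5e-3)
    np.testing.assert_allclose(j.c01[interior], 0.0, atol=1e-10)
    for resp in (j.c20[interior], j.c02[interior], j.c11[interior]):
        np.testing.assert_allclose(resp, 0.0, atol=1e-10)


def test_jet_nonpositive_sigma_rejected():
    with pytest.raises(ValueError, match="sigma"):
        jet(np.zeros((4, 4)), 0.0)


def test_gaussian_blob_laplacian_extremal_at_centre():
    yy, xx = np.mgrid[:33, :33] - 16.0
    img = np.exp(-(yy**2 + xx**2) / (2 * 3.0**2))  # bright blob
    j = jet(img, 3.0)
    lam = j.c20 + j.c02
    assert lam.argmin() == np.ravel_multi_index((16, 16), lam.shape)


@pytest.mark.parametrize("sigma", [0.7, 1.4, 2.1])
@pytest.mark.parametrize(
    "orders", [(0, 0), (0, 1), (1, 0), (0, 2), (1, 1), (2, 0)]
)
def test_separable_filtering_matches_direct_convolution_oracle(sigma, orders):
    rng = np.random.default_rng(99)
    img = rng.uniform(0, 1, (32, 32))
    j = jet(img, sigma)
    fast = {
        (0, 0): j.c00, (0, 1): j.c10, (1, 0): j.c01,
        (0, 2): j.c20, (1, 1): j.c11, (2, 0): j.c02,
    }[orders]
    slow = direct_jet_component(img, sigma, *orders)
    scale = np.abs(slow).max() or 1.0
    np.testing.assert_allclose(fast / scale, slow / scale, atol=1e-8)


# --- classification ------------------------------------------------------


def test_constant_positive_image_is_all_flat():
    labels = classify_bif(jet(np.full((20, 20), 3.0), 0.7), DEFAULT_EPSILON)
    assert (labels == FLAT).all()


def test_low_intensity_ramp_is_slope_high_offset_ramp_is_flat():
    base = np.tile(np.arange(48, dtype=float), (48, 1))
    interior = (slice(12, -12),) * 2
    # flat score eps*c00 ~ 0.11*x stays below the slope score 2*sigma = 3
    labels = classify_bif(jet(base, 1.5), DEFAULT_EPSILON)
    assert (labels[interior][:, :5] == SLOPE).all()  # x <= 16 there
    # adding a large offset makes eps*c00 dominate -> flat
    labels_hi = classify_bif(jet(base + 1000.0, 1.5), DEFAULT_EPSILON)
    assert (labels_hi[interior] == FLAT).all()


def test_dark_disc_is_dark_blob_at_matching_scale():
    img = np.ones((64, 64))
    yy, xx = np.mgrid[:64, :64]
    img[(yy - 32) ** 2 + (xx - 32) ** 2 <= 16] = 0.0  # radius-4 dark disc
    labels = classify_bif(jet(img, 2.8), DEFAULT_EPSILON)
    assert labels[32, 32] == DARK_BLOB


@settings(max_examples=20, deadline=None)
@given(
    seed=st.integers(min_value=0, max_value=2**16),
    factor=st.sampled_from([0.25, 0.5, 2.0, 8.0]),  # powers of two: exact floats
)
def test_labels_invariant_under_positive_intensity_scaling(seed, factor):
    img = np.random.default_rng(seed).uniform(0, 1, (24, 24))
    j1, j2 = jet(img, 1.4), jet(img * factor, 1.4)
    np.testing.assert_array_equal(
        classify_bif(j1, DEFAULT_EPSILON), classify_bif(j2, DEFAULT_EPSILON)
    )


def test_only_seven_label_values_ever_emitted(rng):
    img = rng.uniform(0, 1, (40, 40))
    stack = bif_stack(img)
    assert set(np.unique(stack.labels)) <= set(range(1, 8))


# --- stacks and features -------------------------------------------------


def test_default_stack_has_four_scales_and_single_scale_has_one():
    img = np.random.default_rng(5).uniform(0, 1, (30, 30))
    assert bif_stack(img).labels.shape == (30, 30, 4)
    assert bif_stack(img, scales=(1.0,)).labels.shape == (30, 30, 1)
    assert DEFAULT_SCALES == (0.7, 1.4, 2.8, 5.6)


def test_constant_image_features_are_all_flat_counts():
    fs = compute_features(np.full((60, 60), 2.0))
    assert fs.n_features == 28
    vec = fs.features[30, 30]
    for s in range(4):
        np.testing.assert_array_equal(vec[7 * s : 7 * s + 7], [625, 0, 0, 0, 0, 0, 0])
    assert vec.sum() == 2500


def test_histogram_bins_sum_to_window_squared_everywhere(rng):
    img = rng.uniform(0, 1, (50, 50))
    fs = feature_stack(bif_stack(img), window=9)
    sums = fs.features.reshape(50, 50, 4, 7).sum(axis=3)
    assert (sums == 81).all()


def test_window_one_gives_one_hot_histograms(rng):
    img = rng.uniform(0, 1, (20, 20))
    stack = bif_stack(img)
    fs = feature_stack(stack, window=1)
    hist = fs.features.reshape(20, 20, 4, 7)
    assert (hist.sum(axis=3) == 1).all()
    recovered = hist.argmax(axis=3) + 1
    np.testing.assert_array_equal(recovered, stack.labels)


def test_even_window_rejected(rng):
    with pytest.raises(ValueError, match="odd"):
        feature_stack(bif_stack(rng.uniform(0, 1, (10, 10))), window=8)
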