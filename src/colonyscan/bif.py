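"""Basic Image Features: multiscale derivative-of-Gaussian texture labels.

Each pixel is assigned to one of seven local-symmetry classes — flat, slope,
dark blob, light blob, dark line, light line, saddle — from the
scale-normalised responses of Gaussian-derivative filters up to second
order.  Doing this at several scales and histogramming the labels over a
local window yields a texture descriptor that separates the fine granular
texture of stem-cell colonies from the sparse elongated fibroblast
background.

Scale normalisation: the response of the (i, j)-th derivative filter at
scale sigma is multiplied by sigma**(i+j), which makes all seven class
scores commensurable and the labelling invariant to image rescaling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "BIF_CLASS_NAMES",
    "DEFAULT_SCALES",
    "DEFAULT_EPSILON",
    "DEFAULT_WINDOW",
    "JetResponse",
    "BIFStack",
    "FeatureStack",
    "jet",
    "bif_scores",
    "classify_bif",
    "bif_stack",
    "feature_stack",
    "compute_features",
]

#: Class labels, index 1..7.  Order matters: argmax ties break to the lowest
#: index, so "flat" wins any exact tie.
BIF_CLASS_NAMES = {
    1: "flat",
    2: "slope",
    3: "dark_blob",
    4: "light_blob",
    5: "dark_line",
    6: "light_line",
    7: "saddle",
}

N_CLASSES = 7
DEFAULT_SCALES: tuple[float, ...] = (0.7, 1.4, 2.8, 5.6)
DEFAULT_EPSILON = 0.11
DEFAULT_WINDOW = 25
_TRUNCATE = 4.0  # Gaussian kernels truncated at 4 sigma


@dataclass
class JetResponse:
    """Scale-normalised Gaussian-derivative responses at one scale.

    ``cIJ`` is ``sigma**(I+J)`` times the image convolved with the
    derivative of a Gaussian of order I in x (columns) and J in y (rows).
    """

    sigma: float
    c00: np.ndarray
    c10: np.ndarray
    c01: np.ndarray
    c20: np.ndarray
    c11: np.ndarray
    c02: np.ndarray

    def arrays(self) -> tuple[np.ndarray, ...]:
        return (self.c00, self.c10, self.c01, self.c20, self.c11, self.c02)


@dataclass
class BIFStack:
    """Per-pixel BIF labels, one plane per scale (values in 1..7)."""

    labels: np.ndarray  # H x W x S, integer
    scales: tuple[float, ...]
    epsilon: float


@dataclass
class FeatureStack:
    """Per-pixel local BIF-histogram features.

    ``features[r, c]`` concatenates, in scale order, the 7-bin count
    histogram of BIF labels in the centred ``window x window`` neighbourhood
    of pixel (r, c).  With 4 scales the vector has 28 elements and each
    scale's bins sum to ``window**2`` (625 for the default 25-pixel window).
    """

    features: np.ndarray  # H x W x (7*S), integer counts
    window: int
    scales: tuple[float, ...]
    epsilon: float

    @property
    def n_features(self) -> int:
        return self.features.shape[2]

    def as_table(self) -> "np.ndarray":
        """Flatten to an (H*W) x n_features matrix in row-major pixel order."""
        h, w, f = self.features.shape
        return self.features.reshape(h * w, f)


def _deriv_kernel1d(sigma: float, order: int, radius: int) -> np.ndarray:
    """Sampled Gaussian-derivative kernel.

    The smoothing kernel is normalised to unit sum; derivative kernels are
    DC-corrected so that a constant image yields exactly zero response
    (the sampled analytic derivative has a tiny nonzero sum from truncation
    and discretisation).
    """
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 * (x / sigma) ** 2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return -x / sigma**2 * phi  # odd-symmetric: zero DC by construction
    k = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
    return k - k.sum() / k.size


def jet(image: np.ndarray, sigma: float, *, truncate: float = _TRUNCATE) -> JetResponse:
    """Compute the scale-normalised 2-jet of an image at one scale.

    Uses separable convolution with sampled Gaussian-derivative kernels and
    reflective boundary handling.

    Raises
    ------
    ValueError
        If ``sigma`` is not positive.
    """
    if not sigma > 0:
        raise ValueError(f"sigma must be positive, got {sigma}")
    img = np.asarray(image, dtype=np.float64)
    radius = int(truncate * sigma + 0.5)

    def g(order_y: int, order_x: int) -> np.ndarray:
        # correlate with the flipped kernel == convolve with the kernel
        ky = _deriv_kernel1d(sigma, order_y, radius)[::-1]
        kx = _deriv_kernel1d(sigma, order_x, radius)[::-1]
        resp = ndimage.correlate1d(img, ky, axis=0, mode="reflect")
        resp = ndimage.correlate1d(resp, kx, axis=1, mode="reflect")
        return resp * sigma ** (order_y + order_x)

    return JetResponse(
        sigma=sigma,
        c00=g(0, 0),
        c10=g(0, 1),
        c01=g(1, 0),
        c20=g(0, 2),
        c11=g(1, 1),
        c02=g(2, 0),
    )


def bif_scores(j: JetResponse, epsilon: float) -> np.ndarray:
    """Stack of the seven class scores, shape (7, H, W).

    With lam = c20 + c02 (Laplacian) and
    gam = sqrt((c20 - c02)**2 + 4*c11**2) (second-order eccentricity):

    ==========  =======================
    flat        epsilon * c00
    slope       2 * sqrt(c10^2 + c01^2)
    dark blob   +lam
    light blob  -lam
    dark line   (gam + lam) / sqrt(2)
    light line  (gam - lam) / sqrt(2)
    saddle      gam
    ==========  =======================

    The sign convention makes a local intensity minimum (positive Laplacian)
    a *dark* blob.  All scores are homogeneous of degree 1 in the image, so
    labels are invariant to positive intensity scaling.
    """
    if not epsilon > 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    shapes = {a.shape for a in j.arrays()}
    if len(shapes) != 1:
        raise ValueError(f"jet responses have mismatched shapes: {shapes}")
    lam = j.c20 + j.c02
    gam = np.sqrt((j.c20 - j.c02) ** 2 + 4.0 * j.c11**2)
    sqrt2 = np.sqrt(2.0)
    return np.stack(
        [
            epsilon * j.c00,
            2.0 * np.hypot(j.c10, j.c01),
            lam,
            -lam,
            (gam + lam) / sqrt2,
            (gam - lam) / sqrt2,
            gam,
        ]
    )


def classify_bif(j: JetResponse, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Label each pixel 1..7 by the largest class score.

    Ties break to the lowest class index (flat first), making the labelling
    deterministic.
    """
    scores = bif_scores(j, epsilon)
    return np.argmax(scores, axis=0).astype(np.uint8) + 1


def bif_stack(
    image: np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    epsilon: float = DEFAULT_EPSILON,
) -> BIFStack:
    """Classify every pixel at each scale; labels shape H x W x S."""
    scales = tuple(float(s) for s in scales)
    if len(scales) == 0:
        raise ValueError("at least one scale is required")
    planes = [classify_bif(jet(image, s), epsilon) for s in scales]
    return BIFStack(labels=np.stack(planes, axis=-1), scales=scales, epsilon=epsilon)


def feature_stack(bifs: BIFStack, window: int = DEFAULT_WINDOW) -> FeatureStack:
    """Local BIF-count histograms around every pixel, concatenated by scale.

    The window is uniformly weighted and centred; boundaries are handled by
    reflection so every pixel's per-scale histogram sums to ``window**2``.

    Raises
    ------
    ValueError
        If ``window`` is even or < 1.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError(f"window must be odd and >= 1, got {window}")
    labels = bifs.labels
    h, w, n_scales = labels.shape
    out = np.empty((h, w, N_CLASSES * n_scales), dtype=np.uint16)
    area = float(window * window)
    for s in range(n_scales):
        plane = labels[:, :, s]
        for k in range(1, N_CLASSES + 1):
            ind = (plane == k).astype(np.float64)
            if window == 1:
                counts = ind
            else:
                counts = ndimage.uniform_filter(ind, size=window, mode="reflect") * area
            out[:, :, s * N_CLASSES + (k - 1)] = np.rint(counts).astype(np.uint16)
    return FeatureStack(
        features=out, window=window, scales=bifs.scales, epsilon=bifs.epsilon
    )


def compute_features(
    image: np.ndarray,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    epsilon: float = DEFAULT_EPSILON,
    window: int = DEFAULT_WINDOW,
) -> FeatureStack:
    """BIF classification + local histograms in one call."""
    return feature_stack(bif_stack(image, scales, epsilon), window)
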