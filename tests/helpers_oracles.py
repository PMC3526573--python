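"""Independent brute-force oracles used to validate the fast implementations.

These deliberately avoid the code paths they check: direct (non-separable)
2-D convolution for the Gaussian-derivative jets, an explicit per-pixel
tally for confusion counts, and a BFS flood fill for connected-component
cleanup.
"""

from collections import deque

import numpy as np


def gaussian_derivative_kernel1d(sigma: float, order: int, radius: int) -> np.ndarray:
    """Sampled derivative-of-Gaussian kernel, normalised like a smoothing
    kernel of the same sigma (the order-0 kernel sums to 1)."""
    x = np.arange(-radius, radius + 1, dtype=np.float64)
    phi = np.exp(-0.5 * x**2 / sigma**2)
    phi /= phi.sum()
    if order == 0:
        return phi
    if order == 1:
        return -x / sigma**2 * phi
    if order == 2:
        k = (x**2 / sigma**4 - 1.0 / sigma**2) * phi
        return k - k.sum() / k.size  # zero-DC: no response to constants
    raise ValueError(order)


def direct_jet_component(
    img: np.ndarray, sigma: float, order_y: int, order_x: int, truncate: float = 4.0
) -> np.ndarray:
    """Scale-normalised jet response by direct 2-D convolution.

    Reflective (edge-repeating) padding, kernel truncated at
    ``truncate * sigma`` — the same conventions as the separable path, but
    computed as one dense quadratic-cost convolution.
    """
    radius = int(truncate * sigma + 0.5)
    ky = gaussian_derivative_kernel1d(sigma, order_y, radius)
    kx = gaussian_derivative_kernel1d(sigma, order_x, radius)
    k2 = np.outer(ky, kx)
    padded = np.pad(np.asarray(img, dtype=np.float64), radius, mode="symmetric")
    h, w = img.shape
    out = np.zeros((h, w), dtype=np.float64)
    size = 2 * radius + 1
    for u in range(size):  # convolution: out[i,j] += k2[u',v'] img[i-u', j-v']
        for v in range(size):
            out += k2[u, v] * padded[
                2 * radius - u : 2 * radius - u + h,
                2 * radius - v : 2 * radius - v + w,
            ]
    return out * sigma ** (order_y + order_x)


def loop_confusion(pred: np.ndarray, ref: np.ndarray) -> tuple[int, int, int, int]:
    """Exhaustive per-pixel TP/FP/FN/TN tally."""
    tp = fp = fn = tn = 0
    for i in range(pred.shape[0]):
        for j in range(pred.shape[1]):
            p, r = bool(pred[i, j]), bool(ref[i, j])
            if p and r:
                tp += 1
            elif p:
                fp += 1
            elif r:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def _flood_components(mask: np.ndarray, connectivity: int) -> list[set]:
    """BFS connected components of True pixels (connectivity 1=4-way, 2=8-way)."""
    if connectivity == 1:
        steps = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    else:
        steps = [(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)]
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                comp = set()
                queue = deque([(i, j)])
                seen[i, j] = True
                while queue:
                    y, x = queue.popleft()
                    comp.add((y, x))
                    for dy, dx in steps:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            queue.append((ny, nx))
                comps.append(comp)
    return comps


def flood_fill_cleanup(
    raw: np.ndarray, min_object: int, min_hole_fill: int
) -> np.ndarray:
    """Reference cleanup: drop 8-connected objects < min_object, then fill
    4-connected enclosed background regions < min_hole_fill."""
    mask = raw.astype(bool).copy()
    for comp in _flood_components(mask, connectivity=2):
        if len(comp) < min_object:
            for y, x in comp:
                mask[y, x] = False
    h, w = mask.shape
    for comp in _flood_components(~mask, connectivity=1):
        touches_border = any(y in (0, h - 1) or x in (0, w - 1) for y, x in comp)
        if not touches_border and len(comp) < min_hole_fill:
            for y, x in comp:
                mask[y, x] = True
    return mask
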