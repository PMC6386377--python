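"""Higher-order local autocorrelation (HLAC) image features.

HLAC features are shift-invariant texture/shape descriptors.  For a local
window of half-width ``d`` (window ``(2d+1) x (2d+1)``, default 3x3), the
N-th order autocorrelation with displacements ``a_1 .. a_N`` is

    x(a_1, ..., a_N) = sum_r I(r) * I(r + a_1) * ... * I(r + a_N)

restricted to displacements within the window.  Up to second order
(products of at most three pixels) the distinct displacement sets — "mask
patterns" marking which window cells enter the product, the centre always
marked — reduce under translation equivalence to 25 canonical patterns for
d=1: 1 of order 0, 4 of order 1, 20 of order 2.  Two patterns are
equivalent iff one is a translate of the other, because translating the
displacement set only shifts the summation index.

Here the sum runs over all window positions fully inside the image (the
interior), and each feature is normalised by the number of interior
positions, so features of images of different sizes are comparable and
translation invariance holds exactly for interior content.

Intensities are normalised to [0, 1] by the stated input range before the
products are taken (grayscale HLAC); on {0, 1} images this degenerates to
the classical binary HLAC.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import List, Sequence, Tuple

import numpy as np

__all__ = ["hlac_masks", "hlac_features", "hlac_feature_names"]

Offset = Tuple[int, int]
Mask = Tuple[Offset, ...]


def _canonical(mask: Sequence[Offset]) -> Mask:
    """Translation-invariant canonical form: shift the bounding box to 0."""
    rows = [r for r, _ in mask]
    cols = [c for _, c in mask]
    r0, c0 = min(rows), min(cols)
    return tuple(sorted((r - r0, c - c0) for r, c in mask))


def hlac_masks(d: int = 1, max_order: int = 2) -> List[Mask]:
    """Enumerate the canonical HLAC mask patterns for window half-width *d*.

    Masks are subsets of window offsets of size ``1 .. max_order+1`` that
    contain the centre, deduplicated under translation (a translated
    displacement set gives the same correlation sum).  Returned in a
    deterministic order (by order, then lexicographically by canonical
    form); every returned mask contains the centre ``(0, 0)`` and all its
    offsets lie within ``[-d, d]``.  For ``d=1, max_order=2`` this yields
    exactly 25 masks: 1 + 4 + 20.
    """
    if d < 1:
        raise ValueError("displacement d must be >= 1")
    offsets = [(r, c) for r in range(-d, d + 1) for c in range(-d, d + 1)]
    offsets.remove((0, 0))
    seen = {}
    for size in range(0, max_order + 1):
        for extra in combinations(offsets, size):
            mask = tuple(sorted(((0, 0),) + extra))
            key = _canonical(mask)
            if key not in seen:
                seen[key] = mask
    # return centre-contained representatives (offsets within [-d, d]),
    # ordered deterministically by their canonical form
    ordered = sorted(seen.items(), key=lambda kv: (len(kv[0]), kv[0]))
    return [rep for _, rep in ordered]


def hlac_feature_names(d: int = 1, max_order: int = 2) -> List[str]:
    names = []
    for mask in hlac_masks(d, max_order):
        cells = "+".join(f"({r},{c})" for r, c in mask)
        names.append(f"hlac[{cells}]")
    return names


def hlac_features(image: np.ndarray, d: int = 1, max_order: int = 2,
                  normalise_intensity: bool = True,
                  binary: bool = False) -> np.ndarray:
    """The canonical HLAC feature vector of a 2-D image.

    Parameters
    ----------
    image
        2-D array of finite intensities.
    d
        Window half-width; the correlation window is ``(2d+1) x (2d+1)``
        and the image must be strictly larger than ``2d`` in each axis.
    normalise_intensity
        Divide by the image maximum (when positive) before taking
        products, so features are comparable across exposure levels.
    binary
        Threshold at the midpoint of the range first (classical binary
        HLAC variant).

    Returns
    -------
    ndarray of length 25 for ``d=1, max_order=2``: each entry is the mean
    over interior window positions of the product of intensities at the
    mask's marked cells.
    """
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim != 2:
        raise ValueError("hlac_features requires a 2-D image")
    h, w = arr.shape
    if h <= 2 * d or w <= 2 * d:
        raise ValueError(
            f"image {arr.shape} smaller than the ({2*d+1}x{2*d+1}) window")
    if binary:
        lo, hi = arr.min(), arr.max()
        arr = (arr > (lo + hi) / 2.0).astype(np.float64) if hi > lo else np.zeros_like(arr)
    elif normalise_intensity:
        m = arr.max()
        if m > 0:
            arr = arr / m

    masks = hlac_masks(d, max_order)
    # interior positions: the full (2d+1)-window fits for every mask
    core = np.s_[d:h - d, d:w - d]
    n_positions = (h - 2 * d) * (w - 2 * d)
    feats = np.empty(len(masks), dtype=np.float64)
    for i, mask in enumerate(masks):
        prod = np.ones((h - 2 * d, w - 2 * d), dtype=np.float64)
        for (dr, dc) in mask:
            prod *= arr[d + dr:h - d + dr, d + dc:w - d + dc]
        feats[i] = prod.sum() / n_positions
    return feats
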