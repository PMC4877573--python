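"""Local binary patterns (classic 3x3 integer-offset variant).

Each interior pixel is encoded by thresholding its P neighbours at radius R
against the centre: bit p is set when the neighbour's gray level is >= the
centre's.  For the default P=8, R=1 the neighbours are the eight
integer-offset pixels, bit 0 at the east neighbour and subsequent bits
proceeding counterclockwise, and the histogram of the 256 possible codes
over all interior pixels is the texture feature.  No circular interpolation
is performed (unnecessary at integer offsets); border pixels are skipped so
every code uses real pixels only.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .imaging import validate_gray


def neighbor_offsets(P: int = 8, R: int = 1) -> list[tuple[int, int]]:
    """(row, col) offsets, p = 0 at angle 0 (east) proceeding counterclockwise."""
    offs = []
    for p in range(P):
        ang = 2.0 * np.pi * p / P
        offs.append((-int(round(R * np.sin(ang))), int(round(R * np.cos(ang)))))
    return offs


def lbp_code(img: np.ndarray, i: int, j: int, P: int = 8, R: int = 1) -> int:
    """LBP code of pixel (i, j): sum over p of s(g_p - g_c) * 2^p, s(x>=0)=1.

    (i, j) must lie at least R pixels from every border.
    """
    img = validate_gray(img)
    M, N = img.shape
    if not (R <= i < M - R and R <= j < N - R):
        raise ValueError(f"pixel ({i}, {j}) is within {R} of the border of {img.shape}")
    gc = int(img[i, j])
    code = 0
    for p, (di, dj) in enumerate(neighbor_offsets(P, R)):
        if int(img[i + di, j + dj]) >= gc:
            code |= 1 << p
    return code


def lbp_histogram(img: np.ndarray, P: int = 8, R: int = 1, normalize: bool = False) -> np.ndarray:
    """Histogram of LBP codes over all interior pixels.

    Returns 2^P counts summing to (M - 2R)(N - 2R); with ``normalize`` the
    counts become frequencies.
    """
    img = validate_gray(img)
    M, N = img.shape
    if M < 2 * R + 1 or N < 2 * R + 1:
        raise ValueError(f"image {img.shape} too small for R={R}")
    center = img[R : M - R, R : N - R].astype(np.int64)
    codes = np.zeros_like(center)
    for p, (di, dj) in enumerate(neighbor_offsets(P, R)):
        neigh = img[R + di : M - R + di, R + dj : N - R + dj].astype(np.int64)
        codes |= (neigh >= center).astype(np.int64) << p
    hist = np.bincount(codes.ravel(), minlength=2**P).astype(np.float64)
    if normalize:
        hist /= hist.sum()
    return hist


class LBPDescriptor(BaseEstimator, TransformerMixin):
    """Transformer computing the 2^P-bin LBP histogram per image.

    Parameters
    ----------
    neighbors : int, default 8
        Number of neighbours P (histogram length 2^P).
    radius : int, default 1
        Neighbourhood radius R in pixels (integer offsets).
    normalize : bool, default False
        Emit frequencies instead of raw counts.
    """

    def __init__(self, neighbors: int = 8, radius: int = 1, normalize: bool = False):
        self.neighbors = neighbors
        self.radius = radius
        self.normalize = normalize

    def fit(self, X, y=None):
        if self.neighbors < 1 or self.radius < 1:
            raise ValueError("neighbors and radius must be >= 1")
        return self

    def transform(self, X) -> np.ndarray:
        return np.vstack(
            [lbp_histogram(img, self.neighbors, self.radius, self.normalize) for img in X]
        )
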