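"""Image loading, grayscale conversion and contrast enhancement.

Microscopy images of dissociated leaf epidermis are stained (safranin), so
colour carries preparation artefacts rather than anatomy.  The pipeline
therefore works on 8-bit grayscale intensities and, before any texture
descriptor is computed, stretches the histogram so that a small fraction of
pixel mass saturates at each intensity extreme (1% by default).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

logger = logging.getLogger(__name__)

#: ITU-R BT.601 luma weights used for RGB -> gray conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)

MAX_LEVEL = 255  # 2**bpp - 1 with bpp = 8


def validate_gray(img: np.ndarray, min_size: int = 3) -> np.ndarray:
    """Check an array satisfies the grayscale-image contract.

    Images are 2-D integer grids with intensities in [0, 255] and at least
    ``min_size`` per side (3, the minimum extent for any neighbourhood
    operator, except for point-wise consumers such as the spectrum).
    Returns the array unchanged (never a copy).
    """
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {img.shape}")
    if img.shape[0] < min_size or img.shape[1] < min_size:
        raise ValueError(f"image too small: {img.shape} (minimum {min_size}x{min_size})")
    if not np.issubdtype(img.dtype, np.integer):
        raise ValueError(f"expected integer intensities, got dtype {img.dtype}")
    if img.min() < 0 or img.max() > MAX_LEVEL:
        raise ValueError("intensities out of range [0, 255]")
    return img


def to_grayscale(arr: np.ndarray) -> np.ndarray:
    """Convert an image array to 8-bit grayscale.

    RGB(A) inputs are combined with the BT.601 luma weights
    (0.299, 0.587, 0.114) and rounded to the nearest integer; an alpha
    channel, if present, is ignored.  Single-channel inputs pass through
    unchanged.
    """
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[2] in (3, 4):
        w = np.asarray(LUMA_WEIGHTS, dtype=np.float64)
        gray = arr[:, :, :3].astype(np.float64) @ w
        out = np.rint(gray).astype(np.int64)
    elif arr.ndim == 2:
        if not np.issubdtype(arr.dtype, np.integer):
            out = np.rint(np.asarray(arr, dtype=np.float64)).astype(np.int64)
        else:
            out = arr.astype(np.int64)
    else:
        raise ValueError(f"unsupported image shape {arr.shape}")
    out = np.clip(out, 0, MAX_LEVEL)
    return validate_gray(out)


def load_grayscale(path: str | Path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image from disk as an 8-bit grayscale grid."""
    import imageio.v3 as iio

    path = Path(path)
    try:
        arr = iio.imread(path)
    except FileNotFoundError:
        raise
    except Exception as exc:  # imageio wraps many backend errors
        raise IOError(f"cannot read image file {path}: {exc}") from exc
    if np.issubdtype(np.asarray(arr).dtype, np.integer) and np.asarray(arr).max(initial=0) > MAX_LEVEL:
        raise ValueError(f"{path}: unsupported bit depth (expected 8-bit, max value {np.asarray(arr).max()})")
    return to_grayscale(arr)


def saturation_bounds(img: np.ndarray, saturation: float = 0.01) -> tuple[int, int]:
    """Lower/upper stretch bounds under the nearest-rank quantile convention.

    With ``n`` pixels and ``k = floor(saturation * n)``, the bounds are the
    (k)-th and (n-1-k)-th order statistics (0-indexed), so at most a
    ``saturation`` fraction of pixels lies strictly below ``lo`` or strictly
    above ``hi``.
    """
    if not (0 <= saturation < 0.5):
        raise ValueError(f"saturation fraction must be in [0, 0.5), got {saturation}")
    flat = np.sort(np.asarray(img), axis=None)
    n = flat.size
    k = int(np.floor(saturation * n))
    return int(flat[k]), int(flat[n - 1 - k])


def enhance_contrast(img: np.ndarray, saturation: float = 0.01) -> np.ndarray:
    """Linear histogram stretch with saturation at both intensity extremes.

    Pixels map by ``(p - lo) * 255 / (hi - lo)``, clipped to [0, 255] and
    rounded, where ``lo``/``hi`` are the ``saturation`` and
    ``1 - saturation`` nearest-rank quantiles of the input.  A near-constant
    image (``hi == lo``) is returned unchanged with a warning, so degenerate
    synthetic inputs flow through the pipeline.
    """
    img = validate_gray(img)
    lo, hi = saturation_bounds(img, saturation)
    if hi == lo:
        warnings.warn("degenerate contrast stretch (hi == lo); image returned unchanged")
        return img.copy()
    stretched = (img.astype(np.float64) - lo) * (MAX_LEVEL / (hi - lo))
    out = np.rint(np.clip(stretched, 0, MAX_LEVEL)).astype(np.int64)
    return out


class ContrastStretch(BaseEstimator, TransformerMixin):
    """Transformer applying the saturating histogram stretch to image stacks.

    Parameters
    ----------
    saturation : float, default 0.01
        Fraction of pixel mass clipped at each intensity extreme.
    """

    def __init__(self, saturation: float = 0.01):
        self.saturation = saturation

    def fit(self, X, y=None):
        if not (0 <= self.saturation < 0.5):
            raise ValueError("saturation fraction must be in [0, 0.5)")
        self.n_features_in_ = 0  # stateless; images arrive as a stack
        return self

    def transform(self, X):
        """Apply the stretch to each image in an iterable/stack of 2-D grids."""
        return [enhance_contrast(img, self.saturation) for img in X]
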