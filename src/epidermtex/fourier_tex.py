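"""Fourier spectral texture descriptors.

The centered 2-D Fourier magnitude spectrum of an epidermis image
concentrates periodic cell-wall structure near the origin and micro-texture
in the high-frequency tails.  Two partitions of the spectrum serve as
texture features:

* *circular* — cumulative sums of |F| over concentric disks of integer
  radius 1..G around the zero-frequency bin, G = floor(min(M, N)/2) - 1,
  capturing the radial (scale) energy profile;
* *circular-angular* — sums of |F| over ring x wedge sectors (8 annuli with
  outer radii 3, 6, ..., 24 by default, times 8 equal 45-degree wedges),
  capturing joint scale/orientation structure in 64 numbers.

Magnitudes come from the unnormalised forward DFT; the zero-frequency bin is
included in the cumulative disks ("from the origin") but excluded from the
sectors (its angle is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .imaging import validate_gray

DEFAULT_RING_RADII = (3.0, 6.0, 9.0, 12.0, 15.0, 18.0, 21.0, 24.0)
DEFAULT_N_ANGLES = 8


@dataclass(frozen=True)
class RingWedgePartition:
    """Ring x wedge partition of the centered spectrum.

    ``ring_radii`` are the strictly increasing outer radii (in spectrum bins)
    of the annuli; ``n_angles`` equal wedges start on the positive
    horizontal-frequency axis and proceed counterclockwise.  Descriptor
    length is ``len(ring_radii) * n_angles``.
    """

    ring_radii: tuple[float, ...] = DEFAULT_RING_RADII
    n_angles: int = DEFAULT_N_ANGLES

    def __post_init__(self):
        radii = tuple(float(r) for r in self.ring_radii)
        if len(radii) == 0 or any(r <= 0 for r in radii):
            raise ValueError("ring radii must be positive")
        if any(b <= a for a, b in zip(radii, radii[1:])):
            raise ValueError("ring radii must be strictly increasing")
        if self.n_angles < 1:
            raise ValueError("n_angles must be >= 1")
        object.__setattr__(self, "ring_radii", radii)

    @property
    def n_features(self) -> int:
        return len(self.ring_radii) * self.n_angles


def centered_spectrum(img: np.ndarray) -> np.ndarray:
    """Magnitude of the 2-D DFT with zero frequency shifted to the center.

    The center lands at bin ``(floor(M/2), floor(N/2))``.  With the
    unnormalised forward transform, Parseval's identity reads
    ``sum |F|^2 = M*N * sum p^2``.
    """
    img = validate_gray(img, min_size=2)  # point-wise: no neighbourhood needed
    return np.abs(np.fft.fftshift(np.fft.fft2(img.astype(np.float64))))


def spectrum_center(shape: tuple[int, int]) -> tuple[int, int]:
    return shape[0] // 2, shape[1] // 2


def _radius_grid(shape: tuple[int, int]) -> np.ndarray:
    ci, cj = spectrum_center(shape)
    ii = np.arange(shape[0])[:, None] - ci
    jj = np.arange(shape[1])[None, :] - cj
    return np.hypot(ii, jj)


def n_circular_features(shape: tuple[int, int]) -> int:
    """Descriptor length G = floor(min(M, N)/2) - 1 for an M x N image."""
    return min(shape) // 2 - 1


def circular_descriptor(spectrum: np.ndarray) -> np.ndarray:
    """Cumulative disk sums of the centered magnitude spectrum.

    Entry ``g`` (1-based radius, g = 1..G) is the sum of magnitudes over all
    bins within Euclidean distance ``g`` of the center bin, center included;
    the sequence is non-decreasing.  Requires min(M, N) >= 6 so at least two
    rings fit.
    """
    spectrum = np.asarray(spectrum, dtype=np.float64)
    if min(spectrum.shape) < 6:
        raise ValueError(f"spectrum too small for circular descriptor: {spectrum.shape}")
    G = n_circular_features(spectrum.shape)
    r = _radius_grid(spectrum.shape)
    # bin b holds mass first included at disk radius b = ceil(r)
    rbin = np.ceil(r).astype(np.int64)
    inside = rbin <= G
    sums = np.bincount(rbin[inside], weights=spectrum[inside], minlength=G + 1)
    return np.cumsum(sums)[1:]


def circular_angular_descriptor(
    spectrum: np.ndarray, partition: RingWedgePartition | None = None
) -> np.ndarray:
    """Ring x wedge sector sums of the centered magnitude spectrum.

    Annuli are half-open in distance from the center, ``(r_lo, r_hi]`` (the
    r = 0 center bin is excluded); wedges are ``[k*2pi/n, (k+1)*2pi/n)``
    measured counterclockwise from the positive horizontal-frequency axis.
    Ordering is ring-major: ring 1 wedges 0..n-1, then ring 2, and so on.
    """
    if partition is None:
        partition = RingWedgePartition()
    spectrum = np.asarray(spectrum, dtype=np.float64)
    r_max = partition.ring_radii[-1]
    if r_max > min(spectrum.shape) // 2:
        raise ValueError(
            f"outermost radius {r_max} exceeds spectrum half-extent {min(spectrum.shape) // 2}"
        )
    ci, cj = spectrum_center(spectrum.shape)
    ii = np.arange(spectrum.shape[0])[:, None] - ci
    jj = np.arange(spectrum.shape[1])[None, :] - cj
    r = np.hypot(ii, jj)
    # counterclockwise angle with the image row axis pointing "down"
    theta = np.mod(np.arctan2(-ii, jj), 2.0 * np.pi)

    edges = np.concatenate(([0.0], np.asarray(partition.ring_radii)))
    n_rings, n_ang = len(partition.ring_radii), partition.n_angles
    ring_idx = np.searchsorted(edges, r, side="left") - 1  # (r_lo, r_hi] -> ring
    wedge_idx = np.minimum((theta * n_ang / (2.0 * np.pi)).astype(np.int64), n_ang - 1)
    valid = (r > 0) & (r <= edges[-1])
    sector = ring_idx[valid] * n_ang + wedge_idx[valid]
    return np.bincount(sector, weights=spectrum[valid], minlength=n_rings * n_ang)


def fourier_features(
    img: np.ndarray,
    mode: str = "circular",
    partition: RingWedgePartition | None = None,
) -> np.ndarray:
    """Full-image Fourier descriptor in the requested mode.

    ``mode='circular'`` returns the cumulative-disk descriptor;
    ``mode='circular+angular'`` appends the 64 sector sums to it.
    """
    spec = centered_spectrum(img)
    if mode == "circular":
        return circular_descriptor(spec)
    if mode in ("circular+angular", "circular_angular"):
        return np.concatenate(
            [circular_descriptor(spec), circular_angular_descriptor(spec, partition)]
        )
    raise ValueError(f"unknown mode {mode!r}")


class FourierDescriptor(BaseEstimator, TransformerMixin):
    """Transformer computing Fourier spectral descriptors for image stacks.

    Parameters
    ----------
    mode : {'circular', 'circular+angular'}, default 'circular'
        Radial cumulative descriptor, optionally concatenated with the
        ring x wedge sector sums.
    ring_radii : tuple of float
        Outer annulus radii for the sector partition.
    n_angles : int
        Number of equal wedges.

    Notes
    -----
    The circular descriptor length depends on image size, so all images in a
    stack must share one shape; mixed shapes raise a ValueError.
    """

    def __init__(
        self,
        mode: str = "circular",
        ring_radii: tuple[float, ...] = DEFAULT_RING_RADII,
        n_angles: int = DEFAULT_N_ANGLES,
    ):
        self.mode = mode
        self.ring_radii = ring_radii
        self.n_angles = n_angles

    def _partition(self) -> RingWedgePartition:
        return RingWedgePartition(tuple(self.ring_radii), self.n_angles)

    def fit(self, X, y=None):
        self._partition()  # validate
        return self

    def transform(self, X) -> np.ndarray:
        part = self._partition()
        shapes = {np.asarray(img).shape for img in X}
        if len(shapes) > 1:
            raise ValueError(
                "circular descriptor length depends on image size; got mixed "
                f"shapes {sorted(shapes)} — crop/resize first"
            )
        return np.vstack([fourier_features(img, self.mode, part) for img in X])
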