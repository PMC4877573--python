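"""Corrosion-Inspired Texture Analysis (CITA).

The image is treated as a metal surface and evolved as a cellular automaton:
each pixel is a cell whose state is its gray level (256 states).  At every
synchronous step, a cell compares its state with the lowest state in its
Moore 8-neighbourhood; if the difference ``d`` exceeds a surface-roughness
threshold ``v``, the cell corrodes by ``C = floor(gamma * d)`` (``gamma`` in
[0, 1] is the pitting power) and its state drops by ``C``.  The running
cumulative corroded mass after each of ``T`` iterations is the texture
descriptor: smooth surfaces corrode little and saturate early, rough
micro-textures sustain corrosion for many steps.

The update rule is reconstructed from its prose description and isolated in
:func:`corrosion_amounts` so an alternative form can be swapped in.  Border
cells use their in-grid neighbours only (no padding); the vectorised kernel
uses a full 3x3 minimum filter with edge replication, which is exactly
equivalent for ``v >= 0`` (including the centre or replicated edge values in
the minimum can only force ``d = 0`` where the centre-excluded rule would
give ``d <= 0`` — no corrosion either way).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter

from .imaging import validate_gray


@dataclass(frozen=True)
class CITAParams:
    """Automaton parameters: roughness threshold ``v``, pitting power
    ``gamma`` in [0, 1], iteration count ``T``."""

    v: float = 2.0
    gamma: float = 0.05
    T: int = 200

    def __post_init__(self):
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError(f"gamma must be in [0, 1], got {self.gamma}")
        if self.v < 0:
            raise ValueError(f"v must be >= 0, got {self.v}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")


@dataclass
class CITAState:
    """Automaton grid plus the cumulative corroded-mass series."""

    grid: np.ndarray
    mass_series: list[float]

    @property
    def t(self) -> int:
        return len(self.mass_series)


def corrosion_amounts(grid: np.ndarray, params: CITAParams) -> np.ndarray:
    """Per-cell corrosion C = floor(gamma * d) where d exceeds v, else 0.

    ``d`` is the central state minus the minimum state over the Moore
    neighbourhood (centre-excluded, truncated at borders).
    """
    neigh_min = minimum_filter(grid, size=3, mode="nearest")
    d = grid - neigh_min
    C = np.floor(params.gamma * d).astype(grid.dtype)
    C[d <= params.v] = 0
    return C


def cita_step(state: CITAState, params: CITAParams) -> CITAState:
    """One synchronous automaton step; appends to the cumulative mass series."""
    C = corrosion_amounts(state.grid, params)
    prev = state.mass_series[-1] if state.mass_series else 0.0
    return CITAState(grid=state.grid - C, mass_series=state.mass_series + [prev + float(C.sum())])


def cita_descriptor(img: np.ndarray, params: CITAParams | None = None) -> np.ndarray:
    """Cumulative corroded-mass series of length ``T`` for an image."""
    if params is None:
        params = CITAParams()
    grid = validate_gray(img).astype(np.int64)
    masses = np.empty(params.T, dtype=np.float64)
    total = 0.0
    for t in range(params.T):
        C = corrosion_amounts(grid, params)
        inc = float(C.sum())
        total += inc
        masses[t] = total
        if inc == 0.0:  # fixed point: nothing will corrode later either
            masses[t:] = total
            break
        grid -= C
    return masses


def cita_descriptor_reference(img: np.ndarray, params: CITAParams) -> np.ndarray:
    """Scalar (non-vectorised) reference automaton.

    Explicit double loop over cells with the centre-excluded truncated Moore
    neighbourhood; intended for small grids and for validating the
    vectorised kernel bitwise.
    """
    grid = validate_gray(img).astype(np.int64).copy()
    M, N = grid.shape
    masses = np.empty(params.T, dtype=np.float64)
    total = 0.0
    for t in range(params.T):
        new = grid.copy()
        inc = 0
        for i in range(M):
            for j in range(N):
                lo = None
                for di in (-1, 0, 1):
                    for dj in (-1, 0, 1):
                        if di == 0 and dj == 0:
                            continue
                        ii, jj = i + di, j + dj
                        if 0 <= ii < M and 0 <= jj < N:
                            s = grid[ii, jj]
                            lo = s if lo is None else min(lo, s)
                d = grid[i, j] - lo
                if d > params.v:
                    C = int(np.floor(params.gamma * d))
                    new[i, j] -= C
                    inc += C
        grid = new
        total += inc
        masses[t] = total
    return masses


from sklearn.base import BaseEstimator, TransformerMixin  # noqa: E402


class CITADescriptor(BaseEstimator, TransformerMixin):
    """Transformer computing the CITA cumulative-mass descriptor per image.

    Parameters mirror :class:`CITAParams`: ``v`` (roughness threshold,
    default 2), ``gamma`` (pitting power, default 0.05) and ``n_iter``
    (descriptor length ``T``, default 200).
    """

    def __init__(self, v: float = 2.0, gamma: float = 0.05, n_iter: int = 200):
        self.v = v
        self.gamma = gamma
        self.n_iter = n_iter

    def _params(self) -> CITAParams:
        return CITAParams(v=self.v, gamma=self.gamma, T=self.n_iter)

    def fit(self, X, y=None):
        self._params()  # validate
        return self

    def transform(self, X) -> np.ndarray:
        params = self._params()
        return np.vstack([cita_descriptor(img, params) for img in X])
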