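"""Uniform node-centered Cartesian grids for the tissue domain.

Mesh points sit at cell corners: ``x_i = i*h`` for ``i = 0..n`` along each
axis, with ``h = length/n``.  ``n`` must be a power of two so the geometric
multigrid hierarchy can coarsen down to ``n = 4``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    dim: int
    n: int
    length: float

    def __post_init__(self):
        if self.dim not in (2, 3):
            raise ValueError("dim must be 2 or 3")
        # n = 4 is permitted internally as the multigrid coarsest level;
        # solver entry points require n >= 8
        if self.n < 4 or self.n & (self.n - 1):
            raise ValueError("n must be a power of two >= 4")
        if self.length <= 0:
            raise ValueError("length must be positive")

    @property
    def h(self) -> float:
        return self.length / self.n

    @property
    def shape(self) -> tuple[int, ...]:
        return (self.n + 1,) * self.dim

    @property
    def size(self) -> int:
        return (self.n + 1) ** self.dim

    def axis_coords(self) -> np.ndarray:
        return np.linspace(0.0, self.length, self.n + 1)

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape)

    def contains(self, pts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
        """Boolean mask of points inside the closed domain box."""
        pts = np.atleast_2d(pts)
        eps = tol * self.length
        return np.all((pts >= -eps) & (pts <= self.length + eps), axis=1)

    def coarsen(self) -> "Grid":
        if self.n <= 4:
            raise ValueError("cannot coarsen below n=4")
        return Grid(self.dim, self.n // 2, self.length)
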