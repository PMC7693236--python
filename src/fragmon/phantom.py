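"""Voxel phantom: a grid of relative-to-water densities on 2 mm isotropic voxels.

Stands in for the planning / re-evaluation CT pair.  Voxel indices are 0-based
with half-open voxel intervals [origin + i*vox, origin + (i+1)*vox); points
outside the grid have density 0 (air).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Phantom"]


@dataclass(frozen=True)
class Phantom:
    """Relative-density voxel grid.

    Parameters
    ----------
    densities : (nx, ny, nz) float array of densities relative to water, in [0, 3].
    origin : position (mm) of the low corner of voxel (0, 0, 0) in the room frame.
    voxel_mm : isotropic voxel pitch, default 2 mm.
    """

    densities: np.ndarray
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    voxel_mm: float = 2.0

    def __post_init__(self):
        d = np.asarray(self.densities, dtype=float)
        if d.ndim != 3:
            raise ValueError("densities must be a 3-D array")
        if np.any(d < 0) or np.any(d > 3):
            raise ValueError("relative densities must lie in [0, 3]")
        object.__setattr__(self, "densities", d)
        object.__setattr__(self, "origin", np.asarray(self.origin, dtype=float))
        if self.voxel_mm <= 0:
            raise ValueError("voxel pitch must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.densities.shape

    @property
    def extent(self) -> np.ndarray:
        """(3, 2) array of [low, high] bounds per axis in mm."""
        lo = self.origin
        hi = self.origin + self.voxel_mm * np.array(self.shape)
        return np.stack([lo, hi], axis=1)

    def density_at(self, points: np.ndarray) -> np.ndarray:
        """Density at (N, 3) room-frame points; 0 outside the grid."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((p - self.origin) / self.voxel_mm).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)
        out = np.zeros(len(p))
        if np.any(inside):
            ii = idx[inside]
            out[inside] = self.densities[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out

    def wepl_along(
        self,
        start: np.ndarray,
        direction: np.ndarray,
        length_mm: float,
        step_mm: float = 1.0,
    ) -> float:
        """Water-equivalent path length along a single ray (midpoint rule)."""
        d = np.asarray(direction, float)
        d = d / np.linalg.norm(d)
        n = max(1, int(np.ceil(length_mm / step_mm)))
        s = (np.arange(n) + 0.5) * (length_mm / n)
        pts = np.asarray(start, float)[None, :] + s[:, None] * d[None, :]
        return float(self.density_at(pts).sum() * (length_mm / n))

    def wepl_along_rays(
        self,
        starts: np.ndarray,
        directions: np.ndarray,
        lengths_mm: np.ndarray,
        step_mm: float = 2.0,
    ) -> np.ndarray:
        """Vectorised WEPL for N rays with per-ray lengths (midpoint rule).

        All rays are sampled with the same number of steps (set by the longest
        ray), so per-ray step sizes are <= ``step_mm``.
        """
        p0 = np.asarray(starts, float)
        d = np.asarray(directions, float)
        d = d / np.linalg.norm(d, axis=1, keepdims=True)
        ell = np.asarray(lengths_mm, float)
        if len(ell) == 0:
            return np.zeros(0)
        # bucket rays by length so short rays do not inherit the longest ray's
        # step count; each bucket shares one fixed step number <= step_mm
        out = np.empty(len(ell))
        order = np.argsort(ell)
        n_buckets = min(8, len(ell))
        for chunk in np.array_split(order, n_buckets):
            if len(chunk) == 0:
                continue
            out[chunk] = self._wepl_fixed_steps(p0[chunk], d[chunk], ell[chunk], step_mm)
        return out

    def _wepl_fixed_steps(self, p0, d, ell, step_mm: float) -> np.ndarray:
        n = max(1, int(np.ceil(ell.max() / step_mm)))
        frac = (np.arange(n) + 0.5) / n
        s = ell[:, None] * frac[None, :]  # (N, n) sample arc lengths
        # work per axis in voxel-index space to avoid an (N, n, 3) intermediate
        dens_flat = self.densities.ravel()
        inside = np.ones(s.shape, dtype=bool)
        flat = np.zeros(s.shape, dtype=np.int64)
        for a, dim in enumerate(self.shape):
            ia = np.floor(
                (p0[:, a, None] + s * d[:, a, None] - self.origin[a]) / self.voxel_mm
            ).astype(np.int64)
            inside &= (ia >= 0) & (ia < dim)
            np.clip(ia, 0, dim - 1, out=ia)
            flat *= dim
            flat += ia
        acc = dens_flat[flat]
        acc[~inside] = 0.0
        return acc.sum(axis=1) * (ell / n)

    def column_cumwepl(self, x_mm: float, y_mm: float, z_grid: np.ndarray) -> np.ndarray:
        """Cumulative WEPL from z_grid[0] along +z at lateral position (x, y).

        Returns an array of the same length as ``z_grid`` with the cumulative
        water-equivalent depth at each grid point (0 at the first point).
        """
        z = np.asarray(z_grid, float)
        dz = np.diff(z)
        mid = np.stack(
            [np.full(len(dz), x_mm), np.full(len(dz), y_mm), z[:-1] + 0.5 * dz], axis=1
        )
        rho = self.density_at(mid)
        return np.concatenate([[0.0], np.cumsum(rho * dz)])
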