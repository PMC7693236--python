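"""Treatment-plan model: pencil beams, end-range estimation, Super-Pencil-Beam merging.

A pencil-beam-scanning plan is a delivery-ordered list of spots.  Each spot's
end range (the depth at which its residual range in water is exhausted) is
estimated with a Bragg-Kleeman range-energy relation R(E) = alpha * E**p and a
water-equivalent marching integration through the phantom; only the *relative*
end-range geometry matters here, which is why a parametric range model is
sufficient in place of a treatment-planning dose engine.

Spots whose end ranges fall in the same aggregation cell (default
10 x 10 x 6 mm, boundaries anchored at the isocenter) are merged into Super
Pencil Beams (SPBs) of at most 75 members; the SPB is the statistical unit of
the inter-fraction comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantom import Phantom

__all__ = [
    "PencilBeam",
    "EndRange",
    "SuperPB",
    "bragg_kleeman_range",
    "bragg_kleeman_energy",
    "compute_end_range",
    "compute_end_ranges",
    "merge_into_spbs",
]

#: Bragg-Kleeman defaults: R [mm water] = ALPHA * (E [MeV/u]) ** P
BK_ALPHA = 0.0094
BK_P = 1.75

MAX_SPB_MEMBERS = 75
DEFAULT_CELL_MM = (10.0, 10.0, 6.0)


class RangeBeyondPhantomError(ValueError):
    """The residual range is not exhausted inside the phantom grid."""


@dataclass(frozen=True)
class PencilBeam:
    """One plan spot: lateral position at the isocenter plane, energy, fluence."""

    pb_id: int
    spot_xy: tuple[float, float]
    energy: float  # MeV/u
    n_ions: float
    field_angle: float = 0.0

    def __post_init__(self):
        if self.n_ions < 1:
            raise ValueError("n_ions must be >= 1")
        if not (50.0 <= self.energy <= 500.0):
            raise ValueError(f"energy {self.energy} MeV/u outside sanity bounds [50, 500]")


@dataclass(frozen=True)
class EndRange:
    """Depth at which a pencil beam's residual range is exhausted."""

    point: np.ndarray  # (3,) mm
    wepl: float  # mm water-equivalent consumed inside the phantom

    def __post_init__(self):
        object.__setattr__(self, "point", np.asarray(self.point, dtype=float))
        if self.wepl < 0:
            raise ValueError("wepl must be >= 0")


@dataclass(frozen=True)
class SuperPB:
    spb_id: int
    member_pb_ids: tuple[int, ...]
    cell_index: tuple[int, int, int]
    centroid: np.ndarray  # (3,) mm

    def __post_init__(self):
        if not 1 <= len(self.member_pb_ids) <= MAX_SPB_MEMBERS:
            raise ValueError("SPB must have 1..75 members")
        object.__setattr__(self, "centroid", np.asarray(self.centroid, dtype=float))


def bragg_kleeman_range(energy: float | np.ndarray, alpha: float = BK_ALPHA,
                        p: float = BK_P) -> float | np.ndarray:
    """Range in water (mm) for a given beam kinetic energy (MeV/u)."""
    return alpha * np.asarray(energy, float) ** p


def bragg_kleeman_energy(range_mm: float | np.ndarray, alpha: float = BK_ALPHA,
                         p: float = BK_P) -> float | np.ndarray:
    """Inverse of :func:`bragg_kleeman_range`."""
    return (np.asarray(range_mm, float) / alpha) ** (1.0 / p)


def _column_grid(phantom: Phantom, step_mm: float) -> np.ndarray:
    lo, hi = phantom.extent[2]
    n = int(np.ceil((hi - lo) / step_mm))
    return lo + np.arange(n + 1) * step_mm


def compute_end_range(
    pb: PencilBeam,
    phantom: Phantom,
    range_shifter_wet: float = 30.0,
    alpha: float = BK_ALPHA,
    p: float = BK_P,
    step_mm: float = 1.0,
) -> EndRange:
    """March along +z through the phantom until the residual range is exhausted.

    The residual range in water after the range shifter is
    ``R(E) - range_shifter_wet``; the marching step accumulates
    ``step * local relative density`` and the crossing point is interpolated
    within the exhausting step.
    """
    if range_shifter_wet < 0:
        raise ValueError("range_shifter_wet must be >= 0")
    residual = float(bragg_kleeman_range(pb.energy, alpha, p)) - range_shifter_wet
    x, y = pb.spot_xy
    z = _column_grid(phantom, step_mm)
    if residual <= 0:
        return EndRange(point=np.array([x, y, z[0]]), wepl=0.0)
    cum = phantom.column_cumwepl(x, y, z)
    if residual > cum[-1]:
        raise RangeBeyondPhantomError(
            f"range beyond phantom for pb {pb.pb_id}: residual {residual:.1f} mm "
            f"water > column WEPL {cum[-1]:.1f} mm"
        )
    k = int(np.searchsorted(cum, residual))
    # interpolate inside step k-1 -> k
    dcum = cum[k] - cum[k - 1]
    frac = (residual - cum[k - 1]) / dcum if dcum > 0 else 1.0
    z_cross = z[k - 1] + frac * (z[k] - z[k - 1])
    return EndRange(point=np.array([x, y, float(z_cross)]), wepl=float(residual))


def compute_end_ranges(
    pbs: Sequence[PencilBeam],
    phantom: Phantom,
    range_shifter_wet: float = 30.0,
    alpha: float = BK_ALPHA,
    p: float = BK_P,
    step_mm: float = 1.0,
) -> list[EndRange]:
    """Vectorised :func:`compute_end_range` over a whole plan."""
    if not pbs:
        return []
    z = _column_grid(phantom, step_mm)
    xy = np.array([pb.spot_xy for pb in pbs], float)
    dz = np.diff(z)
    zmid = z[:-1] + 0.5 * dz
    # (n_pb * n_steps, 3) midpoints in one lookup
    pts = np.empty((len(pbs), len(zmid), 3))
    pts[:, :, 0] = xy[:, 0][:, None]
    pts[:, :, 1] = xy[:, 1][:, None]
    pts[:, :, 2] = zmid[None, :]
    rho = phantom.density_at(pts.reshape(-1, 3)).reshape(len(pbs), len(zmid))
    cum = np.concatenate([np.zeros((len(pbs), 1)), np.cumsum(rho * dz, axis=1)], axis=1)

    residual = bragg_kleeman_range(np.array([pb.energy for pb in pbs]), alpha, p)
    residual = residual - range_shifter_wet

    out: list[EndRange] = []
    for i, pb in enumerate(pbs):
        r = float(residual[i])
        if r <= 0:
            out.append(EndRange(point=np.array([xy[i, 0], xy[i, 1], z[0]]), wepl=0.0))
            continue
        if r > cum[i, -1]:
            raise RangeBeyondPhantomError(
                f"range beyond phantom for pb {pb.pb_id}: residual {r:.1f} mm"
            )
        k = int(np.searchsorted(cum[i], r))
        d = cum[i, k] - cum[i, k - 1]
        frac = (r - cum[i, k - 1]) / d if d > 0 else 1.0
        out.append(
            EndRange(point=np.array([xy[i, 0], xy[i, 1], float(z[k - 1] + frac * (z[k] - z[k - 1]))]),
                     wepl=r)
        )
    return out


def merge_into_spbs(
    pbs: Sequence[PencilBeam],
    end_ranges: Sequence[EndRange],
    cell: tuple[float, float, float] = DEFAULT_CELL_MM,
) -> list[SuperPB]:
    """Group pencil beams whose end ranges share an aggregation cell.

    The grid is anchored at the isocenter (cell boundaries at integer multiples
    of the cell dimensions, half-open intervals).  Within a cell, beams are
    assigned in delivery order to consecutive SPBs of at most 75 members, so
    the partition is deterministic and fraction-independent.
    """
    if len(pbs) != len(end_ranges):
        raise ValueError("one end range per pencil beam required")
    if any(c <= 0 for c in cell):
        raise ValueError("cell dimensions must be > 0")
    if not pbs:
        return []

    cells: dict[tuple[int, int, int], list[int]] = {}
    order: list[tuple[int, int, int]] = []
    for i, er in enumerate(end_ranges):
        key = tuple(int(np.floor(er.point[a] / cell[a])) for a in range(3))
        if key not in cells:
            cells[key] = []
            order.append(key)
        cells[key].append(i)

    spbs: list[SuperPB] = []
    spb_id = 0
    for key in order:
        members = cells[key]
        for start in range(0, len(members), MAX_SPB_MEMBERS):
            chunk = members[start : start + MAX_SPB_MEMBERS]
            centroid = np.mean([end_ranges[i].point for i in chunk], axis=0)
            spbs.append(
                SuperPB(
                    spb_id=spb_id,
                    member_pb_ids=tuple(pbs[i].pb_id for i in chunk),
                    cell_index=key,
                    centroid=centroid,
                )
            )
            spb_id += 1
    return spbs
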