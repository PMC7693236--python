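"""2D PCA occupancy maps, overlap classification and distal-edge range reading.

The horizontal-plane (x, z) projection of the PCA cloud gives a coarse range
map of the delivered field.  Comparing the reference and test maps shows where
the fragment-emitting volume moved: cells present only in the test map at
distal z indicate a range elongation (lower density crossed by the beam), and
the per-column distal-edge difference converts that picture into millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Map2D",
    "OverlapMap",
    "build_map2d",
    "classify_overlap",
    "distal_edge_shift",
]

DEFAULT_MAP_BIN_MM = 5.0
PRESENCE_THRESHOLD_FRAC = 0.05
EDGE_THRESHOLD_FRAC = 0.20
EDGE_SMOOTH_BINS = 3
COLUMN_COUNT_FLOOR = 50.0

CATEGORIES = ("neither", "only_ref", "only_test", "both")


@dataclass
class Map2D:
    """Weighted occupancy of PCA positions in the horizontal (x, z) plane."""

    edges_x: np.ndarray
    edges_z: np.ndarray
    counts: np.ndarray  # (n_x, n_z)

    def __post_init__(self):
        self.edges_x = np.asarray(self.edges_x, float)
        self.edges_z = np.asarray(self.edges_z, float)
        self.counts = np.asarray(self.counts, float)
        if self.counts.shape != (len(self.edges_x) - 1, len(self.edges_z) - 1):
            raise ValueError("counts shape inconsistent with bin edges")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    def same_binning(self, other: "Map2D") -> bool:
        return np.array_equal(self.edges_x, other.edges_x) and np.array_equal(
            self.edges_z, other.edges_z
        )


@dataclass
class OverlapMap:
    """Per-cell presence category for a ref/test map pair."""

    edges_x: np.ndarray
    edges_z: np.ndarray
    category: np.ndarray  # (n_x, n_z) int indices into CATEGORIES
    threshold_frac: float

    def count(self, name: str) -> int:
        return int(np.sum(self.category == CATEGORIES.index(name)))


def build_map2d(
    positions: np.ndarray,
    weights: np.ndarray | None = None,
    edges_x: np.ndarray | None = None,
    edges_z: np.ndarray | None = None,
    bin_mm: float = DEFAULT_MAP_BIN_MM,
) -> Map2D:
    """Weighted 2D histogram of PCA (x, z) positions.

    Default binning spans the data, snapped to multiples of ``bin_mm``.
    """
    pos = np.asarray(positions, float).reshape(-1, 3)
    x, z = pos[:, 0], pos[:, 2]
    if edges_x is None:
        lo = np.floor((x.min() if len(x) else 0.0) / bin_mm) * bin_mm
        hi = np.ceil(((x.max() if len(x) else 0.0) + 1e-9) / bin_mm) * bin_mm
        edges_x = np.arange(lo, hi + bin_mm / 2, bin_mm)
    if edges_z is None:
        lo = np.floor((z.min() if len(z) else 0.0) / bin_mm) * bin_mm
        hi = np.ceil(((z.max() if len(z) else 0.0) + 1e-9) / bin_mm) * bin_mm
        edges_z = np.arange(lo, hi + bin_mm / 2, bin_mm)
    counts, ex, ez = np.histogram2d(x, z, bins=[edges_x, edges_z], weights=weights)
    return Map2D(edges_x=ex, edges_z=ez, counts=counts)


def classify_overlap(
    ref: Map2D, test: Map2D, threshold_frac: float = PRESENCE_THRESHOLD_FRAC
) -> OverlapMap:
    """Three-way overlap of two maps after normalising them to equal totals.

    A cell is "present" in a map when its content is at least
    ``threshold_frac`` of that map's maximum.
    """
    if not ref.same_binning(test):
        raise ValueError("maps must share identical binning")
    a = ref.counts / ref.total if ref.total > 0 else ref.counts
    b = test.counts / test.total if test.total > 0 else test.counts
    pa = a >= threshold_frac * a.max() if a.max() > 0 else np.zeros_like(a, bool)
    pb = b >= threshold_frac * b.max() if b.max() > 0 else np.zeros_like(b, bool)
    cat = np.zeros(a.shape, dtype=np.int8)
    cat[pa & ~pb] = CATEGORIES.index("only_ref")
    cat[~pa & pb] = CATEGORIES.index("only_test")
    cat[pa & pb] = CATEGORIES.index("both")
    return OverlapMap(
        edges_x=ref.edges_x, edges_z=ref.edges_z, category=cat, threshold_frac=threshold_frac
    )


def _smooth_column(col: np.ndarray, width: int) -> np.ndarray:
    kernel = np.ones(width) / width
    return np.convolve(col, kernel, mode="same")


def _distal_edge(col: np.ndarray, edges_z: np.ndarray,
                 frac: float, smooth: int) -> float:
    sm = _smooth_column(col, smooth)
    m = sm.max()
    if m <= 0:
        return np.nan
    above = np.nonzero(sm >= frac * m)[0]
    # distal boundary of the last bin at/above threshold
    return float(edges_z[above[-1] + 1])


def distal_edge_shift(
    ref: Map2D,
    test: Map2D,
    count_floor: float = COLUMN_COUNT_FLOOR,
    edge_frac: float = EDGE_THRESHOLD_FRAC,
    smooth_bins: int = EDGE_SMOOTH_BINS,
) -> dict[float, float]:
    """Per-x-column distal-edge difference edge_test - edge_ref, in mm.

    Columns with fewer than ``count_floor`` counts in either map are excluded.
    The edge is the distal boundary of the largest-z bin whose 3-bin-smoothed
    content is at least ``edge_frac`` of the column maximum.  The result is
    keyed by column center x.  Invariant under common rescaling of the maps.
    """
    if not ref.same_binning(test):
        raise ValueError("maps must share identical binning")
    centers_x = 0.5 * (ref.edges_x[:-1] + ref.edges_x[1:])
    out: dict[float, float] = {}
    for i, xc in enumerate(centers_x):
        cr, ct = ref.counts[i], test.counts[i]
        if cr.sum() < count_floor or ct.sum() < count_floor:
            continue
        er = _distal_edge(cr, ref.edges_z, edge_frac, smooth_bins)
        et = _distal_edge(ct, test.edges_z, edge_frac, smooth_bins)
        if np.isnan(er) or np.isnan(et):
            continue
        out[float(xc)] = float(et - er)
    return out
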