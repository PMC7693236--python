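"""Per-SPB 1D emission profiles: livetime weighting, origin windows, leading-edge mask.

The monitored observable is the 1D distribution of PCA positions projected on
the beam axis (z), per Super Pencil Beam.  Three corrections shape it:

* livetime weights undo the non-paralyzable acquisition dead time (tau ~ 5 us
  at track rates up to O(100) kHz), so fractions taken at different beam
  intensities remain comparable in absolute yield;
* an origin window classifies each PCA as range-shifter (RS), patient or other
  - RS fragments are anatomy-independent and excluded from the morphology
  profiles (they serve the alignment systematic instead);
* the profile leading edge - the rising region most sensitive to millimetre
  patient/detector misalignment - is masked out of the chi-square comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

__all__ = [
    "DeadTimeModel",
    "EmissionProfile",
    "OriginClass",
    "classify_origin",
    "livetime_weights",
    "build_profile",
    "leading_edge_mask",
]

DEFAULT_BIN_MM = 5.0
#: leading-edge rule: exclude up to and including the first bin exceeding this
#: fraction of the profile maximum
LEADING_EDGE_FRAC = 0.5


class DeadTimeValidityError(ValueError):
    """Recorded rate x tau too close to saturation for the livetime inversion."""


@dataclass(frozen=True)
class DeadTimeModel:
    """Non-paralyzable dead time with sliding-window rate estimation."""

    tau: float = 5e-6  # s
    window: float = 1e-3  # s, rate-estimation window

    def __post_init__(self):
        if self.tau < 0:
            raise ValueError("tau must be >= 0")
        if self.window <= self.tau:
            raise ValueError("rate window must exceed tau")


@dataclass
class EmissionProfile:
    """Weighted, binned 1D distribution of PCA positions along the beam axis."""

    spb_id: int
    fraction_id: int
    bin_edges: np.ndarray
    weights: np.ndarray
    sumw2: np.ndarray
    n_raw: int

    def __post_init__(self):
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.weights = np.asarray(self.weights, float)
        self.sumw2 = np.asarray(self.sumw2, float)
        if len(self.weights) != len(self.bin_edges) - 1:
            raise ValueError("len(weights) must equal len(bin_edges) - 1")
        if self.weights.shape != self.sumw2.shape:
            raise ValueError("weights and sumw2 must have the same shape")
        if np.any(self.weights < 0) or np.any(self.sumw2 < 0):
            raise ValueError("weights and sumw2 must be non-negative")

    @property
    def total(self) -> float:
        return float(self.weights.sum())

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass(frozen=True)
class OriginClass:
    """Disjoint z windows [z_min, z_max) labelling the fragment origin region."""

    z_windows: dict = field(
        default_factory=lambda: {
            "range_shifter": (-126.0, -84.0),
            "patient": (-25.0, 200.0),
        }
    )

    def __post_init__(self):
        wins = sorted(self.z_windows.values())
        for (a0, a1), (b0, b1) in zip(wins, wins[1:]):
            if a1 > b0:
                raise ValueError("origin windows must be disjoint")
        for lo, hi in wins:
            if not lo < hi:
                raise ValueError("each window must satisfy z_min < z_max")

    @classmethod
    def from_rs_position(
        cls,
        rs_z_mm: float,
        resolution_mm: float = 7.0,
        patient_window: tuple[float, float] = (-25.0, 200.0),
    ) -> "OriginClass":
        """RS window centred on the range-shifter z, +/- 3 sigma of the
        backprojection resolution."""
        half = 3.0 * resolution_mm
        return cls({"range_shifter": (rs_z_mm - half, rs_z_mm + half),
                    "patient": patient_window})


def classify_origin(s_beam: float | np.ndarray, windows: OriginClass) -> np.ndarray:
    """Label PCA axial positions by window membership ('other' outside all)."""
    s = np.atleast_1d(np.asarray(s_beam, float))
    labels = np.full(len(s), "other", dtype=object)
    for name, (lo, hi) in windows.z_windows.items():
        labels[(s >= lo) & (s < hi)] = name
    return labels


def livetime_weights(timestamps: np.ndarray, model: DeadTimeModel) -> np.ndarray:
    """Per-event livetime weights 1 / (1 - r(t) * tau) for non-paralyzable dead time.

    ``r(t)`` is the instantaneous *recorded* rate estimated by counting recorded
    events in a sliding window of ``model.window`` centred on each event.  For a
    non-paralyzable system with true rate lambda the recorded rate is
    m = lambda / (1 + lambda tau), so lambda = m / (1 - m tau): weighting each
    recorded event by 1 / (1 - m tau) recovers the true counts in expectation.
    """
    t = np.asarray(timestamps, float)
    if len(t) == 0:
        return np.zeros(0)
    if np.any(np.diff(t) < 0):
        raise ValueError("timestamps must be sorted ascending")
    if model.tau == 0.0:
        return np.ones(len(t))
    half = 0.5 * model.window
    counts = np.searchsorted(t, t + half, side="right") - np.searchsorted(
        t, t - half, side="left"
    )
    rate = counts / model.window
    occupancy = rate * model.tau
    if np.any(occupancy >= 0.9):
        raise DeadTimeValidityError(
            f"dead-time correction out of validity: max r*tau = {occupancy.max():.3f}"
        )
    return 1.0 / (1.0 - occupancy)


def build_profile(
    s_beam: np.ndarray,
    weights: np.ndarray | None,
    bin_edges: np.ndarray,
    spb_id: int,
    fraction_id: int,
) -> EmissionProfile:
    """Weighted histogram of PCA axial positions with per-bin sum of squared weights."""
    s = np.asarray(s_beam, float)
    w = np.ones(len(s)) if weights is None else np.asarray(weights, float)
    hist, edges = np.histogram(s, bins=bin_edges, weights=w)
    sumw2, _ = np.histogram(s, bins=bin_edges, weights=w * w)
    return EmissionProfile(
        spb_id=spb_id,
        fraction_id=fraction_id,
        bin_edges=edges,
        weights=hist,
        sumw2=sumw2,
        n_raw=int(len(s)),
    )


def uniform_edges(z_min: float, z_max: float, bin_mm: float = DEFAULT_BIN_MM) -> np.ndarray:
    n = int(np.ceil((z_max - z_min) / bin_mm))
    return z_min + bin_mm * np.arange(n + 1)


def leading_edge_mask(reference: EmissionProfile,
                      frac: float = LEADING_EDGE_FRAC) -> np.ndarray:
    """Boolean per-bin mask (True = usable) excluding the profile leading edge.

    Every bin up to and including the first bin whose content exceeds
    ``frac`` of the profile maximum is excluded; all later bins are kept.
    An all-zero reference yields an all-excluded mask with a warning.
    """
    w = reference.weights
    mask = np.zeros(len(w), dtype=bool)
    if w.max() <= 0:
        warnings.warn("leading_edge_mask: all-zero reference profile, all bins excluded")
        return mask
    above = np.nonzero(w > frac * w.max())[0]
    mask[above[0] + 1 :] = True
    return mask
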