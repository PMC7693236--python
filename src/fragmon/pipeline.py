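"""Fraction processing: track list -> livetime weights -> PCAs -> per-SPB profiles.

This is the glue between the simulator / track files and the comparator: it
computes every track's point of closest approach to its own pencil-beam axis,
classifies the origin (range shifter / patient / other), applies the
non-paralyzable dead-time correction, and accumulates the patient-labelled
PCAs of each Super Pencil Beam into a weighted 1D emission profile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compare import RsTrackSet
from .geometry import DetectorPose, compute_pca_batch
from .plan import PencilBeam, SuperPB, compute_end_ranges, merge_into_spbs
from .phantom import Phantom
from .profiles import (
    DeadTimeModel,
    EmissionProfile,
    OriginClass,
    build_profile,
    classify_origin,
    livetime_weights,
    uniform_edges,
)

__all__ = ["PipelineConfig", "ProcessedFraction", "process_fraction", "plan_spbs"]


@dataclass(frozen=True)
class PipelineConfig:
    bin_mm: float = 5.0
    patient_window: tuple[float, float] = (-25.0, 200.0)
    rs_z_mm: float = -105.0
    resolution_mm: float = 7.0
    dead_time: DeadTimeModel = field(default_factory=DeadTimeModel)
    correct_dead_time: bool = True

    def origin_windows(self) -> OriginClass:
        return OriginClass.from_rs_position(
            self.rs_z_mm, self.resolution_mm, self.patient_window
        )

    def bin_edges(self) -> np.ndarray:
        return uniform_edges(*self.patient_window, self.bin_mm)


@dataclass
class ProcessedFraction:
    """Per-fraction analysis products consumed by the comparator and map builder."""

    fraction_id: int
    pose: DetectorPose
    profiles: dict[int, EmissionProfile]
    spb_s_beam: dict[int, np.ndarray]
    spb_pca_positions: dict[int, np.ndarray]
    spb_weights: dict[int, np.ndarray]
    spb_track_dirs: dict[int, np.ndarray]  # unit track directions, for shift trials
    rs_tracks: RsTrackSet
    pca_table: pd.DataFrame  # per-track: s_beam, miss, label, weight, spb_id, x/y/z

    def patient_positions(self) -> np.ndarray:
        t = self.pca_table
        sel = t["label"] == "patient"
        return t.loc[sel, ["x", "y", "z"]].to_numpy()

    def patient_weights(self) -> np.ndarray:
        t = self.pca_table
        return t.loc[t["label"] == "patient", "weight"].to_numpy()


def plan_spbs(
    plan: list[PencilBeam],
    planning_phantom: Phantom,
    range_shifter_wet_mm: float = 30.0,
    cell: tuple[float, float, float] = (10.0, 10.0, 6.0),
) -> list[SuperPB]:
    """Fraction-independent SPB definitions from the plan and planning phantom."""
    ers = compute_end_ranges(plan, planning_phantom, range_shifter_wet_mm)
    return merge_into_spbs(plan, ers, cell)


def process_fraction(
    tracks: pd.DataFrame,
    plan: list[PencilBeam],
    spbs: list[SuperPB],
    pose: DetectorPose,
    config: PipelineConfig = PipelineConfig(),
) -> ProcessedFraction:
    """Turn a per-fraction track list into per-SPB emission profiles."""
    df = tracks.sort_values("t", kind="stable").reset_index(drop=True)
    pts = df[["x", "y", "z"]].to_numpy(float)
    dirs = df[["dx", "dy", "dz"]].to_numpy(float)
    pbid = df["pb_id"].to_numpy(np.int64)

    spot_by_pb = {pb.pb_id: pb.spot_xy for pb in plan}
    missing = set(np.unique(pbid)) - set(spot_by_pb)
    if missing:
        raise ValueError(f"tracks reference pb_ids absent from the plan: {sorted(missing)[:5]}")
    axes = np.zeros((len(df), 3))
    if len(df):
        uniq, inverse = np.unique(pbid, return_inverse=True)
        xy_uniq = np.array([spot_by_pb[i] for i in uniq])
        axes[:, :2] = xy_uniq[inverse]

    positions, miss, s_beam, degen = compute_pca_batch(pts, dirs, axes)
    labels = classify_origin(s_beam, config.origin_windows())

    if config.correct_dead_time:
        w = livetime_weights(df["t"].to_numpy(float), config.dead_time)
    else:
        w = np.ones(len(df))

    spb_of_pb: dict[int, int] = {}
    for spb in spbs:
        for p in spb.member_pb_ids:
            spb_of_pb[p] = spb.spb_id
    spb_ids = np.array([spb_of_pb.get(i, -1) for i in pbid], dtype=np.int64)

    table = pd.DataFrame(
        {
            "x": positions[:, 0], "y": positions[:, 1], "z": positions[:, 2],
            "s_beam": s_beam, "miss": miss, "degenerate": degen,
            "label": labels.astype(str), "weight": w,
            "pb_id": pbid, "spb_id": spb_ids,
        }
    )

    edges = config.bin_edges()
    fraction_id = int(df["fraction_id"].iloc[0]) if len(df) else -1
    profiles: dict[int, EmissionProfile] = {}
    s_by_spb: dict[int, np.ndarray] = {}
    pos_by_spb: dict[int, np.ndarray] = {}
    w_by_spb: dict[int, np.ndarray] = {}
    dir_by_spb: dict[int, np.ndarray] = {}
    pat = (table["label"] == "patient").to_numpy() & (spb_ids >= 0)
    idx_pat = np.flatnonzero(pat)
    grp = idx_pat[np.argsort(spb_ids[idx_pat], kind="stable")]
    grp_keys = spb_ids[grp]
    for spb in spbs:
        lo = np.searchsorted(grp_keys, spb.spb_id, side="left")
        hi = np.searchsorted(grp_keys, spb.spb_id, side="right")
        sel = grp[lo:hi]
        s = s_beam[sel]
        profiles[spb.spb_id] = build_profile(s, w[sel], edges, spb.spb_id, fraction_id)
        s_by_spb[spb.spb_id] = s
        pos_by_spb[spb.spb_id] = positions[sel]
        w_by_spb[spb.spb_id] = w[sel]
        dir_by_spb[spb.spb_id] = dirs[sel]

    rs_sel = (table["label"] == "range_shifter").to_numpy()
    rs = RsTrackSet(
        points=pts[rs_sel], directions=dirs[rs_sel],
        axis_origins=axes[rs_sel], weights=w[rs_sel],
    )
    return ProcessedFraction(
        fraction_id=fraction_id,
        pose=pose,
        profiles=profiles,
        spb_s_beam=s_by_spb,
        spb_pca_positions=pos_by_spb,
        spb_weights=w_by_spb,
        spb_track_dirs=dir_by_spb,
        rs_tracks=rs,
        pca_table=table,
    )
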