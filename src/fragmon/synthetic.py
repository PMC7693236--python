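"""Seeded synthetic delivery/detector simulator.

Generates per-fraction reconstructed-track lists with the statistical structure
the monitoring analysis assumes, standing in for clinical trial data:

* a pencil-beam-scanning plan on a voxel phantom (CNAO-like: energies giving
  end ranges over several slices, 1e3-7e5 ions per beam, a 3 cm water range
  shifter upstream);
* fragment emission uniform per unit water-equivalent path along each beam up
  to its end range (emission density proportional to local density), with
  exponential water-equivalent attenuation on the exit path;
* a planar 30 x 30 cm tracker at ~50 cm from the isocenter, 60 degrees to the
  beam and 30 degrees upward, ~90% per-layer efficiency over 4 layer pairs;
* multiple-scattering-limited backprojection: recorded directions are smeared
  by a Highland-formula angle from the fragment energy and exit depth;
* non-paralyzable acquisition dead time (5 us) at spill rates up to O(100) kHz,
  and per-fraction detector pose offsets drawn from the placement uncertainty.

Every emitted record is linked to a truth record (true emission point, origin
label, parent beam) so parameter-recovery tests can close the loop.

Sampling note: candidate exit rays are importance-sampled uniformly over the
detector face rather than over the full sphere; the face subtends a small
solid angle over which a broad forward-peaked angular density is flat, so the
detected-sample distribution is unchanged while no candidates are wasted on
rays that miss the tracker.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .geometry import DetectorPose
from .phantom import Phantom
from .plan import PencilBeam, bragg_kleeman_energy, compute_end_ranges

__all__ = [
    "PhantomSpec",
    "PlanSpec",
    "SpillModel",
    "ScenarioConfig",
    "SimulatedFraction",
    "make_phantom",
    "build_plan",
    "simulate_fraction",
    "scenario_suite",
]

PROTON_MASS_MEV = 938.272
X0_WATER_MM = 360.8
TRACK_COLUMNS = ["x", "y", "z", "dx", "dy", "dz", "t", "pb_id", "fraction_id"]


@dataclass(frozen=True)
class PhantomSpec:
    """Water body box with an optional low-density cavity box.

    The cavity fill fraction ``f`` interpolates voxel density between empty
    (``rho_cavity``, ~0.05) at f=0 and filled (water, 1.0) at f=1, emulating a
    gradually emptying/refilling nasal cavity.
    """

    body_lo: tuple[float, float, float] = (-60.0, -60.0, 0.0)
    body_hi: tuple[float, float, float] = (60.0, 60.0, 160.0)
    grid_lo: tuple[float, float, float] = (-64.0, -64.0, -4.0)
    grid_hi: tuple[float, float, float] = (64.0, 64.0, 164.0)
    voxel_mm: float = 2.0
    cavity_lo: tuple[float, float, float] | None = None
    cavity_hi: tuple[float, float, float] | None = None
    rho_cavity: float = 0.05
    fill: float = 1.0


@dataclass(frozen=True)
class PlanSpec:
    """Rectangular spot grid with one lateral scan per energy slice.

    Delivery order: energy slices outermost (deepest last), row-major lateral
    scan within a slice.  Ion counts per beam are log-uniform over
    ``n_ions_range`` (the plan-to-plan spread of clinical spot weights), drawn
    once per plan seed so every fraction delivers the identical plan.
    """

    half_extent_mm: float = 36.0
    spacing_mm: float = 3.0
    end_depths_mm: tuple[float, ...] = (40.0, 52.0, 64.0, 76.0, 88.0)
    n_ions_range: tuple[float, float] = (1e4, 7e5)
    field_angle: float = 0.0


@dataclass(frozen=True)
class SpillModel:
    """Piecewise-constant detected-candidate rate, one level per energy slice
    (cycled).  Rates are track rates at the detector, in /s."""

    rate_levels: tuple[float, ...] = (5e4,)

    def rate_for_slice(self, s: int) -> float:
        return self.rate_levels[s % len(self.rate_levels)]


@dataclass(frozen=True)
class ScenarioConfig:
    """Full, seeded description of one synthetic fraction."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    plan: PlanSpec = field(default_factory=PlanSpec)
    spill: SpillModel = field(default_factory=SpillModel)
    detector_distance_mm: float = 500.0
    detector_tilt_deg: float = 60.0
    detector_elevation_deg: float = 30.0
    detector_half_size_mm: float = 150.0
    sigma_xyz: tuple[float, float, float] = (1.2, 1.2, 1.2)
    yield_per_pb: float = 100.0  # mean detected patient tracks per PB
    rs_fraction: float = 0.4  # detected-track fraction originating in the RS
    rs_z_mm: float = -105.0  # range-shifter slab center
    rs_thickness_mm: float = 30.0
    range_shifter_wet_mm: float = 30.0
    mu_wepl: float = 0.005  # attenuation coefficient per mm water-equivalent
    tau_s: float = 5e-6
    fragment_energy_mev: tuple[float, float] = (80.0, 250.0)
    layer_efficiency: float = 0.9
    n_layer_pairs: int = 4
    apply_pose_offset: bool = True
    apply_dead_time: bool = True
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.rs_fraction <= 1.0:
            raise ValueError("rs_fraction must lie in [0, 1]")
        if self.yield_per_pb < 0:
            raise ValueError("yield must be >= 0")

    def pose(self) -> DetectorPose:
        return DetectorPose.nominal(
            distance_mm=self.detector_distance_mm,
            tilt_deg=self.detector_tilt_deg,
            elevation_deg=self.detector_elevation_deg,
            sigma_xyz=self.sigma_xyz,
        )

    def track_efficiency(self) -> float:
        return self.layer_efficiency ** self.n_layer_pairs

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown scenario keys: {sorted(unknown)}")

        def _sub(key, sub_cls):
            if key in d and isinstance(d[key], dict):
                sub_known = set(sub_cls.__dataclass_fields__)
                sub_unknown = set(d[key]) - sub_known
                if sub_unknown:
                    raise ValueError(f"unknown {key} keys: {sorted(sub_unknown)}")
                kw = {
                    k: (tuple(v) if isinstance(v, list) else v) for k, v in d[key].items()
                }
                d[key] = sub_cls(**kw)

        _sub("phantom", PhantomSpec)
        _sub("plan", PlanSpec)
        _sub("spill", SpillModel)
        for k, v in d.items():
            if isinstance(v, list):
                d[k] = tuple(v)
        return cls(**d)


@dataclass
class SimulatedFraction:
    fraction_id: int
    tracks: pd.DataFrame  # TRACK_COLUMNS (+ track_id)
    truth: pd.DataFrame  # track_id, x_true, y_true, z_true, origin, pb_id
    plan: list[PencilBeam]
    scenario: ScenarioConfig
    pose_offset: np.ndarray


def make_phantom(spec: PhantomSpec) -> Phantom:
    """Build the voxel phantom from its box description."""
    lo = np.asarray(spec.grid_lo, float)
    hi = np.asarray(spec.grid_hi, float)
    shape = np.round((hi - lo) / spec.voxel_mm).astype(int)
    dens = np.zeros(tuple(shape))

    def _slice(a, b):
        i0 = np.clip(np.floor((np.asarray(a) - lo) / spec.voxel_mm).astype(int), 0, shape)
        i1 = np.clip(np.ceil((np.asarray(b) - lo) / spec.voxel_mm).astype(int), 0, shape)
        return tuple(slice(int(x), int(y)) for x, y in zip(i0, i1))

    dens[_slice(spec.body_lo, spec.body_hi)] = 1.0
    if spec.cavity_lo is not None:
        clo, chi = np.asarray(spec.cavity_lo, float), np.asarray(spec.cavity_hi, float)
        if np.any(clo < np.asarray(spec.body_lo)) or np.any(chi > np.asarray(spec.body_hi)):
            raise ValueError("cavity box must lie inside the body box")
        if not 0.0 <= spec.fill <= 1.0:
            raise ValueError("fill fraction must lie in [0, 1]")
        rho = spec.rho_cavity + spec.fill * (1.0 - spec.rho_cavity)
        dens[_slice(clo, chi)] = rho
    return Phantom(densities=dens, origin=lo, voxel_mm=spec.voxel_mm)


def build_plan(scenario: ScenarioConfig) -> list[PencilBeam]:
    """Deterministic plan from the scenario seed: spot grid x energy slices."""
    spec = scenario.plan
    rng = np.random.default_rng([int(scenario.seed) % (2**31), 7])
    coords = np.arange(-spec.half_extent_mm, spec.half_extent_mm + 1e-9, spec.spacing_mm)
    energies = bragg_kleeman_energy(
        np.asarray(spec.end_depths_mm) + scenario.range_shifter_wet_mm
    )
    lo, hi = spec.n_ions_range
    pbs: list[PencilBeam] = []
    pb_id = 0
    for e in energies:
        for y in coords:
            for x in coords:
                n_ions = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
                pbs.append(
                    PencilBeam(pb_id=pb_id, spot_xy=(float(x), float(y)),
                               energy=float(e), n_ions=n_ions,
                               field_angle=spec.field_angle)
                )
                pb_id += 1
    return pbs


def _highland_theta0(energy_mev: np.ndarray, wepl_mm: np.ndarray) -> np.ndarray:
    """Highland RMS projected scattering angle for protons through water."""
    t = np.asarray(energy_mev, float)
    e_tot = t + PROTON_MASS_MEV
    pc = np.sqrt(t * (t + 2.0 * PROTON_MASS_MEV))
    pbeta = pc * pc / e_tot
    xr = np.clip(np.asarray(wepl_mm, float), 1e-3, None) / X0_WATER_MM
    corr = np.clip(1.0 + 0.038 * np.log(xr), 0.0, None)
    return 13.6 / pbeta * np.sqrt(xr) * corr


def _smear_directions(d: np.ndarray, theta0: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    """Add two independent N(0, theta0) transverse angular kicks (small-angle)."""
    ref = np.zeros_like(d)
    ref[:, 1] = 1.0
    near_pole = np.abs(d[:, 1]) > 0.9
    ref[near_pole] = [1.0, 0.0, 0.0]
    e1 = np.cross(ref, d)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(d, e1)
    kick1 = rng.normal(0.0, theta0)
    kick2 = rng.normal(0.0, theta0)
    out = d + kick1[:, None] * e1 + kick2[:, None] * e2
    return out / np.linalg.norm(out, axis=1, keepdims=True)


def _grid_exit_length(phantom: Phantom, starts: np.ndarray,
                      dirs: np.ndarray) -> np.ndarray:
    """Distance from each (interior) start point to the grid bounding box exit."""
    lo, hi = phantom.extent[:, 0], phantom.extent[:, 1]
    with np.errstate(divide="ignore", invalid="ignore"):
        t_lo = (lo - starts) / dirs
        t_hi = (hi - starts) / dirs
    t_far = np.maximum(t_lo, t_hi)
    t_far[~np.isfinite(t_far)] = np.inf
    return np.clip(t_far.min(axis=1), 0.0, None)


def _apply_dead_time(t_sorted: np.ndarray, tau: float) -> np.ndarray:
    """Non-paralyzable dead time: boolean accept mask over sorted arrival times."""
    keep = np.ones(len(t_sorted), dtype=bool)
    last = -np.inf
    for i, ti in enumerate(t_sorted):
        if ti - last < tau:
            keep[i] = False
        else:
            last = ti
    return keep


def simulate_fraction(
    scenario: ScenarioConfig,
    fraction_id: int,
    plan: list[PencilBeam] | None = None,
) -> SimulatedFraction:
    """Simulate one treatment fraction; fully determined by (scenario, fraction_id).

    Returns the recorded track list (room frame, detector-pose offset applied)
    and the linked truth table.  ``plan`` may be passed in to share the plan
    object across fractions; it is rebuilt deterministically otherwise.
    """
    rng = np.random.default_rng([int(scenario.seed) % (2**31), 1000 + int(fraction_id)])
    phantom = make_phantom(scenario.phantom)
    if plan is None:
        plan = build_plan(scenario)
    pose = scenario.pose()
    ux, vy = pose.face_axes
    face_center = pose.translation
    half = scenario.detector_half_size_mm
    eff = scenario.track_efficiency()
    mu = scenario.mu_wepl
    # calibration so that `yield_per_pb` is the mean *detected* patient count
    nominal_exit_wepl = 60.0
    eff_cal = eff * np.exp(-mu * nominal_exit_wepl)

    end_ranges = compute_end_ranges(plan, phantom, scenario.range_shifter_wet_mm)
    wepl = np.array([er.wepl for er in end_ranges])
    n_ions = np.array([pb.n_ions for pb in plan])
    mean_wepl = wepl.mean() if wepl.mean() > 0 else 1.0
    yields = scenario.yield_per_pb * (n_ions / n_ions.mean()) * (wepl / mean_wepl)

    rs_half = 0.5 * scenario.rs_thickness_mm
    r = scenario.rs_fraction
    rs_gen_mean = yields * (r / (1.0 - r)) / eff if r < 1.0 else yields * 0.0

    # cumulative WEPL per unique beam column for emission-depth inversion
    zlo, zhi = phantom.extent[2]
    zgrid = np.arange(zlo, zhi + 0.5, 1.0)
    spot_xy = np.array([pb.spot_xy for pb in plan])
    ucols, col_of_pb = np.unique(spot_xy, axis=0, return_inverse=True)
    zmid = 0.5 * (zgrid[:-1] + zgrid[1:])
    mid_pts = np.empty((len(ucols), len(zmid), 3))
    mid_pts[:, :, 0] = ucols[:, 0][:, None]
    mid_pts[:, :, 1] = ucols[:, 1][:, None]
    mid_pts[:, :, 2] = zmid[None, :]
    rho = phantom.density_at(mid_pts.reshape(-1, 3)).reshape(len(ucols), len(zmid))
    cum_cols = np.concatenate(
        [np.zeros((len(ucols), 1)), np.cumsum(rho * np.diff(zgrid), axis=1)], axis=1
    )

    n_pat = rng.poisson(np.clip(np.where(wepl > 0, yields / eff_cal, 0.0), 0.0, None))

    pb_idx_pat = np.repeat(np.arange(len(plan)), n_pat)
    u = rng.uniform(size=len(pb_idx_pat)) * wepl[pb_idx_pat]
    col = col_of_pb[pb_idx_pat]
    # invert the per-column cumulative WEPL with one flat searchsorted
    nz = cum_cols.shape[1]
    offs = cum_cols[:, -1].max() + 1.0
    flat_cum = (cum_cols + offs * np.arange(len(ucols))[:, None]).ravel()
    k = np.searchsorted(flat_cum, u + offs * col, side="right")
    k = np.clip(k, 1, len(flat_cum) - 1)
    c_hi = flat_cum[k] - offs * col
    c_lo = flat_cum[k - 1] - offs * col
    k_loc = k - col * nz
    dz = zgrid[k_loc] - zgrid[k_loc - 1]
    frac = np.where(c_hi > c_lo, (u - c_lo) / np.maximum(c_hi - c_lo, 1e-30), 1.0)
    z_pat = zgrid[k_loc - 1] + np.clip(frac, 0.0, 1.0) * dz

    def _face_rays(em_pts, count):
        fu = rng.uniform(-half, half, size=count)
        fv = rng.uniform(-half, half, size=count)
        tg = face_center[None, :] + fu[:, None] * ux[None, :] + fv[:, None] * vy[None, :]
        d = tg - em_pts
        d /= np.linalg.norm(d, axis=1, keepdims=True)
        return tg, d

    # patient candidates: exit rays, stepped water-equivalent exit depth,
    # per-track efficiency and exit attenuation
    pts_p = np.column_stack(
        [spot_xy[pb_idx_pat, 0], spot_xy[pb_idx_pat, 1], z_pat]
    )
    targets_p, dirs_p = _face_rays(pts_p, len(pts_p))
    if len(pts_p):
        lengths = _grid_exit_length(phantom, pts_p, dirs_p)
        wepl_p = phantom.wepl_along_rays(pts_p, dirs_p, lengths, step_mm=2.5)
    else:
        wepl_p = np.zeros(0)
    surv_p = np.exp(-mu * wepl_p)
    keep_p = rng.uniform(size=len(pts_p)) < eff * surv_p

    # RS candidates: sized from the *realised* patient survival so the
    # detected RS fraction matches rs_fraction; analytic slab-crossing depth
    s_rel = float(surv_p.mean()) / np.exp(-mu * nominal_exit_wepl) if len(surv_p) else 1.0
    n_rs = rng.poisson(rs_gen_mean * s_rel)
    pb_idx_rs = np.repeat(np.arange(len(plan)), n_rs)
    z_rs = rng.uniform(
        scenario.rs_z_mm - rs_half, scenario.rs_z_mm + rs_half, size=len(pb_idx_rs)
    )
    pts_r = np.column_stack([spot_xy[pb_idx_rs, 0], spot_xy[pb_idx_rs, 1], z_rs])
    targets_r, dirs_r = _face_rays(pts_r, len(pts_r))
    if len(pts_r):
        dzr = np.clip(dirs_r[:, 2], 1e-6, None)
        wepl_r = np.clip(
            (scenario.rs_z_mm + rs_half - pts_r[:, 2]) / dzr, 0.0, 4.0 * rs_half
        )
    else:
        wepl_r = np.zeros(0)
    keep_r = rng.uniform(size=len(pts_r)) < eff

    plan_ids = np.array([pb.pb_id for pb in plan], dtype=np.int64)
    pts = np.concatenate([pts_p[keep_p], pts_r[keep_r]])
    targets = np.concatenate([targets_p[keep_p], targets_r[keep_r]])
    dirs = np.concatenate([dirs_p[keep_p], dirs_r[keep_r]])
    exit_wepl = np.concatenate([wepl_p[keep_p], wepl_r[keep_r]])
    pb_index = np.concatenate([pb_idx_pat[keep_p], pb_idx_rs[keep_r]])
    origin = np.concatenate(
        [np.zeros(int(keep_p.sum()), dtype=np.int8), np.ones(int(keep_r.sum()), dtype=np.int8)]
    )
    pbid = plan_ids[pb_index]
    n_det = len(pts)
    if n_det == 0:
        tracks = pd.DataFrame(columns=TRACK_COLUMNS + ["track_id"])
        truth = pd.DataFrame(
            columns=["track_id", "x_true", "y_true", "z_true", "origin", "pb_id"]
        )
        return SimulatedFraction(fraction_id, tracks, truth, plan, scenario, np.zeros(3))

    # multiple-scattering direction smearing (Highland, water)
    energies = rng.uniform(*scenario.fragment_energy_mev, size=n_det)
    theta0 = _highland_theta0(energies, exit_wepl)
    sm_dirs = _smear_directions(dirs, theta0, rng)

    # arrival times: beams delivered in plan order at the slice spill rate
    counts = np.bincount(pb_index, minlength=len(plan))
    n_spots = max(1, len(plan) // max(1, len(scenario.plan.end_depths_mm)))
    slice_rates = np.array(
        [scenario.spill.rate_for_slice(i // n_spots) for i in range(len(plan))]
    )
    durations = counts / slice_rates
    starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
    times = starts[pb_index] + rng.uniform(size=n_det) * durations[pb_index]

    tsort = np.argsort(times, kind="stable")
    pts, pbid, origin, sm_dirs, targets, times = (
        pts[tsort], pbid[tsort], origin[tsort], sm_dirs[tsort], targets[tsort], times[tsort]
    )
    if scenario.apply_dead_time and scenario.tau_s > 0:
        acc = _apply_dead_time(times, scenario.tau_s)
        pts, pbid, origin, sm_dirs, targets, times = (
            pts[acc], pbid[acc], origin[acc], sm_dirs[acc], targets[acc], times[acc]
        )

    # recorded track: point at the detector face, direction detector -> patient,
    # pose placement error applied to the recorded coordinates
    pose_offset = (
        rng.normal(0.0, np.asarray(scenario.sigma_xyz, float))
        if scenario.apply_pose_offset
        else np.zeros(3)
    )
    rec_pts = targets + pose_offset
    rec_dirs = -sm_dirs

    track_id = np.arange(len(rec_pts))
    tracks = pd.DataFrame(
        {
            "x": rec_pts[:, 0], "y": rec_pts[:, 1], "z": rec_pts[:, 2],
            "dx": rec_dirs[:, 0], "dy": rec_dirs[:, 1], "dz": rec_dirs[:, 2],
            "t": times, "pb_id": pbid.astype(np.int64),
            "fraction_id": np.full(len(rec_pts), int(fraction_id), dtype=np.int64),
            "track_id": track_id,
        }
    )
    truth = pd.DataFrame(
        {
            "track_id": track_id,
            "x_true": pts[:, 0], "y_true": pts[:, 1], "z_true": pts[:, 2],
            "origin": np.where(origin == 0, "patient", "range_shifter"),
            "pb_id": pbid.astype(np.int64),
        }
    )
    return SimulatedFraction(int(fraction_id), tracks, truth, plan, scenario, pose_offset)


def scenario_suite(
    name: str,
    base_seed: int = 0,
    n_null_fractions: int = 2,
    fills: tuple[float, ...] = (1.0, 0.9, 0.75, 0.5, 0.0),
    base: ScenarioConfig | None = None,
    cavity_lo: tuple[float, float, float] = (-25.0, -25.0, 40.0),
    cavity_hi: tuple[float, float, float] = (25.0, 25.0, 60.0),
) -> list[ScenarioConfig]:
    """Named scenario families.

    ``null``
        identical phantom and plan, one config per fraction (seeded alike; the
        per-fraction randomness comes from the fraction id).
    ``cavity_progression``
        a cavity box gradually emptying across fractions (fill 1.0 -> 0.0);
        the first entry (fill 1.0) is the reference fraction.
    """
    if base is None:
        base = ScenarioConfig(seed=base_seed)
    else:
        base = replace(base, seed=base_seed)

    if name == "null":
        return [base for _ in range(n_null_fractions)]
    if name == "cavity_progression":
        out = []
        for f in fills:
            ph = replace(base.phantom, cavity_lo=cavity_lo, cavity_hi=cavity_hi,
                         fill=float(f))
            out.append(replace(base, phantom=ph))
        return out
    raise ValueError(f"unknown scenario suite {name!r}")
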