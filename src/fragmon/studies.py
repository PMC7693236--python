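"""End-to-end study drivers: calibration, resolution, change detection, dead time.

These functions wire the simulator and the analysis pipeline into the named
studies the method is validated with:

* ``null_calibration`` - two fractions of the same scenario; the chi-square
  p-value distribution must be flat and the flag rate must equal alpha.
* ``backprojection_resolution`` - dispersion of the reconstructed PCA about
  the true emission point (the multiple-scattering-limited resolution).
* ``cavity_progression`` - flag counts across a gradually emptying cavity,
  with localisation of the flagged-SPB PCA cloud.
* ``deadtime_study`` - same scenario at two very different spill rates, with
  and without livetime correction.
* ``range_elongation`` - 2D-map distal-edge reading of an imposed range shift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .compare import CompareConfig, FractionReport, compare_fractions
from .geometry import compute_pca_batch
from .pipeline import PipelineConfig, ProcessedFraction, plan_spbs, process_fraction
from .range_maps import build_map2d, classify_overlap, distal_edge_shift
from .synthetic import (
    ScenarioConfig,
    SimulatedFraction,
    build_plan,
    make_phantom,
    scenario_suite,
    simulate_fraction,
)

__all__ = [
    "simulate_and_process",
    "null_calibration",
    "backprojection_resolution",
    "cavity_progression",
    "deadtime_study",
    "range_elongation",
]


def _pipe_config(scenario: ScenarioConfig, **overrides) -> PipelineConfig:
    return PipelineConfig(rs_z_mm=scenario.rs_z_mm, **overrides)


def simulate_and_process(
    scenario: ScenarioConfig,
    fraction_id: int,
    spbs=None,
    plan=None,
    pipe: PipelineConfig | None = None,
) -> tuple[SimulatedFraction, ProcessedFraction]:
    """Simulate one fraction and run it through the analysis pipeline."""
    if plan is None:
        plan = build_plan(scenario)
    if spbs is None:
        spbs = plan_spbs(plan, make_phantom(scenario.phantom),
                         scenario.range_shifter_wet_mm)
    if pipe is None:
        pipe = _pipe_config(scenario)
    sim = simulate_fraction(scenario, fraction_id, plan=plan)
    proc = process_fraction(sim.tracks, plan, spbs, scenario.pose(), pipe)
    return sim, proc


@dataclass
class NullCalibrationResult:
    report: FractionReport
    flag_rate: float
    n_tested: int
    p_values: np.ndarray


def null_calibration(
    seed: int = 0,
    base: ScenarioConfig | None = None,
    alpha: float = 0.02,
    compare: CompareConfig | None = None,
) -> NullCalibrationResult:
    """Type-I-error calibration: two seeded deliveries of the identical scenario."""
    cfgs = scenario_suite("null", base_seed=seed, base=base)
    plan = build_plan(cfgs[0])
    spbs = plan_spbs(plan, make_phantom(cfgs[0].phantom), cfgs[0].range_shifter_wet_mm)
    _, ref = simulate_and_process(cfgs[0], 0, spbs, plan)
    _, test = simulate_and_process(cfgs[1], 1, spbs, plan)
    cc = compare or CompareConfig(alpha=alpha, seed=seed)
    report = compare_fractions(ref, test, cc)
    rate = report.n_flagged / report.n_tested if report.n_tested else float("nan")
    return NullCalibrationResult(
        report=report, flag_rate=rate, n_tested=report.n_tested,
        p_values=report.p_values,
    )


def backprojection_resolution(
    seed: int = 0, base: ScenarioConfig | None = None
) -> dict:
    """Dispersion of the PCA about the true emission point, patient tracks only.

    Returns the standard deviation (mm) of the 3D distance between each
    recorded patient track's PCA and its true emission point, together with
    companion statistics (RMS, per-axis dispersions).
    """
    scenario = base if base is not None else ScenarioConfig(seed=seed)
    scenario = replace(scenario, seed=seed, apply_pose_offset=False)
    plan = build_plan(scenario)
    sim = simulate_fraction(scenario, 0, plan=plan)
    spot_by_pb = {pb.pb_id: pb.spot_xy for pb in plan}

    truth = sim.truth
    pat = (truth["origin"] == "patient").to_numpy()
    tr = sim.tracks.loc[pat]
    th = truth.loc[pat]
    pts = tr[["x", "y", "z"]].to_numpy(float)
    dirs = tr[["dx", "dy", "dz"]].to_numpy(float)
    axes = np.zeros((len(tr), 3))
    uniq, inverse = np.unique(tr["pb_id"].to_numpy(), return_inverse=True)
    axes[:, :2] = np.array([spot_by_pb[i] for i in uniq])[inverse]
    pos, miss, s_beam, _ = compute_pca_batch(pts, dirs, axes)

    true_pts = th[["x_true", "y_true", "z_true"]].to_numpy(float)
    delta = pos - true_pts
    dist = np.linalg.norm(delta, axis=1)
    return {
        "sigma_mm": float(dist.std()),
        "rms_mm": float(np.sqrt(np.mean(dist**2))),
        "sigma_z_mm": float(delta[:, 2].std()),
        "n_tracks": int(len(dist)),
    }


@dataclass
class ProgressionResult:
    fills: tuple[float, ...]
    flag_counts: list[int]
    n_tested: list[int]
    null_expectation: float
    reports: list[FractionReport]
    cavity_lo: np.ndarray
    cavity_hi: np.ndarray
    flagged_centroids: list[list[np.ndarray]]

    def localization_fraction(self, margin_mm: float = 15.0) -> float:
        """Fraction of flagged-SPB PCA centroids within ``margin_mm`` of the
        cavity bounding box, pooled over the non-reference fractions."""
        dists = []
        for cents in self.flagged_centroids:
            for c in cents:
                d = np.maximum(
                    np.maximum(self.cavity_lo - c, c - self.cavity_hi), 0.0
                )
                dists.append(np.linalg.norm(d))
        if not dists:
            return float("nan")
        return float(np.mean(np.asarray(dists) <= margin_mm))


def cavity_progression(
    seed: int = 0,
    base: ScenarioConfig | None = None,
    fills: tuple[float, ...] = (1.0, 0.9, 0.75, 0.5, 0.0),
    compare: CompareConfig | None = None,
) -> ProgressionResult:
    """Run one seeded repeat of the gradual cavity-emptying scenario.

    The first (fully filled) fraction is the reference; every other fraction
    is compared against it.  Flag counts are expected to grow as the cavity
    empties, with the flagged PCA cloud concentrating at the cavity.
    """
    cfgs = scenario_suite("cavity_progression", base_seed=seed, fills=fills, base=base)
    plan = build_plan(cfgs[0])
    # SPB definitions from the planning (filled) phantom, shared by all fractions
    spbs = plan_spbs(plan, make_phantom(cfgs[0].phantom), cfgs[0].range_shifter_wet_mm)
    cc = compare or CompareConfig(seed=seed)

    _, ref = simulate_and_process(cfgs[0], 0, spbs, plan)
    reports: list[FractionReport] = []
    centroids: list[list[np.ndarray]] = []
    for k, cfg in enumerate(cfgs[1:], start=1):
        _, proc = simulate_and_process(cfg, k, spbs, plan)
        rep = compare_fractions(ref, proc, cc)
        reports.append(rep)
        cents = []
        for r in rep.results:
            if r.flagged:
                cloud = np.concatenate(
                    [ref.spb_pca_positions[r.spb_id], proc.spb_pca_positions[r.spb_id]]
                )
                cents.append(cloud.mean(axis=0))
        centroids.append(cents)

    return ProgressionResult(
        fills=fills,
        flag_counts=[r.n_flagged for r in reports],
        n_tested=[r.n_tested for r in reports],
        null_expectation=float(np.mean([cc.alpha * r.n_tested for r in reports])),
        reports=reports,
        cavity_lo=np.asarray(cfgs[1].phantom.cavity_lo, float),
        cavity_hi=np.asarray(cfgs[1].phantom.cavity_hi, float),
        flagged_centroids=centroids,
    )


def deadtime_study(
    seed: int = 0,
    rates: tuple[float, float] = (2e4, 8e4),
    base: ScenarioConfig | None = None,
    compare: CompareConfig | None = None,
) -> dict:
    """Same scenario at two spill rates, compared with and without livetime weights."""
    base = base if base is not None else ScenarioConfig()
    cfg_a = replace(base, seed=seed, spill=replace(base.spill, rate_levels=(rates[0],)))
    cfg_b = replace(base, seed=seed, spill=replace(base.spill, rate_levels=(rates[1],)))
    plan = build_plan(cfg_a)
    spbs = plan_spbs(plan, make_phantom(cfg_a.phantom), cfg_a.range_shifter_wet_mm)
    cc = compare or CompareConfig(seed=seed)

    sim_a = simulate_fraction(cfg_a, 0, plan=plan)
    sim_b = simulate_fraction(cfg_b, 1, plan=plan)
    out = {}
    for corrected in (True, False):
        pipe = _pipe_config(cfg_a, correct_dead_time=corrected)
        pa = process_fraction(sim_a.tracks, plan, spbs, cfg_a.pose(), pipe)
        pb = process_fraction(sim_b.tracks, plan, spbs, cfg_b.pose(), pipe)
        rep = compare_fractions(pa, pb, cc)
        key = "corrected" if corrected else "uncorrected"
        out[key] = rep
    return out


def range_elongation(
    seed: int = 0,
    delta_wepl_mm: float = 10.0,
    base: ScenarioConfig | None = None,
) -> dict:
    """Impose a known water-equivalent range elongation and read it back.

    The test phantom carries a cavity whose fill is chosen so rays crossing it
    lose ``delta_wepl_mm`` of water-equivalent depth, elongating the range by
    the same amount (the material beyond the cavity is water).  Returns the 2D
    maps, the overlap classification and the per-column distal-edge shifts.
    """
    base = base if base is not None else ScenarioConfig()
    base = replace(base, apply_pose_offset=False)
    cfgs = scenario_suite("cavity_progression", base_seed=seed, fills=(1.0,), base=base)
    ref_cfg = cfgs[0]
    ph = ref_cfg.phantom
    thickness = ph.cavity_hi[2] - ph.cavity_lo[2]
    fill = 1.0 - delta_wepl_mm / (thickness * (1.0 - ph.rho_cavity))
    if not 0.0 <= fill <= 1.0:
        raise ValueError("delta_wepl_mm not achievable with this cavity geometry")
    test_cfg = replace(ref_cfg, phantom=replace(ph, fill=fill))

    plan = build_plan(ref_cfg)
    spbs = plan_spbs(plan, make_phantom(ref_cfg.phantom), ref_cfg.range_shifter_wet_mm)
    _, ref = simulate_and_process(ref_cfg, 0, spbs, plan)
    _, test = simulate_and_process(test_cfg, 1, spbs, plan)

    # horizontal-plane slab through the cavity: only beams inside the cavity's
    # y band contribute, so per-x-column edges read the imposed elongation
    y_lo, y_hi = ph.cavity_lo[1], ph.cavity_hi[1]

    def _slab(proc):
        pos = proc.patient_positions()
        w = proc.patient_weights()
        sel = (pos[:, 1] >= y_lo) & (pos[:, 1] < y_hi)
        return pos[sel], w[sel]

    bins = np.arange(-40.0, 165.0, 5.0)
    pos_r, w_r = _slab(ref)
    pos_t, w_t = _slab(test)
    map_ref = build_map2d(pos_r, w_r, edges_x=np.arange(-45.0, 50.0, 5.0), edges_z=bins)
    map_test = build_map2d(pos_t, w_t, edges_x=np.arange(-45.0, 50.0, 5.0), edges_z=bins)
    overlap = classify_overlap(map_ref, map_test)
    shifts = distal_edge_shift(map_ref, map_test)
    return {
        "map_ref": map_ref,
        "map_test": map_test,
        "overlap": overlap,
        "shifts": shifts,
        "cavity_x": (ph.cavity_lo[0], ph.cavity_hi[0]),
        "imposed_mm": delta_wepl_mm,
    }
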