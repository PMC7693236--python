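"""Per-SPB statistical comparison of two fractions and fraction-level reporting.

For every Super Pencil Beam with enough statistics on both sides, the two
livetime-weighted emission profiles are compared with a binned chi-square test
(primary) and a two-sample Kolmogorov-Smirnov test (binning-independent
cross-check).  SPBs with a chi-square p-value below ``alpha`` (default 2%) are
flagged, and the PCA clouds of flagged SPBs are pooled so that a change can be
localised in space.

Two chi-square normalisations are provided:

``area``
    both profiles scaled to unit area; tests shape only.  With unit weights,
    no systematic band and equal totals this reduces exactly to the textbook
    two-histogram statistic sum (n_i - m_i)^2 / (n_i + m_i) with ndf = bins - 1.
``exposure``
    absolute weighted counts are compared directly (ndf = bins).  Valid because
    the two fractions deliver the same plan, so after livetime correction the
    expected yields per SPB are equal; this retains sensitivity to efficiency-
    scale effects (notably an uncorrected dead-time difference) that a pure
    shape test cancels.  This is the pipeline default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

from .geometry import DetectorPose, compute_pca_batch
from .profiles import EmissionProfile, build_profile, leading_edge_mask

__all__ = [
    "ComparisonResult",
    "FractionReport",
    "SystematicBand",
    "RsTrackSet",
    "chi2_profiles",
    "ks_profiles",
    "positioning_systematic",
    "compare_fractions",
    "CompareConfig",
]

log = logging.getLogger(__name__)


class UndefinedComparisonError(ValueError):
    """Fewer than two usable bins: the chi-square test is undefined."""


@dataclass(frozen=True)
class ComparisonResult:
    spb_id: int
    chi2: float
    ndf: int
    p_chi2: float
    p_ks: float
    n_ref: int
    n_test: int
    flagged: bool


@dataclass(frozen=True)
class SystematicBand:
    """Per-bin positioning systematic on the unit-area profile scale."""

    sigma_sys: np.ndarray
    shift_trials: int
    mean_shift: float = 0.0  # ref-vs-test RS profile mean offset, mm (diagnostic)

    def __post_init__(self):
        s = np.asarray(self.sigma_sys, float)
        if np.any(s < 0):
            raise ValueError("sigma_sys must be >= 0")
        object.__setattr__(self, "sigma_sys", s)

    @classmethod
    def zero(cls, n_bins: int) -> "SystematicBand":
        return cls(sigma_sys=np.zeros(n_bins), shift_trials=0)


@dataclass
class FractionReport:
    reference_fraction_id: int
    test_fraction_id: int
    results: list[ComparisonResult]
    n_flagged: int
    flagged_pca_cloud: np.ndarray  # (N, 3) PCA positions of all flagged SPBs
    n_tested: int = 0
    alpha: float = 0.02
    systematic: SystematicBand | None = None

    def to_dict(self) -> dict:
        return {
            "reference_fraction_id": int(self.reference_fraction_id),
            "test_fraction_id": int(self.test_fraction_id),
            "alpha": self.alpha,
            "n_tested": int(self.n_tested),
            "n_flagged": int(self.n_flagged),
            "null_expectation": self.alpha * self.n_tested,
            "results": [
                {
                    "spb_id": int(r.spb_id),
                    "chi2": float(r.chi2),
                    "ndf": int(r.ndf),
                    "p_chi2": float(r.p_chi2),
                    "p_ks": float(r.p_ks),
                    "n_ref": int(r.n_ref),
                    "n_test": int(r.n_test),
                    "flagged": bool(r.flagged),
                }
                for r in self.results
            ],
        }

    @property
    def p_values(self) -> np.ndarray:
        return np.array([r.p_chi2 for r in self.results])


def chi2_profiles(
    ref: EmissionProfile,
    test: EmissionProfile,
    mask: np.ndarray | None = None,
    sys: SystematicBand | None = None,
    alpha: float = 0.02,
    min_entries: int = 100,
    normalization: str = "area",
    min_bin_total: float = 5.0,
) -> ComparisonResult:
    """Binned chi-square homogeneity test between two emission profiles.

    Bins outside ``mask`` or whose summed content across both profiles falls
    below ``min_bin_total`` (the classic chi-square validity floor; such bins
    are too sparse for the Gaussian approximation and only narrow the
    statistic's null distribution) are skipped.  Per-bin variances come from
    the summed squared weights (leading-order propagation), inflated by the
    positioning systematic band.
    """
    if not np.array_equal(ref.bin_edges, test.bin_edges):
        raise ValueError("profiles must share identical binning")
    n_bins = len(ref.weights)
    if mask is None:
        mask = np.ones(n_bins, dtype=bool)
    ssys = np.zeros(n_bins) if sys is None else sys.sigma_sys
    if len(ssys) != n_bins:
        raise ValueError("systematic band binning mismatch")

    W, M = ref.total, test.total
    usable = mask & ((ref.weights + test.weights) >= max(min_bin_total, 1e-300))
    if usable.sum() < 2 or W == 0 or M == 0:
        raise UndefinedComparisonError("fewer than two usable bins")

    if normalization == "area":
        p = ref.weights / W
        q = test.weights / M
        var = ref.sumw2 / W**2 + test.sumw2 / M**2 + ssys**2
        ndf = int(usable.sum()) - 1
    elif normalization == "exposure":
        p = ref.weights
        q = test.weights
        scale = 0.5 * (W + M)
        var = ref.sumw2 + test.sumw2 + (ssys * scale) ** 2
        ndf = int(usable.sum())
    else:
        raise ValueError(f"unknown normalization {normalization!r}")

    num = (p - q)[usable] ** 2
    den = var[usable]
    chi2 = float(np.sum(num / den))
    p_chi2 = float(stats.chi2.sf(chi2, ndf))
    flagged = bool(p_chi2 < alpha and ref.n_raw >= min_entries and test.n_raw >= min_entries)
    return ComparisonResult(
        spb_id=ref.spb_id,
        chi2=chi2,
        ndf=ndf,
        p_chi2=p_chi2,
        p_ks=np.nan,
        n_ref=ref.n_raw,
        n_test=test.n_raw,
        flagged=flagged,
    )


def ks_profiles(z_ref: np.ndarray, z_test: np.ndarray,
                mask_window: tuple[float, float] | None = None) -> float:
    """Two-sample KS p-value (asymptotic) on unbinned axial positions.

    ``mask_window`` restricts both samples to the unmasked z range so the KS
    cross-check sees the same region as the chi-square test.  Returns NaN when
    either restricted sample is empty.
    """
    a = np.asarray(z_ref, float)
    b = np.asarray(z_test, float)
    if mask_window is not None:
        lo, hi = mask_window
        a = a[(a >= lo) & (a < hi)]
        b = b[(b >= lo) & (b < hi)]
    if len(a) == 0 or len(b) == 0:
        return float("nan")
    return float(stats.ks_2samp(a, b, method="asymp").pvalue)


def shift_response(track_dirs: np.ndarray) -> np.ndarray:
    """Per-track response of the PCA axial coordinate to a rigid translation.

    For axis = +z and unit track direction d with b = d_z, a translation
    ``delta`` of the track point moves s_beam by ``delta . v`` with
    ``v = (-b dx / (1-b^2), -b dy / (1-b^2), 1)``.
    """
    d = np.asarray(track_dirs, float)
    b = d[:, 2]
    denom = np.clip(1.0 - b * b, 1e-12, None)
    return np.column_stack(
        [-b * d[:, 0] / denom, -b * d[:, 1] / denom, np.ones(len(d))]
    )


def estimate_pose_shift(
    rs_ref: "RsTrackSet", rs_test: "RsTrackSet", n_dir_bins: int = 3
) -> np.ndarray:
    """Relative detector-translation estimate from range-shifter fragments.

    The RS is anatomy-independent, so any difference between its ref and test
    PCA profiles reflects the relative detector placement.  Tracks are binned
    by direction (quantiles of dx, dy); within each cell the mean axial PCA
    offset equals ``v̄ . delta``, giving an overdetermined linear system for
    the 3-vector ``delta`` solved by weighted least squares.
    """
    if len(rs_ref.points) == 0 or len(rs_test.points) == 0:
        return np.zeros(3)

    def _sv(ts: RsTrackSet):
        _, _, s, _ = compute_pca_batch(ts.points, ts.directions, ts.axis_origins)
        return s, shift_response(ts.directions)

    s_r, v_r = _sv(rs_ref)
    s_t, v_t = _sv(rs_test)
    qx = np.quantile(rs_ref.directions[:, 0], np.linspace(0, 1, n_dir_bins + 1)[1:-1])
    qy = np.quantile(rs_ref.directions[:, 1], np.linspace(0, 1, n_dir_bins + 1)[1:-1])

    def _cells(ts: RsTrackSet):
        ix = np.searchsorted(qx, ts.directions[:, 0])
        iy = np.searchsorted(qy, ts.directions[:, 1])
        return ix * n_dir_bins + iy

    c_r, c_t = _cells(rs_ref), _cells(rs_test)
    rows, rhs, wts = [], [], []
    for c in range(n_dir_bins * n_dir_bins):
        mr, mt = c_r == c, c_t == c
        if mr.sum() < 20 or mt.sum() < 20:
            continue
        wr, wt = rs_ref.weights[mr], rs_test.weights[mt]
        d_mean = np.average(s_t[mt], weights=wt) - np.average(s_r[mr], weights=wr)
        v_bar = 0.5 * (
            np.average(v_r[mr], axis=0, weights=wr)
            + np.average(v_t[mt], axis=0, weights=wt)
        )
        n_eff = 1.0 / (1.0 / mr.sum() + 1.0 / mt.sum())
        rows.append(v_bar)
        rhs.append(d_mean)
        wts.append(n_eff)
    if len(rows) < 3:
        return np.zeros(3)
    A = np.asarray(rows) * np.sqrt(np.asarray(wts))[:, None]
    b = np.asarray(rhs) * np.sqrt(np.asarray(wts))
    delta, *_ = np.linalg.lstsq(A, b, rcond=None)
    return delta


class RsTrackSet(NamedTuple):
    """Range-shifter-labelled tracks of one fraction, as flat arrays."""

    points: np.ndarray  # (N, 3)
    directions: np.ndarray  # (N, 3)
    axis_origins: np.ndarray  # (N, 3) spot position of each track's PB
    weights: np.ndarray  # (N,) livetime weights


def positioning_systematic(
    rs_ref: RsTrackSet,
    rs_test: RsTrackSet,
    pose: DetectorPose,
    bin_edges: np.ndarray,
    K: int = 50,
    rng: np.random.Generator | int | None = 0,
    max_tracks: int = 20000,
) -> SystematicBand:
    """Positioning-systematic band from range-shifter fragments.

    The RS is a copious anatomy-independent fragment source, so its emission
    profile isolates the effect of the detector placement reproducibility.  For
    each of ``K`` trials an independent pose offset per axis ~ N(0, sigma_xyz)
    is applied to the recorded track points, the PCA projection and unit-area
    profile are rebuilt, and the band is the per-bin standard deviation over
    trials.  Also reports the ref-vs-test RS profile mean offset as an
    alignment diagnostic.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n_bins = len(bin_edges) - 1
    if len(rs_ref.points) == 0 or len(rs_test.points) == 0:
        log.warning("positioning_systematic: no RS tracks, returning zero band")
        return SystematicBand.zero(n_bins)

    pts, dirs, axo, w = rs_ref
    if len(pts) > max_tracks:
        sel = rng.choice(len(pts), size=max_tracks, replace=False)
        pts, dirs, axo, w = pts[sel], dirs[sel], axo[sel], w[sel]

    trials = np.empty((K, n_bins))
    for k in range(K):
        offset = rng.normal(0.0, pose.sigma_xyz)
        _, _, s_beam, _ = compute_pca_batch(pts + offset, dirs, axo)
        hist, _ = np.histogram(s_beam, bins=bin_edges, weights=w)
        tot = hist.sum()
        trials[k] = hist / tot if tot > 0 else hist
    sigma = trials.std(axis=0, ddof=1) if K > 1 else np.zeros(n_bins)

    def _mean(ts: RsTrackSet) -> float:
        _, _, s, _ = compute_pca_batch(ts.points, ts.directions, ts.axis_origins)
        return float(np.average(s, weights=ts.weights))

    return SystematicBand(sigma_sys=sigma, shift_trials=K,
                          mean_shift=_mean(rs_test) - _mean(rs_ref))


def pose_shift_band(
    s_beam: np.ndarray,
    track_dirs: np.ndarray,
    weights: np.ndarray,
    bin_edges: np.ndarray,
    sigma_xyz: np.ndarray,
    normalized: bool = True,
) -> np.ndarray:
    """Per-bin profile sensitivity to the detector placement reproducibility.

    A rigid translation ``delta`` of the recorded track points moves each PCA
    axial coordinate by ``delta . v`` with
    ``v = (-b dx, -b dy, 1 - b dz) / (1 - b^2)`` and ``b = d_z`` (axis = +z);
    note the z coefficient is exactly 1.  The coherent profile shift per
    fraction is therefore Gaussian with variance ``g' Sigma g`` where ``g`` is
    the weighted mean of ``v``, and the induced content systematic in bin i is
    ``|dW/dz|_i`` times that shift scale - the local-gradient propagation of a
    rigid profile displacement.  Both fractions carry independent placement
    errors, hence the sqrt(2).
    """
    n_bins = len(bin_edges) - 1
    if len(s_beam) == 0:
        return np.zeros(n_bins)
    d = np.asarray(track_dirs, float)
    b = d[:, 2]
    denom = np.clip(1.0 - b * b, 1e-12, None)
    v = np.column_stack([-b * d[:, 0] / denom, -b * d[:, 1] / denom, np.ones(len(b))])
    g = np.average(v, axis=0, weights=weights)
    sigma_shift = float(np.sqrt(np.sum((g * np.asarray(sigma_xyz, float)) ** 2)))

    hist, _ = np.histogram(s_beam, bins=bin_edges, weights=weights)
    kernel = np.ones(3) / 3.0
    sm = np.convolve(hist, kernel, mode="same")
    bin_w = np.diff(bin_edges)
    grad = np.gradient(sm) / bin_w
    band = np.sqrt(2.0) * sigma_shift * np.abs(grad)
    if normalized:
        tot = hist.sum()
        if tot > 0:
            band = band / tot
    return band


@dataclass(frozen=True)
class CompareConfig:
    """Knobs of the fraction-to-fraction comparison.

    ``align_with_rs`` subtracts the RS-measured relative axial shift from the
    test fraction before profiling: the range shifter is an anatomy-independent
    fragment source, so this removes the detector-placement misalignment
    without absorbing genuine morphological signal.  ``sys_trials`` controls
    the per-SPB pose-shift systematic band applied on top of the *residual*
    alignment uncertainty ``residual_sigma_mm`` (the part of the placement
    error the RS alignment cannot constrain, per axis).
    """

    alpha: float = 0.02
    min_entries: int = 100
    sys_trials: int = 50
    normalization: str = "exposure"
    seed: int = 0
    align_with_rs: bool = True
    use_systematic: bool = True
    residual_sigma_mm: float = 0.4
    min_bin_total: float = 5.0


def compare_fractions(ref, test, config: CompareConfig = CompareConfig()) -> FractionReport:
    """Compare two processed fractions SPB by SPB.

    ``ref`` and ``test`` are :class:`fragmon.pipeline.ProcessedFraction` objects
    built from the same plan (SPB definitions are plan-derived, hence shared).
    Per SPB with at least ``min_entries`` raw patient PCAs on both sides:
    leading-edge mask from the reference profile, chi-square test, KS
    cross-check, flag at ``p_chi2 < alpha``.
    """
    shared = sorted(set(ref.profiles) & set(test.profiles))
    if not shared:
        raise ValueError("no shared SPBs between fractions")

    # relative alignment from the anatomy-independent RS fragments: estimate
    # the rigid detector-translation offset and undo it track by track
    if config.align_with_rs:
        delta = estimate_pose_shift(ref.rs_tracks, test.rs_tracks)
    else:
        delta = np.zeros(3)
    mean_shift = float(delta[2])
    aligned = bool(np.any(delta != 0.0))
    residual = np.full(3, config.residual_sigma_mm if config.align_with_rs
                       else np.asarray(ref.pose.sigma_xyz, float).max())

    results: list[ComparisonResult] = []
    clouds: list[np.ndarray] = []
    band_used: SystematicBand | None = None
    for spb_id in shared:
        pr = ref.profiles[spb_id]
        if aligned:
            s_t = test.spb_s_beam[spb_id] - shift_response(
                test.spb_track_dirs[spb_id]
            ) @ delta if len(test.spb_s_beam[spb_id]) else test.spb_s_beam[spb_id]
            pt = build_profile(s_t, test.spb_weights[spb_id], pr.bin_edges,
                               spb_id, test.fraction_id)
        else:
            s_t = test.spb_s_beam[spb_id]
            pt = test.profiles[spb_id]
        if pr.n_raw < config.min_entries or pt.n_raw < config.min_entries:
            continue
        mask = leading_edge_mask(pr)
        band: SystematicBand | None = None
        if config.use_systematic:
            sigma = pose_shift_band(
                ref.spb_s_beam[spb_id], ref.spb_track_dirs[spb_id],
                ref.spb_weights[spb_id], pr.bin_edges, residual,
            )
            band = SystematicBand(sigma_sys=sigma, shift_trials=0,
                                  mean_shift=mean_shift)
            band_used = band
        try:
            res = chi2_profiles(
                pr, pt, mask=mask, sys=band, alpha=config.alpha,
                min_entries=config.min_entries, normalization=config.normalization,
                min_bin_total=config.min_bin_total,
            )
        except UndefinedComparisonError:
            log.info("SPB %d: chi-square undefined (too few usable bins), skipped", spb_id)
            continue
        usable_idx = np.nonzero(mask)[0]
        if len(usable_idx):
            window = (pr.bin_edges[usable_idx[0]], pr.bin_edges[-1])
        else:
            window = None
        p_ks = ks_profiles(ref.spb_s_beam[spb_id], s_t, window)
        res = ComparisonResult(**{**res.__dict__, "p_ks": p_ks})
        results.append(res)
        if res.flagged:
            clouds.append(ref.spb_pca_positions[spb_id])
            clouds.append(test.spb_pca_positions[spb_id])

    cloud = np.concatenate(clouds, axis=0) if clouds else np.zeros((0, 3))
    n_flagged = sum(r.flagged for r in results)
    return FractionReport(
        reference_fraction_id=ref.fraction_id,
        test_fraction_id=test.fraction_id,
        results=results,
        n_flagged=n_flagged,
        flagged_pca_cloud=cloud,
        n_tested=len(results),
        alpha=config.alpha,
        systematic=band_used,
    )
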