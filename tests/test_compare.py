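"""Chi-square kernel against hand-computed oracles, KS cross-check, the
positioning systematic, pose-shift estimation and fraction comparison."""

import numpy as np
import pytest
from scipy import stats

from fragmon.compare import (
    CompareConfig,
    RsTrackSet,
    SystematicBand,
    UndefinedComparisonError,
    chi2_profiles,
    compare_fractions,
    estimate_pose_shift,
    ks_profiles,
    pose_shift_band,
    positioning_systematic,
    shift_response,
)
from fragmon.geometry import DetectorPose
from fragmon.profiles import EmissionProfile, uniform_edges


def unit_profile(counts, spb_id=0, fraction_id=0):
    counts = np.asarray(counts, float)
    edges = np.arange(len(counts) + 1) * 5.0
    return EmissionProfile(spb_id, fraction_id, edges, counts, counts,
                           int(counts.sum()))


class TestChi2Kernel:
    def test_hand_oracle_10_20_30(self):
        ref, test = unit_profile([10, 20, 30]), unit_profile([20, 10, 30])
        r = chi2_profiles(ref, test, normalization="area")
        # Σ (n-m)^2/(n+m) = 100/30 + 100/30 = 20/3; 2-dof tail = exp(-x/2)
        assert r.chi2 == pytest.approx(20.0 / 3.0, abs=1e-12)
        assert r.ndf == 2
        assert r.p_chi2 == pytest.approx(np.exp(-10.0 / 3.0), abs=1e-12)

    def test_identity_gives_zero_chi2_unit_p(self):
        p = unit_profile([30, 60, 90])
        r = chi2_profiles(p, p)
        assert r.chi2 == 0.0
        assert r.p_chi2 == 1.0

    def test_area_mode_invariant_under_common_rescaling(self):
        a, b = unit_profile([40, 70, 20]), unit_profile([30, 80, 25])
        r1 = chi2_profiles(a, b, normalization="area")
        a2 = EmissionProfile(0, 0, a.bin_edges, a.weights * 3, a.sumw2 * 9,
                             a.n_raw)
        b2 = EmissionProfile(0, 0, b.bin_edges, b.weights * 3, b.sumw2 * 9,
                             b.n_raw)
        r2 = chi2_profiles(a2, b2, normalization="area")
        assert r2.chi2 == pytest.approx(r1.chi2, rel=1e-9)

    def test_systematic_band_only_decreases_chi2(self):
        a, b = unit_profile([40, 70, 20, 55]), unit_profile([30, 80, 25, 60])
        base = chi2_profiles(a, b)
        for scale in (0.01, 0.05, 0.1):
            sys = SystematicBand(sigma_sys=np.full(4, scale), shift_trials=10)
            r = chi2_profiles(a, b, sys=sys)
            assert r.chi2 < base.chi2
            assert r.p_chi2 > base.p_chi2

    def test_exposure_mode_reduces_to_two_histogram_form(self):
        a, b = unit_profile([25, 50, 12]), unit_profile([30, 41, 20])
        r = chi2_profiles(a, b, normalization="exposure")
        n, m = a.weights, b.weights
        assert r.chi2 == pytest.approx(np.sum((n - m) ** 2 / (n + m)))
        assert r.ndf == 3

    def test_mask_and_validity_floor_drop_bins(self):
        a = unit_profile([50, 40, 2, 30])
        b = unit_profile([50, 45, 1, 35])
        mask = np.array([False, True, True, True])
        r = chi2_profiles(a, b, mask=mask, normalization="exposure")
        assert r.ndf == 2  # bin 0 masked, bin 2 below the validity floor

    def test_under_two_usable_bins_is_undefined(self):
        a, b = unit_profile([50, 0, 0]), unit_profile([55, 0, 0])
        with pytest.raises(UndefinedComparisonError):
            chi2_profiles(a, b)

    def test_binning_mismatch_rejected(self):
        a = unit_profile([1, 2, 3])
        b = EmissionProfile(0, 0, np.arange(4) * 4.0, [1, 2, 3], [1, 2, 3], 6)
        with pytest.raises(ValueError):
            chi2_profiles(a, b)

    def test_null_p_values_uniform_over_repeats(self, rng):
        # two samples of the same density, 400 repeats of the full kernel
        pvals = []
        for _ in range(400):
            lam = rng.uniform(30, 80, 12)
            n = rng.poisson(lam)
            m = rng.poisson(lam)
            a, b = unit_profile(n), unit_profile(m)
            try:
                pvals.append(chi2_profiles(a, b).p_chi2)
            except UndefinedComparisonError:
                continue
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01


class TestKs:
    def test_identical_samples_give_unit_p(self):
        z = np.linspace(0, 50, 300)
        assert ks_profiles(z, z) == pytest.approx(1.0, abs=1e-9)

    def test_null_p_uniform_over_repeats(self, rng):
        pvals = [
            ks_profiles(rng.normal(40, 10, 200), rng.normal(40, 10, 200))
            for _ in range(300)
        ]
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_large_shift_detected_and_matches_reference_implementation(self, rng):
        a = rng.normal(40, 8, 1000)
        b = rng.normal(60, 8, 1000)  # shift >> resolution
        p = ks_profiles(a, b)
        assert p < 1e-6
        assert p == pytest.approx(stats.ks_2samp(a, b, method="asymp").pvalue)

    def test_mask_window_restricts_samples(self):
        a = np.concatenate([np.zeros(50), np.linspace(20, 40, 100)])
        b = np.concatenate([np.full(50, 5.0), np.linspace(20, 40, 100)])
        assert ks_profiles(a, b, (15.0, 45.0)) == pytest.approx(1.0, abs=1e-9)

    def test_empty_sample_undefined(self):
        assert np.isnan(ks_profiles(np.array([]), np.array([1.0])))


def make_rs_set(rng, n=4000, z0=-105.0, spread=9.0):
    """Synthetic RS track lines converging near the detector direction."""
    spots = rng.uniform(-20, 20, (n, 2))
    z = rng.normal(z0, spread, n)
    em = np.column_stack([spots[:, 0], spots[:, 1], z])
    targets = np.column_stack(
        [rng.uniform(250, 500, n), rng.uniform(100, 400, n), rng.uniform(100, 350, n)]
    )
    d = targets - em
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    axes = np.column_stack([spots, np.zeros(n)])
    return RsTrackSet(points=targets, directions=-d, axis_origins=axes,
                      weights=np.ones(n))


class TestPositioningSystematic:
    def test_zero_sigma_gives_zero_band(self, rng):
        rs = make_rs_set(rng)
        pose = DetectorPose.nominal(sigma_xyz=(0, 0, 0))
        band = positioning_systematic(rs, rs, pose, uniform_edges(-150, 0, 5),
                                      K=50, rng=rng)
        assert np.all(band.sigma_sys < 1e-12)

    def test_band_scales_linearly_with_sigma(self, rng):
        rs = make_rs_set(rng, n=20000)
        edges = uniform_edges(-150, 0, 5)
        bands = []
        for s in (0.75, 1.5):
            pose = DetectorPose.nominal(sigma_xyz=(s, s, s))
            b = positioning_systematic(rs, rs, pose, edges, K=120,
                                       rng=np.random.default_rng(7))
            bands.append(b.sigma_sys)
        sel = bands[0] > np.percentile(bands[0], 60)
        ratio = bands[1][sel] / bands[0][sel]
        assert np.median(ratio) == pytest.approx(2.0, rel=0.25)

    def test_band_tracks_profile_gradient(self, rng):
        # steep RS edge: the band should approximate |dP/dz| * effective shift
        rs = make_rs_set(rng, n=30000, spread=4.0)
        edges = uniform_edges(-150, -60, 5)
        pose = DetectorPose.nominal(sigma_xyz=(1.5, 1.5, 1.5))
        band = positioning_systematic(rs, rs, pose, edges, K=150,
                                      rng=np.random.default_rng(3),
                                      max_tracks=30000)
        from fragmon.geometry import compute_pca_batch

        _, _, s_beam, _ = compute_pca_batch(rs.points, rs.directions,
                                            rs.axis_origins)
        hist, _ = np.histogram(s_beam, bins=edges)
        p = hist / hist.sum()
        grad = np.abs(np.gradient(p)) / 5.0
        # effective axial shift scale from the closed-form response
        g = np.average(shift_response(rs.directions), axis=0)
        sigma_shift = np.sqrt(np.sum((g * 1.5) ** 2))
        pred = grad * sigma_shift
        sel = pred > np.percentile(pred, 70)
        ratio = band.sigma_sys[sel] / pred[sel]
        assert 0.7 < np.median(ratio) < 1.3

    def test_no_rs_tracks_warns_and_returns_zero(self, rng):
        empty = RsTrackSet(np.zeros((0, 3)), np.zeros((0, 3)), np.zeros((0, 3)),
                           np.zeros(0))
        band = positioning_systematic(empty, empty, DetectorPose.nominal(),
                                      uniform_edges(-150, 0, 5), K=50, rng=rng)
        assert np.all(band.sigma_sys == 0.0)


class TestPoseShiftBand:
    def test_band_concentrates_at_profile_edges_and_scales_with_sigma(self, rng):
        s = rng.normal(50.0, 8.0, 20000)
        dirs = np.tile([0.8, 0.3, np.sqrt(1 - 0.73)], (20000, 1))
        w = np.ones(20000)
        edges = uniform_edges(0, 100, 5)
        band1 = pose_shift_band(s, dirs, w, edges, np.full(3, 0.5))
        band2 = pose_shift_band(s, dirs, w, edges, np.full(3, 1.0))
        assert np.allclose(band2, 2.0 * band1)  # linear in the shift scale
        centers = 0.5 * (edges[:-1] + edges[1:])
        steep = (np.abs(centers - 50.0) > 4) & (np.abs(centers - 50.0) < 14)
        flat = np.abs(centers - 50.0) <= 3  # symmetry point: gradient ~ 0
        assert band1[steep].mean() > 2 * band1[flat].mean()

    def test_empty_input_gives_zero_band(self):
        band = pose_shift_band(np.zeros(0), np.zeros((0, 3)), np.zeros(0),
                               uniform_edges(0, 50, 5), np.ones(3))
        assert np.all(band == 0.0)


class TestPoseShiftEstimation:
    def test_recovers_injected_translation(self, rng):
        rs = make_rs_set(rng, n=60000)
        delta = np.array([1.1, -0.7, 0.9])
        shifted = RsTrackSet(rs.points + delta, rs.directions, rs.axis_origins,
                             rs.weights)
        est = estimate_pose_shift(rs, shifted)
        # the axial component of the induced PCA shift must match track by track
        v = shift_response(rs.directions)
        assert np.std(v @ est - v @ delta) < 0.15
        assert abs(np.mean(v @ est - v @ delta)) < 0.05

    def test_no_shift_estimates_near_zero(self, rng):
        rs = make_rs_set(rng, n=40000)
        other = make_rs_set(np.random.default_rng(99), n=40000)
        est = estimate_pose_shift(rs, other)
        v = shift_response(rs.directions)
        assert abs(np.mean(v @ est)) < 0.3


class TestCompareFractions:
    def test_self_comparison_flags_nothing(self, processed):
        rep = compare_fractions(processed, processed, CompareConfig(seed=0))
        assert rep.n_flagged == 0
        assert rep.n_tested > 0
        assert all(r.p_chi2 == pytest.approx(1.0) for r in rep.results)

    def test_report_serialises(self, processed):
        rep = compare_fractions(processed, processed, CompareConfig(seed=0))
        d = rep.to_dict()
        assert d["n_flagged"] == 0
        assert len(d["results"]) == rep.n_tested
        assert d["null_expectation"] == pytest.approx(0.02 * rep.n_tested)
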