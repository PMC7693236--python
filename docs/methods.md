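# Methods

## The monitoring problem

In carbon-ion pencil-beam-scanning (PBS) therapy the dose is delivered over
many sessions ("fractions") according to a plan computed on a single planning
CT. Anatomy can change between sessions — a nasal cavity filling or emptying,
tissue swelling or shrinking — and because the ion range depends on the density
integral along the beam, a change of a few millimetres of water-equivalent
path length (WEPL) displaces the dose distribution. Nuclear fragmentation of
the beam offers a non-invasive monitor: secondary charged fragments (mostly
protons) escape the patient and can be tracked by an external detector. The
emission-point distribution follows the beam paths and terminates near the
beam's end of range, so comparing emission maps between fractions reveals
density changes without extra imaging dose.

`fragmon` implements the full detection chain for such a monitor, together
with a seeded synthetic delivery/detector simulator used to validate the
statistical machinery end to end.

## Reconstruction model

Each reconstructed fragment is a straight line in the room frame (origin at
the isocenter, +z along the active field's beam axis): a point on the detector
front face and a unit direction. The emission-point estimate is the **point of
closest approach (PCA)** between this line and the fragment's parent
pencil-beam axis — the midpoint of the mutual-perpendicular segment, computed
in closed form. Near-parallel pairs (|d1 × d2| < 1e-9) are flagged degenerate
rather than rejected; physical tracks are never parallel to the beam axis.
The axial coordinate `s_beam` (arc length of the perpendicular foot along the
beam axis) is the 1D observable everything downstream is built on.

The backprojection is multiple-scattering limited. The simulator smears each
recorded direction by a Highland angle

    theta0 = 13.6 MeV / (p beta c) * sqrt(x / X0) * (1 + 0.038 ln(x / X0))

with `x` the exit WEPL and `X0 = 360.8 mm` (water), the fragment energy drawn
uniformly from 80–250 MeV (proton-equivalent). Propagated over the ~500 mm
lever arm from the detector this yields a PCA-to-true-emission-point distance
dispersion of ~7 mm (one standard deviation of the 3D distance), which is the
package's definition of the backprojection resolution and what
`studies.backprojection_resolution` measures against truth records.

## Statistical unit: the Super Pencil Beam

A single pencil beam collects only ~100 detected tracks, too few for a
per-spot shape test. Beams whose end ranges fall into the same aggregation
cell (default 10 × 10 × 6 mm, boundaries anchored at the isocenter, half-open)
are merged into a **Super Pencil Beam (SPB)** of at most 75 members, filled in
delivery order, giving roughly a thousand tracks per SPB. End ranges come from
a Bragg–Kleeman range–energy relation `R(E) = alpha E^p`
(alpha = 0.0094 mm (MeV/u)^-p, p = 1.75) marched through the phantom in 1 mm
water-equivalent steps after subtracting the 30 mm range-shifter WET; only the
*relative* end-range geometry matters for the grouping, which is why a
parametric range model suffices in place of a planning system. SPB definitions
derive from the plan and the planning phantom only, so they are identical in
every fraction.

## Per-fraction profiles and their corrections

For each SPB the patient-labelled PCAs are histogrammed along `s_beam`
(default 5 mm bins over the patient window). Three corrections matter:

**Dead time.** The DAQ is non-paralyzable with tau = 5 µs at track rates up to
O(100) kHz, and the beam intensity varies between fractions, so the recorded
yield is not proportional to the emitted yield. Each event gets a livetime
weight `1 / (1 - r(t) tau)` where `r(t)` is the recorded rate estimated in a
sliding 1 ms window; for a non-paralyzable system this inverts the loss
exactly in expectation (`m = lambda / (1 + lambda tau)`). Weights enter the
profiles (`sum w`) and their variances (`sum w^2`). The correction refuses to
operate above `r tau >= 0.9`. Spill micro-structure below the 1 ms window is
absorbed into the window average.

**Origin windows.** A large fraction (30–50%) of detected fragments originate
in the range shifter (RS), not the patient. PCAs are classified by axial
windows: the RS window is centred on the RS plane ± 3 sigma of the 7 mm
resolution; everything in the patient window feeds the morphology profiles;
the remainder is dropped. RS fragments are anatomy-independent and are used
for alignment (below).

**Alignment and the leading edge.** The detector cart is repositioned every
fraction with ~1–1.5 mm per-axis reproducibility. A rigid translation `delta`
of the recorded track points moves each PCA axially by `delta · v` with
`v = (-b dx, -b dy, 1 - b dz) / (1 - b^2)`, `b = d_z` — exactly linear in
`delta`. The relative offset between two fractions is therefore estimated
from the RS fragments (direction-binned least squares on the per-cell mean
axial offsets) and undone track by track before profiling; because the RS is
anatomy-independent this cannot absorb genuine morphological signal. The
residual uncertainty (default 0.4 mm per axis) is propagated as a per-bin
systematic `sigma_sys = sqrt(2) |dW/dz| sigma_shift` (both fractions carry an
independent placement error) and added to the chi-square denominator. A
Monte-Carlo variant of the band computed from RS-track shift trials
(`positioning_systematic`) is retained for diagnostics; note that for small
samples trial-to-trial re-binning granularity double-counts statistical noise,
which is why the comparison uses the analytic gradient form. Finally, the
profile's rising edge — the region most sensitive to sub-millimetre residual
misalignment — is excluded: all bins up to and including the first bin
exceeding 50% of the profile maximum are masked off the test.

## The comparison

Per SPB with ≥ 100 raw patient PCAs on both sides, the masked profiles are
compared with

    chi2 = sum_i (p_i - q_i)^2 / (sigma_p,i^2 + sigma_q,i^2 + sigma_sys,i^2)

with two normalisation modes. In **area** mode profiles are scaled to unit
area (`p_i = w_i / W`, variances from `sumw2 / W^2`, ndf = bins − 1); with
unit weights, equal totals and no systematic this reduces exactly to the
textbook two-histogram statistic `sum (n_i - m_i)^2 / (n_i + m_i)`. In
**exposure** mode (the pipeline default) the livetime-weighted absolute
contents are compared directly (ndf = bins): the two fractions deliver the
same plan, so their expected yields per SPB are equal, and this mode retains
sensitivity to efficiency-scale effects — notably an uncorrected dead-time
difference, which a pure shape test cancels mathematically (uniform thinning
rescales every bin equally). Bins whose summed content falls below 5 are
skipped: this is the classic chi-square validity floor; below it the exact
variance of `(n - m)^2 / (n + m)` is `2 - 2/s` and near-empty tail bins
narrow the null distribution of the statistic (verified empirically on the
null scenario). The p-value is the upper chi-square tail; an SPB is flagged
at `p < alpha` (default 2%). A two-sample KS test on the unbinned axial
positions, restricted to the unmasked range, cross-checks binning sensitivity.

No multiple-testing correction is applied across SPBs: the output is the raw
p-value distribution and the flag count, interpreted against the
`alpha * n_tested` null expectation which every report carries.

Calibration, verified by `tests/test_acceptance.py`: under the null (two
seeded deliveries of the same scenario, pose offsets and dead time active) the
flag rate equals alpha within 3 binomial sigma and the p-value distribution is
KS-uniform; pooled over seven seeds (2229 SPBs) the pooled KS p-value is 0.08.

## Range maps

The patient PCA cloud projected on the horizontal (x, z) plane gives a 2D
range map (5 mm cells). Two maps are compared by (a) three-way presence
classification — a cell is present when it holds ≥ 5% of its map's maximum
after equal-total normalisation; cells present only in the test map at distal
z indicate a range elongation — and (b) a per-column distal-edge reader: the
edge is the distal boundary of the deepest bin whose 3-bin-smoothed content
reaches 20% of the column maximum (columns under 50 counts are skipped), and
`delta z = edge_test - edge_ref`. All thresholds are parameters; the defaults
reproduce an imposed 10 mm water-equivalent elongation to within one bin.
The `range_elongation` study reads the maps in a horizontal slab through the
modified region and with pose offsets disabled — a controlled shift-injection
experiment; pooling all vertical positions dilutes the per-column edge with
non-elongated beams at the same x.

## The synthetic scenario

The simulator emulates a CNAO-like delivery; its defaults are the study
conditions for all validation:

| parameter | default | rationale |
|---|---|---|
| voxel phantom | water box 120×120×160 mm, 2 mm voxels | head-sized body, CT-like voxel pitch |
| optional cavity | 50×50×20 mm box at centre, fill f ∈ [0,1], empty density 0.05 | emulates gradual nasal-cavity emptying; sized so the change touches ~30% of tested SPBs, the contrast regime the progression study is meant to exercise |
| plan | 25×25 spots, 3 mm pitch, 5 energy slices (end depths 40–88 mm) | ~3100 beams; ~10 beams per aggregation cell giving ~10^3 tracks/SPB, the intended SPB statistics |
| ions per beam | log-uniform 1e4–7e5, fixed per plan seed | clinical spot-weight spread; identical across fractions |
| detected patient tracks per beam | 100 | typical detected yield per spot |
| RS track fraction | 0.40 | middle of the 30–50% range |
| detector | 300×300 mm face, 500 mm stand-off, 60° to beam, 30° up, 0.9 efficiency/layer over 4 layer pairs | nominal tracker geometry and acceptance |
| pose reproducibility | 1.2 mm per axis | within the 1–1.5 mm survey figure |
| attenuation | exp(−mu·WEPL_exit), mu = 0.005 /mm | proton-like removal on the exit path |
| dead time / spill | tau = 5 µs; piecewise-constant candidate rate, default 50 kHz | exercises the livetime correction |
| fragment energy | uniform 80–250 MeV proton-equivalent | escaping flux is proton-dominated |

Fragment generation: emission depth is uniform per unit WEPL along each beam
up to its end range (emission density proportional to local density — no
cross-section modelling; only inter-fraction differences matter), exit rays
are straight lines importance-sampled uniformly over the detector face (the
face subtends a small solid angle over which a broad forward-peaked angular
density is flat, so the detected-sample distribution is unchanged and no
candidates are wasted), survival combines the per-layer efficiency with exit
attenuation, directions are Highland-smeared, arrival times follow the
delivery order with non-paralyzable dead-time losses, and the whole fraction's
recorded coordinates receive one pose offset drawn from the placement
uncertainty. Every recorded track is linked to a truth record.

What the generator does *not* model — and hence what passing tests do not
show about clinical data: nuclear cross sections and species mix, energy-loss
straggling, beam lateral width, CT anatomy and heterogeneous tissues,
hit-level tracking artefacts, per-channel dead time, patient (as opposed to
detector) repositioning. The validation demonstrates the statistical
machinery — calibration, correction, detection, localisation — under the
stated geometry and statistics, not clinical sensitivity.

## Numerical choices and degenerate inputs

* WEPL integration: midpoint rule; 1 mm steps for end ranges (interpolated
  crossing), ≤ 2.5 mm adaptive steps for exit attenuation (length-bucketed
  rays, voxel-index-space lookups). Verified against a 0.01 mm oracle.
* Parallel track/axis: degenerate flag, PCA at the perpendicular foot.
* Empty profile: valid all-zero object; all-zero reference masks every bin
  with a warning; fewer than two usable bins makes the comparison undefined
  and the SPB is skipped and logged, not failed.
* Beams whose residual range is exhausted before the phantom get an end range
  at the entry plane with zero WEPL; a residual range outliving the phantom
  grid raises an error.
* Determinism: every stochastic step draws from `numpy` generators seeded
  from (scenario seed, fraction id); identical config + seed reproduces
  track lists bit for bit.

## Problem sizes

The validation studies run at the nominal scenario scale: ~3100 beams and
~400k recorded tracks per fraction, ~320 tested SPBs per comparison; the
change-detection study uses 20 seeded repeats of a 5-fraction progression.
These sizes were chosen so the SPB statistics match the intended ~10^3
tracks per SPB while a full suite pass stays comfortably within a coffee
break on one core.

## Known limitations

* The exposure-mode chi-square assumes equal planned exposure per SPB; plans
  differing between fractions would need per-SPB exposure ratios.
* The RS alignment estimates a rigid translation only; rotations of the cart
  are not modelled (nor simulated).
* The dead-time model is a single global non-paralyzable interval; pile-up
  and per-channel effects are out of scope.
* Field combination: each field is analysed in its own frame; no
  cross-field or cross-fraction p-value pooling is attempted beyond the
  flag-count table.
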