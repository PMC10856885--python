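# Methods

This note describes the models, algorithms and parameter choices behind
`circumtrack`, and what the synthetic validation does and does not show
about real recordings.

## Geometry

**Camera model.** Each camera is a pinhole with Brown–Conrady distortion.
World points `P` (centimetres) map to camera coordinates `Pc = R·P + t`,
to normalised coordinates `(x, y) = (Xc/Zc, Yc/Zc)`, through the
distortion polynomial

    x′ = x (1 + k₁r² + k₂r⁴ + k₃r⁶) + p₂(r² + 2x²) + 2p₁xy
    y′ = y (1 + k₁r² + k₂r⁴ + k₃r⁶) + p₁(r² + 2y²) + 2p₂xy,   r² = x² + y²

and finally to pixels `u = fx x′ + cx`, `v = fy y′ + cy` (top-left origin,
pixel centres on integers). The inverse of the distortion has no closed
form; `remove_distortion` uses damped fixed-point iteration (tolerance
1e-10, at most 50 iterations), which converges for any realistic lens in
this setup and round-trips to better than 1e-8 over the 112° field of view.
`k₃` is carried in the model but held at zero during calibration unless at
least 15 board views are available: with a wide-angle lens and few boards
the sixth-order term is poorly constrained and destabilises the fit.

**Single-camera calibration.** From each detected board a pixel homography
is estimated (normalised DLT); the closed-form planar-target constraints on
the image of the absolute conic give initial intrinsics, per-view poses
follow from the homography columns, and a joint Levenberg–Marquardt
refinement over `(fx, fy, cx, cy, k₁, k₂, p₁, p₂)` plus all 6-DoF board
poses minimises the total squared pixel reprojection error. On exact
synthetic corners the truth is recovered to machine precision; with 0.3 px
corner jitter focal lengths come back within ~0.5 % and the residual equals
the injected jitter, as it should.

**Stereo calibration.** With the board visible in both cameras at once,
each placement yields both board poses and hence one relative pose
`R = R_side R_topᵀ`, `t = t_side − R t_top`. Multiple placements are fused
by quaternion averaging (rotations) and arithmetic mean (translations); a
rotation spread above 5° aborts with an error rather than averaging
inconsistent geometry. The essential matrix is `E = [t]×R` and the
fundamental matrix `F = K_side⁻ᵀ E K_top⁻¹`; note the two distinct
intrinsic matrices — a single shared "camera matrix" is only correct for
identical cameras. `F` maps a *top-view pixel* to its epipolar *line in the
side view*. The rig's world frame is anchored at the first stereo board.

**Chessboard detection.** Inner corners are saddle points: Harris peaks
are refined by gradient orthogonality (every window pixel's gradient must
be perpendicular to its offset from the corner — exact under perspective
because chessboard edges are straight lines through the corner), deduped,
and validated by a ring test (an X-junction shows four dark/light
transitions on a circle around it; board-edge L-corners show two and are
discarded). The surviving points are assigned to the 10×7 grid by a
4-corner projective bootstrap followed by an iterated bi-quadratic warp
(which absorbs moderate lens distortion) with optimal one-to-one
assignment. Orientation is canonicalised by requiring positive grid
handedness (a front-viewed board cannot appear mirrored) and a dark
diagonal cell at the origin corner; because an 11×8-square board flips its
colour parity under 180° rotation, this selects a unique physical corner
and the ordering is rotation-stable. Partial grids are reported as absent,
never truncated. On clean synthetic renders the detector is accurate to
better than 0.2 px; calibration-recovery tests therefore feed exact
rendered corner coordinates (optionally jittered) so that calibration
accuracy and detection accuracy are measured separately.

The board is modelled as a 10×7 grid of *inner corners* (11×8 squares);
with the printed outer dimensions this corresponds to ~7.5 cm squares for
the single-camera target and ~5.3 cm for the smaller stereo target. Both
square sizes are configuration parameters.

## Segmentation and lighting logic

Each pixel carries up to 5 Gaussians over grey level. A pixel matches a
component when its squared Mahalanobis distance is below `var_threshold`
(default 16, i.e. 4σ); it is background when the matched component belongs
to the highest-weight set whose cumulative weight reaches
`background_threshold` (default 0.9). Matched components update with
exponential learning rate `α` (default 0.01); unmatched pixels replace the
weakest component. Variances are floored at 1.0 grey²; a freshly seeded
model starts at variance 4.0 — tight enough to separate the plant from the
wall under the dim night safelight (a 10-grey-level contrast is still
>4σ), wide enough that sensor noise does not spawn spurious components.

Sharp photoperiod transitions flood the foreground; when the total
foreground contour area exceeds `lighting_change_area` (default 25 % of
the image) and the cooldown `lighting_change_est_time` has elapsed, the
frame is declared a lighting change, the model is reset (reseeded from the
current frame) and re-detection is suppressed for the cooldown period. No
tip candidates are emitted on a reset frame; it is filled by
interpolation.

Two run-level mechanisms sit on top of the core model:

* **Post-reset burn-in.** The reset exists to shorten stabilisation, so
  the pipeline can use a temporarily raised learning rate
  (`post_reset_learning_rate`) during the cooldown window and drop back to
  the base rate afterwards.
* **Contrast-polarity filter.** The booth is built so the plant has a
  known contrast sign in each view — bright against the dark floor cover
  from above, dark against the white wall from the side. Foreground pixels
  whose sign disagrees (pixels the plant has *vacated*, which revert to
  the background colour) are discarded. This removes motion trails and
  post-reset ghosts that would otherwise bias the geodesic tip search
  backwards along the motion.

## Tip detection, selection and synchronisation

Per retained contour, the candidate is the pixel with the maximal
shortest-path (geodesic) distance — 8-connected, step costs 1 and √2 —
from the contour pixel nearest the configured base anchor. The geodesic
criterion finds the far end of a curled shoot where a Euclidean extremum
would not; ties break towards larger `v`, then larger `u`. In the side
view, contour fragments are first filtered to those within
`epipolar_threshold_px` (default 20 px) of the epipolar line of the
synchronised top-view tip; if none qualify the closest fragment is kept,
and if no top-view estimate exists the filter is skipped.

Selection: one candidate → taken (*automatic*); several → nearest to the
previously selected point (*estimated*; highest-ranked if no history);
none → gap. Gaps are filled by per-coordinate linear interpolation between
the bounding observations (*interpolated*); leading/trailing gaps hold the
nearest observation. Manual corrections (CSV) replace points (*manual*)
and interpolated stretches bounded by a corrected point are recomputed.

The two cameras free-run on their own clocks. Synchronisation uses the
photoperiod: frame indices where the mean luminance jumps by more than
half its dynamic range are step transitions, and the offset is the index
difference of the first matched transition (all transitions are expected
to agree). This recovers offsets far larger than any realistic clock
drift as long as the offset is below half the photoperiod phase length.

## Triangulation and error audit

Both pixels are undistorted to normalised coordinates; the two-ray DLT
system in the rig frame is solved by SVD and refined with one Gauss–Newton
step on the summed squared *pixel* reprojection error (distortion in the
loop). Rays meeting at less than 0.5° raise an error instead of returning
an unstable point. Per frame the pixel distance between each observation
and the reprojected 3D point is recorded; points whose mean error exceeds
`flag_threshold` (default 10 px) are flagged for review. Study-level
aggregation reports the unweighted mean of the per-video per-view mean
errors (point-weighted averaging gives a slightly different figure; the
unweighted convention is used throughout), the flagged share of all
points, and the manual share of all frames.

## Synthetic scenes

The renderer reproduces the recording geometry: a cylindrical booth
(100 cm tall, 93 cm radius), top camera at 130 cm looking down, side
camera on the wall at 55 cm looking at the plant axis (optical axes 90°
apart), both 1280×720 with a 112° field of view and mild distortion
(k₁ = −0.08, k₂ = 0.01, small tangential terms). The lateral view has a
dark lower band (the booth's contrast cover); an optional support pole
(90 × 1.8 cm at 30 cm) can be rendered. Illumination follows a light:dark
pattern (default 40:20 frames, a scaled stand-in for the 960:480 frames of
a real L16:D8 day at one frame per minute) with a 0.1× night level, plus
1.0 grey level of additive sensor noise. All randomness flows through one
seeded generator; equal configs give bit-identical frames.

The plant is a bending stem (quadratic arc from the pot base to the tip)
plus a circular tip blob, with the tip following a growing helix: radius
15 cm, period 120 frames, growth 0.07 cm/frame from 35 cm. The growth
default keeps a 300-frame run below the height at which the tip starts
crossing in front of its own stem in the lateral view — the documented
occlusion failure mode is thereby excluded from the no-occlusion closure
sequence, and can be re-enabled simply by raising the growth rate or
extending the run. An alternative stem model (`growth_path`) renders the
stem as the tip's past helical path with an age-decaying sway, for
occlusion and realism experiments. If the side camera's clock is offset,
its lead-in frames show the backward-extrapolated helix (the plant was
already moving before the other camera started) rather than a frozen
scene.

**What the closure run shows — and what it does not.** The end-to-end
closure (300 frames, 0.5 px corner jitter, 7-frame offset) demonstrates
that the chain is self-consistent: calibration recovers the true optics,
synchronisation is exact, ≥95 % of frames are tracked automatically within
5 px, and the 3D trajectory is recovered to well under 1 cm RMSE. Real
recordings are harder in ways the renderer deliberately omits: leaves and
secondary shoots, tip/stem occlusion, reflections, slow illumination
drift, and plant appearance changes. On real data the automatic fraction
drops and manual corrections become necessary — which is exactly what the
corrections mechanism and the flagged-point audit are for.

**Scaled analysis settings.** Real sequences run ~1440 frames/day; scaled
test sequences compress the photoperiod ~24×. The run settings used for
scaled sequences (`circumtrack.closure.scaled_settings`) therefore differ
from the module defaults: base learning rate 0.02 with a 0.3 burn-in after
resets, background threshold 0.8 (so a tip that briefly stalls in one
view's projection survives ~18 frames before being absorbed into the
background), and a 10-frame lighting cooldown. Module defaults remain the
conservative real-data values.

## Numerical choices and degenerate inputs

* Pose matrices are validated on construction (orthonormality and
  determinant to 1e-9), never trusted.
* Distortion inversion: fixed-point, tolerance 1e-10, max 50 iterations,
  raising with the residual on divergence.
* Homographies use Hartley normalisation; grid assignment uses the
  Hungarian algorithm, so near-ties cannot deadlock.
* Weight renormalisation keeps mixture weights summing to 1 after every
  update; empty tracks, empty stereo overlap, all-coplanar board sets,
  zero baselines and behind-camera points raise typed exceptions.
* Geodesic ties (exactly equal path lengths) break deterministically
  towards the lower-right pixel.

## Known limitations

* Minimum-path tip localisation fails under tip/stem overlap (it returns
  an elevated stem point); detection of that condition is left to the
  reprojection-error audit and the operator.
* The background model is grey-level only; colour cues are unused.
* Offsets approaching half a photoperiod phase are ambiguous for the
  first-transition matcher.
* The chessboard detector expects the full inner grid; heavily occluded
  boards are treated as absent rather than partially used.
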