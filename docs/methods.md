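# Methods

## The navigation model

The system expresses every measurement in one of four coordinate frames:
the 2D ultrasound image plane (US, embedded in 3D with the out-of-plane
coordinate fixed at zero), the EM sensor on the bronchoscope tip (B), a
reference EM sensor (R — on the phantom container during the experiment,
on the calibration arm during probe calibration), and the preoperative CT
volume (CT). A point imaged by the ultrasound probe is located in CT
coordinates through the rigid chain

    p_CT = CT_T_R · R_T_B(t) · B_T_US · p_US

All transforms are proper rigid 4×4 homogeneous matrices; units are
millimetres throughout and seconds for time. Transforms and points carry
coordinate-frame tags that are checked at composition and application
time, so an incorrectly ordered chain raises instead of silently producing
wrong coordinates. Rotation blocks whose orthonormality defect lies
between 1e-9 and 1e-6 (the magnitude of rounding in real tracker logs) are
projected onto the nearest rotation by SVD; anything worse is rejected.

## Closed-form rigid registration

Both unknown transforms of the chain are estimated by the same solver: the
orthogonal-Procrustes least-squares fit with centroid subtraction, SVD of
the cross-covariance and a sign correction on the smallest singular vector
so the rotation is always proper (no reflection), the standard
Arun/Umeyama construction without a scale factor — both spaces are metric
millimetres. Degenerate inputs (fewer than three correspondences, length
mismatch, collinear sources) are rejected. The result reports per-point
residuals, their RMS as the fiducial registration error (FRE), and the
condition number of the centred source set; for the calibration solve the
source points are coplanar by construction (z = 0 in the image plane), so
the condition number is infinite by design and flags that one rotational
degree of freedom is determined only through the 3D destination points.

Correspondence is by index: fiducials are pinpointed in both spaces in a
known order, and no automatic matching is attempted.

## Probe calibration

`B_T_US` is estimated by imaging an 11.5 mm plastic sphere whose centre
p_R is known relative to a reference sensor on a moving calibration arm.
The sphere is swept at 1 mm/s along the image-plane normal, through the
plane and back, at nine positions arranged in a 3×3 angle × depth grid
over the sector — 18 recordings at 40 Hz. Per recording:

1. every frame's sphere cross-section is localized by thresholding the
   bright rim at 0.8 of the frame's 99.5th-percentile intensity and
   fitting an algebraic least-squares (Kasa) circle through the rim
   pixels. The threshold sits between the rendered sphere interior and its
   rim so only rim pixels enter the fit; the 99.5th-percentile peak is
   robust to noise outliers. Frames whose in-sector intensity shows no
   contrast (99.5th percentile within 20% of the median) carry no sphere
   and are skipped.
2. the plane-crossing frame is the frame with the largest fitted radius:
   a sphere of radius R cut |d| mm off-centre shows a chord of radius
   √(R² − d²), maximal exactly at d = 0. On a plateau of numerically
   equal maxima the middle frame is taken. (Whether to pick the incidence
   frame or interpolate between frames was an open choice; the
   maximum-radius rule is simple, deterministic, and exact to one frame
   period, which at 1 mm/s and 40 Hz is 0.025 mm of sphere travel.)
3. the sphere centre is expressed in the probe-sensor frame via the
   tracked pose of that frame, p_B = (R_T_B)⁻¹ · p_R.

The 18 correspondences {(x, y, 0)} ↔ {p_B} are solved closed-form as
above. Noise-free simulation recovers the ground-truth calibration to
better than 0.01 mm / 0.01°.

## Volume reconstruction

Tracked 2D frames are compounded into a CT-frame volume by
pixel-nearest-neighbour (forward) insertion: each in-sector pixel is
mapped through the chain and binned into its containing voxel; a voxel's
value is the mean of its contributions and unfilled voxels are NaN,
excluded from all downstream statistics. Grid spacing defaults to 0.5 mm
isotropic. An optional single hole-filling pass assigns empty voxels with
at least 9 filled 26-neighbours the mean of those neighbours. PNN with
mean compounding was chosen as the simplest method faithful enough for
centroid/surface evaluation; it is deliberately replaceable. Frame poses
are matched to tracking samples by nearest timestamp within half a tracker
period (12.5 ms at 40 Hz); larger gaps are an error rather than an
interpolation, since pose interpolation is out of scope.

## Segmentation and evaluation

Targets are extracted by thresholding (components 26-connected, smaller
than 27 voxels discarded as specks; an optional upper bound excludes
bright fiducial markers when segmenting soft tissue). Centroids are
unweighted means of voxel-centre world coordinates — the reproducible
surrogate for manually pinpointed centres. Cross-modality target identity
is established by mutual-nearest-centroid matching, with unmatched and
ambiguous (two references within 1 mm) cases reported.

Per-acquisition accuracy is the translation-only shift correction aligning
the reconstructed US target with its CT segmentation: primarily the
centroid difference (sign convention US − CT, so CT centre + deviation =
US centre), optionally refined by minimizing the mean squared
nearest-surface distance over a pure translation starting from the
centroid solution. Rotation is never estimated. The per-acquisition error
is the Euclidean norm of the deviation; aggregation reports per-axis mean
and sample SD (n−1 denominator), mean/SD/maximum error, and per-target
min–max ranges in a table with one row per station and footer rows n /
Mean / SD / Maximum. Deviations are reported in CT axes. Automating the
shift correction removes the single-observer variability a manual
alignment would introduce, at the cost of depending on the segmentation
threshold.

## The simulator

The simulator is the package's stand-in for all hardware and defines the
study conditions:

- **Phantom.** A Y-shaped airway centerline (trachea bifurcating into two
  main bronchi) inside a 110 × 70 × 120 mm container; 11 ellipsoidal
  targets (4–7 mm semi-axes) labelled after the IASLC stations
  2R1…2L2, 4R1…4L2, 7, 10L, 11R; 10 non-coplanar fiducials on the
  container surface. Physical phantom dimensions and target sizes are not
  published, so the layout is parameterized; the defaults satisfy the
  geometric invariants (targets inside the container, within 25 mm of the
  centerline, clear of the lumen) rather than claiming to match the
  physical object.
- **CT.** Voxelization at (0.5, 0.5, 0.3) mm — the 0.3 mm slice thickness
  of the phantom CT — with Hounsfield-like class intensities (gelatin 50,
  lumen −1000, targets 300, fiducials 1000; arbitrary but documented, and
  chosen so threshold segmentation is meaningful). A voxel belongs to a
  target iff its centre is inside the ellipsoid.
- **Tracking.** Poses sampled at exactly 40 Hz over half-open intervals.
  Positional noise is Gaussian per axis with σ = 0.48/√3 mm so the 3D
  positional RMS equals the manufacturer's single-number 0.48 mm
  accuracy (verified by Monte-Carlo in the tests); rotational noise
  defaults to 0.1°, an assumption, as no rotational accuracy is published.
- **Ultrasound.** A 60° convex sector, depth range 3–50 mm, 0.2 mm
  pixels (span from the probe's specification; depth/pixel settings are
  assumptions, as the acquisition settings are not published). Frames are
  geometric tissue-class renderings — target rim bright (255), interior
  mid-gray (150), gelatin dark (30), outside the sector 0 — not physical
  speckle simulations: the pipeline needs localizable boundaries, and
  acoustic realism is out of scope. Consequently, passing tests show the
  geometry and estimation chain are correct, not that the localization
  survives speckle, shadowing, or refraction in real B-mode data.
- **Sessions.** The accuracy protocol visits all 11 targets in station
  order, three times (33 acquisitions). Each acquisition orients the
  image plane from the nearest centerline point toward the target and
  sweeps it along the plane normal at 5 mm/s with frames at 10 Hz
  (0.5 mm frame pitch, matching the reconstruction grid). The physical
  experiment accumulated 37 measurements because of repeated and missed
  acquisitions; the simulator reproduces the protocol, not the accidents.
- **Determinism.** Everything is a pure function of (configuration,
  seed); bit-identical outputs across runs. Long calibration sessions can
  be generated lazily (`iter_calibration_sweeps`) so only one sweep's
  frames are in memory at a time.

The world frame coincides with the CT frame of the noise-free phantom;
all ground-truth transforms are generated from it and retained only for
scoring, never used by the pipeline under test.

## Numerical choices and problem sizes

- The zero-noise end-to-end experiment bounds its mean error by grid
  resolution only (voxelization of CT and reconstruction at 0.5 mm);
  measured values are ~0.02 mm, far below the 0.5 mm half-voxel bound.
- Calibration sweeps default to a ±8 mm span (full sphere
  disappearance on both sides); shorter spans are used in some tests
  where only the crossing matters, which leaves results unchanged
  because the crossing frame and its neighbourhood are identical.
- The surface-refined shift correction uses Powell iterations on a
  KD-tree nearest-distance cost; it is started at the centroid solution
  and in simulation agrees with it to < 0.5 mm, so the centroid method is
  the default.
- Ties in the crossing-frame plateau take the middle index; component
  sorting is by size (largest first); all RNGs are numpy Generators
  seeded from a single root seed.

## Known limitations

- No respiratory/cardiac motion, EM field distortion, or probe-tissue
  coupling effects; these dominate real-world error and are exactly what
  the phantom experiment could not isolate either.
- No temporal (latency) calibration between tracker and US stream; the
  simulator generates synchronized data.
- Airway/centerline segmentation is out of scope; the simulator supplies
  the centerline as ground truth.
- The US rendering has no speckle, so segmentation thresholds that work
  here would need re-tuning on real B-mode data.
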