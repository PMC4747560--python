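# Methods

## Geometric face model

The face is modelled as an ellipse centred on a reference point
derived from the eyes: centre x at the midpoint of the eye centres,
centre y half the eye-to-mouth distance below the eye line.  When no
mouth detection is available the eye-to-mouth distance defaults to
1.1 × the inter-eye distance (`eye_mouth_factor`, configurable).  The
ellipse semi-axes come from the face box: `a = width/2`,
`b = height/2 × axis_scale`; when the box itself is inferred from the
eyes, width is 2.5 × the inter-eye distance and height 1.3 × the
width.  These factors are conventional frontal-face proportions; all
are configurable, and none affect the calibration analytics, which
operate on (angle, ratio) readings rather than absolute pixels.

The ellipse radius along a direction uses the centre-polar form
`r(θ) = ab/√((b cosθ)² + (a sinθ)²)`, so `r(0°) = a` and `r(90°) = b`.

### Angle conventions

Marker angles are stored as the unsigned sweep from the +x axis
through the marker's hemisphere, together with hemisphere
(upper/lower) and side (left/right/midline) flags:

* eyebrow markers (~45°, ~65°): upper hemisphere, direction
  `(±cosθ, −sinθ)` in image coordinates (y down);
* mouth corners (~130°): lower hemisphere; 130° is read as a sweep
  past vertical, giving direction `(±|cos θ|, +sin θ)` with the sign
  of x chosen by the side flag — the only reading that puts the
  markers beside the mouth;
* midline markers (upper/lower mouth): pinned to the vertical axis.
  Their distance is `ratio × b` exactly (the "ratio of the y-axes"),
  so their x coordinate equals the centre's by construction.  The
  calibrated angles (90.19°, 89.99°) are retained in the profile as
  calibration metadata; placement does not tilt off-axis for them,
  and inverting a midline marker therefore reads 90°.

Inversion (clicked point → reading) reports the unsigned elevation
from the horizontal; mouth-corner roles are reported as
`180° − elevation` so the conventional ~130° reading round-trips.
Placement followed by inversion is the identity on (angle, ratio) to
better than 1e-9 for all non-midline roles at arbitrary angles.

### Default placement profile

The default (angle, ratio) table is the per-marker mean of the
packaged manual-placement readings (10 subjects, mean of 3 click
trials each).  Two quirks of that calibration are kept as-is rather
than "corrected":

* the left eyebrow ratios are ≈0.72 while the right are ≈0.55, so the
  default profile is not left/right symmetric;
* the upper-mouth ratio (0.3350) slightly exceeds the lower-mouth
  ratio (0.3234), so the two midline markers sit ≈1 px apart on a
  typical face.

The mirror-symmetry and round-trip property tests use symmetrized /
role-generic profiles so the invariants are exercised independently
of these calibration quirks.

## Acquisition and detection

Detection is a pluggable backend (`detect(frame) -> [FaceDetection]`).
Two backends ship: a manual provider that trusts caller-supplied eye
centres (face box inferred from the inter-eye distance), and a
segmentation detector for the synthetic renderer's faces (largest
bright connected region = face, two largest dark blobs in its upper
half = eyes) built on `scipy.ndimage` connected-component labelling.
Cascade-style detectors can be plugged in through the same interface;
the rest of the pipeline never depends on how eyes were found, and
every stage runs with manual eye coordinates alone.

## Lucas–Kanade tracking

Per point and frame pair, the tracker solves the 2×2 normal equations
built from spatial gradients (3-tap central differences of bilinear
samples) and temporal differences inside a square window, iterated
with forward-additive updates, coarse-to-fine over a Gaussian pyramid.

Defaults (all configurable): window 15 px, 3 pyramid levels, 20
iterations, convergence threshold 0.01 px, minimum structure-tensor
eigenvalue 1e-4 (per window pixel, on intensities normalized to
[0, 1]).  A point is flagged *lost* when the tensor is near-singular
(textureless window), the update diverges beyond twice the window, or
the point is within the window margin of the border.  Lost markers
hold their last good position and stay flagged; downstream feature
extraction can exclude flagged frames.  The centre is tracked like any
other marker by default (per-frame re-detection is available via
explicit per-frame centres in `md_series`).

## Features

MD = per-frame Euclidean distance of each of the 8 markers to the
centre, plus the mouth width (distance between the mouth-corner
markers) as feature 9.  CMD subtracts a neutral baseline (first frame
by default; mean of the first k frames via `baseline_frames`).  CMD
differences are signed so the direction of motion is preserved; an
absolute-value mode exists for magnitude-only analyses.  The mouth
width is baselined exactly like the other features.

Trial statistics: arithmetic mean, RMS (`sqrt(mean of squares)`), and
sample variance with the n−1 denominator (the same convention as the
calibration table's Std Dev row).  Note that RMS of a signed CMD
series discards sign; class separation under RMS rests on magnitude
patterns across the nine features.

Normalization: per-dimension min–max, binary to [0, 1] or bipolar to
[−1, 1], fitted on training data only (inside each cross-validation
fold) to avoid leakage.  Dimensions constant in training map to 0
under both schemes.

## Classifiers and cross-validation

KNN: Euclidean metric, majority vote over k neighbours (default 5);
ties break by smallest summed neighbour distance, then lexicographic
label order.  PNN: Gaussian Parzen scores averaged per class,
argmax prediction, lexicographic tie-break; the spread σ is swept over
0.01–0.1 in 0.01 steps and the best value per table cell reported.

Folds are stratified by emotion and seeded (scikit-learn's
`StratifiedKFold`; the optional subject-grouped mode uses
`StratifiedGroupKFold` so no subject appears in both train and test —
off by default).  Per-emotion recognition rates pool correct
classifications across folds; the Average row is the mean of the six
per-emotion rates and Std Dev their n−1 standard deviation.  Building
10 stratified folds requires at least 10 trials in the smallest class;
the classifiers themselves are implemented in-package and are checked
against brute-force oracles in the tests.

## Synthetic data generator

The generator emulates the capture conditions of a seated webcam
recording: a frontal, ellipse-shaped face (default 160×176 px frame,
48 px inter-eye distance), 6-s expressions with a ramp-and-hold
activation (ramp over the first half of the frames), and additive
Gaussian intensity noise (σ = 2 grey levels by default).

Rendering composes a soft-edged bright face ellipse on a darker
background, static smooth texture (Gaussian-filtered noise, ±5 grey
levels), static dark eye blobs, eyebrow strokes drawn between the two
eyebrow markers of each brow, a mouth outline drawn through the four
mouth markers, and a dark dot at every marker position and at the
centre.  Strokes, outline and dots are redrawn each frame from the
current ground-truth marker positions, so the local image structure
moves coherently with the markers — the rendered analogue of visible
sticker markers.

Emotion templates are authored from standard FACS action descriptions
(surprise = brow raise + jaw drop, happiness = lip-corner pull,
anger = brow lowerer + lip press, sadness = lip-corner depressor +
inner-brow raise, fear = brow raise + horizontal mouth stretch,
disgust = upper-lip raise).  Apex displacements are expressed in units
of the inter-eye distance and bounded by 0.5 × that distance.  They
are conventions of this generator, not measured values.

The landmark-space simulator (`simulate_trials`) skips rendering: a
trial is template motion × a per-subject lognormal expressiveness
factor (σ = 0.15 in log space) + i.i.d. Gaussian landmark jitter
(default 0.5 px) on every landmark including the centre, at the
emulated study scale of 30 subjects × 2 trials × 6 emotions with
61 frames per trial.  `rendered_trial_features` instead renders,
tracks and featurizes sequences, carrying the full pipeline's
measurement biases; models meant to classify tracked sequences should
be trained on this path.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real recordings: identity variation
beyond a scalar expressiveness factor, head pose and out-of-plane
motion, illumination change, occlusion, eyelid/blink motion, and
appearance without visible marker dots.  Two rendering-specific
artefacts are worth knowing: the right-side eyebrow markers
(calibrated ratio ≈0.55) sit on the static eye blobs, which biases
their tracked motion low; and the two midline mouth markers nearly
coincide (the calibration-ratio quirk above), so their dots merge and
track almost identically.  Both biases cancel when training and
query features come from the same rendered-and-tracked path.

## Numerical choices

* Coordinates are continuous and 0-based, origin top-left;
  rasterization happens only when writing annotated images.
* Marker CSVs are written with 6-decimal fixed point.
* Comparison against printed reference tables rounds half-up at the
  table's printed precision (`round_half_up`); recomputed summary
  rows are reported at table precision with ties to even.
* Degenerate inputs raise typed errors: zero eye-mouth distance,
  clicked point at the centre, empty frame directories, variance of a
  single frame, unfit normalization.
* Fold construction, the simulator and the renderer are deterministic
  per seed; the CLI logs a config hash for every run.

## Problem sizes

The test suite and acceptance script run at desk scale: rendered
sequences of 15–25 frames at 160×176 px, landmark simulations of 360
trials × 61 frames, 10 shift-recovery instances, 500 round-trip
samples, and 20 label shuffles for the chance control.  These sizes
give stable statistics (CV accuracy varies by ~1–2 points across
seeds) while keeping a full run to seconds.

## Known limitations

* The default placement profile inherits the asymmetries of its
  manual calibration (see above); a symmetrized profile can be
  supplied via the profile YAML when symmetry matters.
* Hold-last-position is a simplistic lost-marker policy; markers that
  leave the border never re-acquire.
* The PNN sweeps σ on the same folds it reports, mirroring the
  reference table convention of reporting the best spread per cell;
  nested selection would be needed for an unbiased estimate of the
  sweep's generalization.
* Real-data recognition rates cannot be validated here: the original
  recordings are not available, so classifier claims are validated
  through oracle equivalence, chance controls and synthetic parameter
  recovery instead.
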