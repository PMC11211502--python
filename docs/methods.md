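# Methods

This note documents the models, conventions, parameter defaults and known
limitations of `gloveforge`, module by module.

## Kinematic hand model (`hand_model`)

The hand is a pure kinematic chain — no muscles, tendons, dynamics or
contact. The wrist is a free joint with 6 DOF (3 translation + 3 rotation);
each of the five digits adds 4 rotational DOF, for 26 DOF in total:

* non-thumb fingers: MCP abduction (about the palm normal), MCP flexion,
  PIP flexion, DIP flexion;
* thumb: CMC abduction, CMC flexion, MCP flexion, IP flexion.

At the zero pose the hand lies flat in the z = 0 plane, fingers along +y,
thumb splayed toward +x (right hand), palm facing +z; positive flexion curls
toward the palm. Digit base directions are splayed in-plane by fixed angles
(thumb −50°, index −10°, middle 0°, ring +10°, pinky +20°).

Twenty-one markers follow the common hand key-point numbering (wrist = 0,
then four points per digit, thumb first); each marker sits at a bone
endpoint, so the 20 marker-graph segments coincide with the 20 bones.
Fifteen candidate sensor sites sit at mid-bone with their frame equal to the
bone frame (+y along the bone): distal/middle/proximal phalanx per finger,
and distal/proximal phalanx plus metacarpal for the thumb.

Bone lengths default to fixed fractions of the wrist-to-middle-fingertip
distance (default 0.193 m, the adult population mean used throughout).
`scale_model` rescales the whole hand to a target length, then adjusts the
index and ring phalanges reciprocally (preserving their geometric-mean
length) to hit a target index:ring digit-length ratio; digit length is
measured over the phalanges (crease to tip). Joint limits ship as data in
the model file (defaults: MCP flexion [−20°, 90°], abduction [−25°, 25°],
PIP [0°, 110°], DIP [−10°, 90°]; thumb CMC [−30°, 60°]/[−10°, 60°],
MCP [0°, 60°], IP [−10°, 80°]) so users can substitute a published limit
table. Splay angles, fractions and limits are plausible stand-ins, not
measured anthropometry.

Units: meters and seconds internally; degrees in poses and motion files;
millimeters for distance errors. Quaternions are scalar-first Hamilton and
renormalized after every interpolation. A bone/site quaternion rotates
local-frame vectors into the ground frame.

## Preprocessing (`preprocess`)

Monocular key-point estimators return coordinates in an arbitrary frame
whose scale and orientation drift per frame. The pipeline is
mirror (left hands only, reflection about the wrist's sagittal plane, with
signed-volume chirality detection when metadata is absent) → per-segment
rescaling to model bone lengths (wrist outward, so the chain stays
connected; zero-length segments inherit the previous frame's direction) →
translation of the wrist key-point onto the model wrist → per-frame Kabsch
rotation onto the model's rest markers.

Kabsch is the standard SVD construction with the determinant sign flip, so
the result is always a proper rotation. Two deliberate choices:

* the rotation pivots about the wrist (uncentered alignment), so the
  translation step's wrist coincidence survives and the fitted rotation can
  never be worse than applying none;
* the correspondence set defaults to the six pose-invariant palm markers
  (wrist, thumb CMC, the four finger MCP knuckles). These are rigid in the
  wrist frame, so the wrist orientation is recovered exactly for **any**
  finger pose and forward-kinematics output is an exact fixed point of the
  whole pipeline (round-trip error at machine precision). Aligning on all
  21 key-points is available via `alignment_markers=range(21)`, but it
  biases the orientation of strongly flexed hands toward the flat rest pose.

## Inverse kinematics (`ik`)

Each frame minimizes the mean squared marker distance over the 26 DOF with
soft quadratic penalties for joint-limit violations (weight 10 per squared
degree of violation by default; penalties only activate outside the limits,
matching an optimizer that merely avoids violations rather than biasing
in-limit solutions). The solver is scipy's trust-region-reflective nonlinear
least squares with finite-difference Jacobians, iteration cap 200 and
tolerance 1e-8; the wrist rotation is parametrized as a rotation vector.
Frames are warm-started from the previous solution; a frame whose optimized
pose is worse than its start returns the start.

Diagnostics: MDE (mean Euclidean marker distance, mm) per frame and
aggregated; CVR (% of frame×joint pairs more than 1e-6° outside their
limits — the tolerance exists because rest angles often sit exactly on a
limit) and CVM (mean/std degrees past the limit over violating pairs).
Takes can be filtered by an MDE threshold (default 10 mm, configurable) or
by keeping the k best takes per gesture; hard clipping to limits is a
separate, idempotent operation computed after the diagnostics.

## Augmentation (`augment`)

**Hand size.** Joint-angle series are invariant to hand geometry, so each
variant pairs the bit-identical motion with a model rescaled to sampled
dimensions: length ~ N(19.3 cm, 1.25 cm), index:ring ratio ~ N(1.0, 0.05),
both truncated at ±4 sd to forbid non-physical hands (the truncation shifts
the moments by far less than the verification tolerances). The variation
appears downstream when sensors are simulated on the resized hand.

**Key-pose time warping.** The variance-trace profile
D = √Tr(QQᵀ) is computed per sliding analysis window (default 5 frames,
≈0.17 s at 30 Hz) from the covariance C of the joint-angle channels:
Q collects the eigenvectors of C scaled by √eigenvalue, so
Tr(QQᵀ) = Σλ = Tr(C) and D is the square root of the total local variance.
(The eigendecomposition reading is the documented interpretation of an
ambiguous construction; it reduces to the windowed standard deviation in
one dimension and makes D a genuine motion-variance profile.) Key poses are
prominence-qualified local extrema of the normalized profile
(`scipy.signal.find_peaks`, default prominence 0.1 of the normalized range)
plus the take endpoints. Each inter-key-pose duration is multiplied by
(1 + u), u ~ Uniform(−0.4, 0.4) — uniform is the maximal-entropy choice for
a stated bound, and u = 0 leaves the take unchanged. Segments are
Fourier-resampled to their new length after removing the endpoint chord
(the residual is near-periodic, which suppresses wrap-around ringing),
low-pass filtered (Butterworth order 4, cutoff 0.3 × Nyquist, zero-phase),
and rejoined with endpoints pinned to the source key poses — so key-pose
angles are preserved exactly and no instantaneous jumps appear. Segments
that would shrink below 2 samples redraw their factor.

## IMU synthesis (`imusim`)

Ground frame z-up, gravity (0, 0, −9.80665) m/s². Site trajectories are
resampled to the IMU rate (default 100 Hz; cubic splines for position,
slerp between hemisphere-aligned quaternions for orientation). Derivatives
are central differences with second-order one-sided ends:
a = d²p/dt² in the ground frame, and angular velocity via two mutually
cross-checking routes — ω_sensor = 2 q\*⊗dq/dt (vector part) and
S(ω_ground) = dR/dt·Rᵀ with ω read off the skew-symmetric part (the
symmetric residual is reported as a numerical-quality metric). The two
routes agree to ~1e-6 rad/s on gentle trajectories at kHz rates; at 100 Hz
the agreement is limited by the O(dt²·ω³) truncation error of the
differencing, not by either formula.

The accelerometer reads specific force — the sensor-frame rotation of
(a − g) — so a resting sensor reports +9.80665 m/s² on its up axis and
orientation is visible through the gravity decomposition; a free-falling
sensor reads zero. The magnetometer rotates a constant ground-frame field
(default 50 µT along +y) into the sensor frame; its magnitude is
time-invariant by construction.

Error model per modality:
y = quantize(saturate(M·diag(s)·x + b + η_white + η_bias-instability +
η_random-walk)) with white-noise sd = noise_density·√(rate/2), bias
instability as first-order-filtered white noise, and random walk as a
cumulative sum with increment sd = random_walk/√rate. Defaults are
datasheet-typical consumer MEMS values for range, resolution and noise
density (±16 g / ±2000 dps, 16-bit, 180 µg/√Hz and 7 mdps/√Hz), with bias,
bias instability and random walk zero — mirroring the practice of using
only manufacturer-provided parameters. The all-zero model is exactly the
identity.

## Placement scoring (`placement`)

Pearson correlation is computed exactly from the covariance/sd quotient; a
constant series yields r = 0 by convention (no movement is uninformative,
not undefined). Averages are taken over sessions within each activity
first, then over activities with equal weight, so session-count imbalance
cannot bias a score. G takes the absolute value of the signed average as
the formula is written, so opposite-signed correlations in different
activities can cancel; `abs_per_activity=True` switches to averaging
per-activity magnitudes. Cross-finger redundancy pairs joints by role
(thumb CMC flexion/abduction ↔ finger MCP flexion/abduction, thumb MCP ↔
PIP, thumb IP ↔ DIP; J = 4), and likewise averages signed correlations over
the four pairs before the norm — consequently negating a *single* joint
column can legitimately change D, while negating a whole finger cannot.

Site importance: distal = H_f; middle phalanx = G(DIP,PIP)·H_f; proximal =
G(PIP,MCP)·G(DIP,MCP)·H_f; thumb distal = H, proximal = G(IP,MCP)·H,
metacarpal = G(IP,CMC)·G(MCP,CMC)·H, with the MCP/CMC flexion series
standing in for those joints in the products. Ranking is by descending
importance with a deterministic anatomical tie-break (thumb → pinky,
distal → proximal); an all-zero score vector is flagged degenerate.
Candidate sets are the nested top-i site lists (and bottom-i lists for
best-vs-worst comparisons). The 15 phalanx sites are the whole candidate
pool; no wrist or exhaustive combinatorial search.

## Recognition pipeline (`pipeline`)

Windows are 0.5 s with 80 % overlap (stride = window·(1 − overlap), windows
wholly inside the stream, majority-label annotation). Splits are assigned
at take level, stratified by gesture, with largest-remainder apportionment
of the 0.6/0.2/0.2 proportions; augmented takes inherit their source take's
split, which is the leakage guard. Normalization standardizes each channel
with train-split statistics only. Training-time augmentation applies one
uniform random 3-D rotation per window jointly to every contiguous
3-channel triplet (orientation robustness) and element-wise multiplicative
Gaussian noise with mean 1, sd 0.2.

Classifiers are pluggable: anything with `fit(windows, labels)` /
`predict(windows)` on (N, channels, samples) arrays. The shipped reference
is per-channel summary statistics (mean/std/min/max) feeding a standardized
logistic regression — fast, deterministic given its seed, and sufficient
for the relative best-vs-worst comparisons the design report makes. The
report trains one classifier per candidate set (channels selected by site
prefix) and tabulates support-weighted F1; channel counts serve as the
hardware-independent cost column, and on-device profiling is an extension
point, not a feature.

## Synthetic data (`synth`)

Gesture templates are key poses at fractional times with smoothstep
transitions and per-take Gaussian jitter on key-pose angles (default 2°)
and duration (default 0.1 s); generated takes respect joint limits.
`project_to_markers` emulates estimator failure modes: isotropic marker
noise, per-frame uniform scale drift in [0.8, 1.2], and per-frame random
rigid motion. The default vocabulary (fist, thumbs-up, rocker, spread, one-
and two-finger clicks) mimics common interaction gestures; its angle values
are fixture choices, not measurements. `build_benchmark` crosses a
vocabulary with subjects whose hand dimensions are drawn from the
population distribution. Default benchmark conditions: 30 Hz takes of ~2–3 s,
a handful of subjects and takes per gesture — the scale at which the test
suite exercises every stage end to end.

The pinch construction (`make_pinch_dataset`, 3 classes × 6 sessions of 2 s
at 50 Hz) is the designed-answer benchmark for placement: thumb and index
joints follow mutually near-orthogonal sinusoids whose amplitudes and
frequencies carry the class, while middle, ring and pinky share one
class-independent carrier — so thumb/index sites must top the ranking and a
best-set classifier must beat a worst-set one.

What the synthetic generator does **not** emulate: soft-tissue artifacts,
marker occlusion and identity switches, estimator-specific bias patterns,
inter-joint coupling of real hands, or real sensor transduction beyond the
parametric error model. Passing tests therefore demonstrate internal
consistency and correct arithmetic of every stage under controlled
conditions, not field performance on recorded gloves. A related caveat: in
key-pose templates all joints transition in lock-step, so within-take
correlations are high and independence scores of such vocabularies are
dominated by jitter; placement ranking is most meaningful on data with
genuinely independent joint drives (like the pinch construction, or real
recordings).

## Numerical choices

* IK: trf least squares, finite-difference Jacobian, cap 200 iterations,
  tolerances 1e-8; never returns a pose worse than its initialization.
* Violation counting tolerance 1e-6°; Kabsch rank guard 1e-10; quaternion
  unit-norm guard 1e-6 with renormalization.
* Degenerate inputs: empty sequences, non-positive rates/lengths and
  mismatched shapes raise validation errors; collinear point sets raise
  alignment errors; constant Pearson series return 0; zero-variance
  channels pass normalization with mean removal only.
* Determinism: every stochastic routine takes a `numpy.random.Generator`;
  reports and splits are bit-reproducible given seeds.
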