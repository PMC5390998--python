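# Methods

This note documents the models, estimators, numerical choices and
synthetic-data design behind `emg2lip`, and what the test suite does and
does not demonstrate.

## Study design and data model

A session records five repetitions of thirteen static facial poses (a
rest pose, seven expressions, five vowels). Per pose and repetition:

* eight sEMG channels at 2048 Hz for ~4 s, in unipolar (electrode vs
  common reference) and bipolar (electrode-pair difference) configurations;
* stereo photographs of ten lip markers and six head markers (two
  infraorbital, two supraorbital, two nasal), from two cameras calibrated
  with a 10×10×10 cm wireframe cube carrying 27 nodes.

Poses are treated as stationary: the raw sEMG within a pose is modelled
as a stationary process, so the sliding-window feature series is reduced
to its time average, one 8-vector ḡ(p, r) per record. Only displacements
from rest are inferable from sEMG, so all errors are referenced to the
per-repetition rest pose.

## sEMG features

Records are bandpass filtered with a Butterworth design of order 4
(8 poles for the bandpass), 15–500 Hz, zero-phase (`sosfiltfilt`) since
the analysis is offline; no mains notch is applied. Four amplitude-domain
features are computed over sliding windows with all-but-one-sample
overlap — MAV, RMS, waveform length (summed absolute first differences),
and Willison amplitude WAMP (count of consecutive-sample differences with
|Δ| ≥ s_lim, thresholds 10 and 20 in the stored amplitude unit). Window
lengths 50–300 ms; the sample count N is rounded to the nearest odd
integer (ties round up) so the centred window index j ± (N−1)/2 is
integral. Only full windows are evaluated: n samples and a window of p
samples give n − p + 1 feature samples. Feature series are truncated to
the **first** 6145 samples (3 s at 2048 Hz, both endpoints counted) so
every record contributes equally; the head of the series is kept because
the zero-phase filter leaves no start-up transient.

The averaged 8-vector is augmented with all 36 distinct quadratic
products g_i·g_j (i ≤ j, squares included, row-major upper-triangular
order) to 44 elements — a second-order Taylor surrogate for the nonlinear
feature→shape map. Augmentation happens **before** normalisation, so all
44 feature elements receive their own normalisation statistics.

## PCA regression

Each record's 30 marker coordinates and 44 augmented features form a
74-vector z. A training pool (12 poses × 4 repetitions = 48 columns;
the rest pose is excluded from pools) is normalised per element to zero
mean and unit sample variance (ddof = 1); test vectors are transformed
with the *training* statistics. Elements with zero variance are guarded
(scale 1, warning). The principal subspace is obtained from the thin SVD
of the normalised 74×48 matrix — mathematically the eigendecomposition of
the 74×74 outer product without ever forming it. Eigenvector signs are
fixed by making each component's largest-magnitude element positive;
eigenvalue ties keep the solver order.

**Eigenvalue scale.** The stored eigenvalues are those of the training
*covariance* matrix: λ_d = s_d²/(n−1). This makes diag(λ) genuinely the
prior covariance C_b of the PCA coefficients, which is what the MMSE
estimator needs. Under the alternative convention λ_d = s_d² the trace is
pinned at ~74·(n−1), every retained λ_d is O(10²–10³), and the shrinkage
term σ_v²C_b⁻¹ is numerically inert for σ_v ≤ 0.3 — the estimator would
collapse to least squares everywhere on its grid, contradicting the
well-documented behaviour that the shrinkage matters (LSE degrades
sharply once the retained subspace picks up feature-poor directions;
MMSE recovers it). With the covariance scale, σ_v in 0.05 steps visibly
trades bias against noise amplification, as expected.

Coefficients are estimated from the feature block Y_g (lower 44 rows)
alone: LSE solves the normal equations; MMSE adds σ_v²·diag(1/λ_d).
With σ_v = 0 the two solve the identical system and coincide to the bit.
A singular normal matrix (e.g. D > 44, or D above the pool rank with
σ_v = 0) falls back to the pseudo-inverse with a warning. MMSE with
σ_v > 0 requires strictly positive λ; in grid sweeps, components beyond
the pool rank have zero prior variance and are therefore pinned to zero —
realised by clipping D at the rank, the exact λ→0 limit. Decoding
ẑ = Y b̂ and undoing the normalisation yields X̂ as the first 30 elements.

Parameter grids: D = 1…48, σ_v = 0, 0.05, …, 0.3.

## Modified GRNN

Each training record is a class c (linear index c = 12(r−1)+p over a
pool, 48 classes). The class likelihood is a full 8-D Gaussian with mean
ḡ_c and covariance C_c estimated from the class's 6145-sample feature
series (1/(T−1) normalisation). Similarity to a probe is the normal
density with covariance α²C_c + γI: the spread factor α ≥ 1 widens the
sparsely populated kernels, the stabiliser γ (default 10⁻⁶, uncritical)
keeps the matrix positive definite. The pose estimate is the weighted
mean X̂ = Σ w_c X_c with weights proportional to the similarities and
summed over **all 48 classes**.

Numerical choices: the Gaussian normalising constant is retained —
covariances differ per class, so determinants genuinely reweight classes.
Weights are computed in log space with max-subtraction; if even the best
class's direct density underflows (probe outside the populated feature
region), the estimate falls back to the single most likely class with a
warning. Cholesky factors and log-determinants are cached at fit time.
Parameter grid: α = 1…10.

## Stereo geometry

Cameras are plain projective 3×4 matrices (no lens distortion) estimated
by DLT with Hartley point normalisation; ≥6 non-coplanar correspondences
are required, coplanarity is detected from the singular values of the
centred node cloud. Rig quality is quantified by leave-one-node-out
calibration: each cube node in turn is held out, both cameras recalibrated
on the remaining 26, the node triangulated and its distance to truth
recorded; the RMS of the 27 distances is reported.

Triangulation uses inhomogeneous linear least squares (w = 1) with each
projection rescaled so the rotational part of its third row is a unit
vector. Both choices matter: the common homogeneous unit-norm formulation
is *not* equivariant under rigid transforms of the world frame, whereas
this one reproduces the leave-one-out RMS exactly when the cube is
expressed in a rotated/translated frame. Nearly parallel viewing rays
(no parallax) raise a warning.

Head motion is corrected by a rigid transform (Kabsch, det = +1 enforced,
no scaling) fitted on the six head markers and applied to all sixteen
points; (near-)collinear head markers are rejected. The common reference
frame is the rest pose of repetition 1, selection run 1. Coordinates are
millimetres; image coordinates are 0-based pixel centres.

## Error metrics and cross-validation

Manual marker selection is noisy, so raw RMS errors are corrected by the
intraobserver error e_obs (RMS discrepancy of two selection runs over ten
markers and thirteen poses; per-marker normaliser 1/130):

* displacement d_RMS (normaliser 1/600 over 12 poses × 5 repetitions ×
  10 markers) → d_c = √(d²_RMS − e²_obs), both selections noisy;
* estimation error e_RMS → e_c = √(e²_RMS − e²_obs/2), one selection run;
* e_r = e_c/d_c; and per-coordinate Pearson correlations over the 60
  records, averaged into ρ (zero-variance coordinates excluded with a
  warning).

Exact boundary values (corrected error exactly zero) are clamped against
float roundoff; genuinely negative corrected squares raise a domain error.

Cross-validation is leave-one-repetition-out: five folds, each repetition
tested exactly once (74×48 train, 74×12 test per fold); squared residuals
are pooled over all folds before the RMS. The settings grid search
averages e_c over volunteers per (configuration, feature, window,
parameters) cell and returns the argmin; ties break deterministically by
smaller window, smaller D or α, smaller σ_v, unipolar first, then the
feature order WAMP10, WAMP20, WL, MAV, RMS. Per-volunteer optima are also
reported. Volunteers whose folds fail in a cell are excluded from that
cell's average with a warning. Significance testing is available only as
a thin wrapper over the standard paired t-test.

## Synthetic volunteers

The generator emulates the study design with known ground truth:

* **Activation** A (13×8 in [0,1]): each active pose dominated by one
  muscle (draw 0.7–1.0), vowel-like poses 9–12 add a second muscle
  (0.35–0.6), plus a uniform cocontraction floor ε = 0.1 — untrained
  subjects cannot isolate facial muscles, so features are never clean
  one-hot patterns.
* **Kinematics**: X = X_rest + L·a + Q·(a⊗a) + N(0, σ_X²); per-muscle
  displacement fields in L have coherent directions with 6–12 mm
  magnitudes (realistic lip excursions), Q adds a small quadratic
  nonlinearity (0.2 mm scale). σ_X = 0.5 mm marker placement noise.
  A small rigid head motion (1.5°, 3 mm) is applied per record and must
  be undone by registration.
* **sEMG**: per-muscle band-limited (15–500 Hz) Gaussian carriers,
  amplitude-modulated by activation × gain (gains 30–60 mV so the WAMP
  thresholds 10/20 are genuinely exercised: counts sit mid-range, not
  saturated), mixed through a diagonally dominant crosstalk matrix
  (off-diagonal up to 0.2). Two electrodes per muscle with pickups 1.0
  and 0.55 share a common-mode noise term (1.5 mV) and carry independent
  baseline noise (2 mV); the bipolar derivation cancels the common mode.
* **Stereo**: two converging cameras (300 mm baseline, 600 mm from the
  face, 1200 px focal length), cube at the face position, pixel selection
  noise σ_px = 0.5 px. Two independent selection runs are generated so
  e_obs is measured exactly as in a real session.
* **Determinism**: all randomness flows from one integer seed through a
  `SeedSequence` splitting scheme (volunteer index, then separate streams
  for anatomy, poses, stereo, and each EMG record).

A `noise_scale` factor multiplies every noise source (σ_X, σ_px,
baseline, common mode) without touching the signal path. An analytic
feature oracle (the infinite-data limit of the RMS feature, i.e. the
channel amplitude envelope) supports exactly-noiseless estimator-recovery
tests; in that limit with a purely linear map, cross-validated PCA-LSE
error is zero to machine precision.

**What the generator does not emulate**: motor-unit physiology and firing
statistics, non-stationarity within a pose, electrode lift-off or motion
artefacts, lens distortion, soft-tissue coupling between muscles beyond
the linear+quadratic map, and between-repetition drift of electrode
placement. Passing tests therefore demonstrate correctness and
statistical behaviour of the estimators under the stated signal model,
not clinical performance on real recordings.

## Problem sizes and observed behaviour

The test suite runs full five-volunteer studies (60 records each, 4 s at
2048 Hz) in minutes on one CPU. The acceptance script evaluates the
cohort at the two volunteer-independent reference settings (PCA-MMSE:
unipolar WAMP-10/300 ms, D = 9, σ_v = 0.05; GRNN: bipolar MAV/50 ms,
α = 2). The end-to-end recovery test instead mirrors the full protocol —
a reduced settings grid (2 configurations × {WAMP10, MAV} × {50, 300} ms;
D ∈ {5, 9, 13, 17}, σ_v ∈ {0.05, 0.15, 0.3}, α ∈ {1, 2, 3, 5}) searched
by the volunteer-averaged criterion — and checks e_r ≤ 0.5 per volunteer
at the selected optimum (observed ≤ 0.24 for both methods), plus that
e_c decreases monotonically as all noise sources are scaled by 1, 0.5,
0.1. At the fixed reference setting without the settings search, e_r at
D = 9 ranges roughly 0.19–0.51 across synthetic volunteers — the hardest
volunteer sits at the bound, which is precisely the regime where the
study's own procedure relies on the settings search and on MMSE
shrinkage. Explained variance at D = 9 is 95–97 % on synthetic
volunteers; the per-class argmax of GRNN weights recovers the true pose
class essentially always when classes are well separated.

## Known limitations

* WAMP thresholds are taken at face value in the stored amplitude unit;
  with real µV-scale recordings they would need rescaling.
* EDF input is not supported (delimited text + JSON sidecar only).
* The GRNN lookup-table character means probes far outside the trained
  feature region degrade to nearest-class behaviour (warned, defined);
  smooth extrapolation is out of scope.
* No lens-distortion model, bundle adjustment, or missing-marker
  imputation; designs with missing (pose, repetition) cells are rejected
  rather than imputed.
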