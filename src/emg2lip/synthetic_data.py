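"""Synthetic volunteers with known ground truth for the full pipeline.

The study design emulated here: five volunteers adopt thirteen static poses
(a rest pose, seven facial expressions, five vowels) five times while eight
facial muscles are recorded at 2048 Hz and two calibrated cameras image ten
lip markers and six head markers.  Since no raw recordings are deposited,
this module generates complete synthetic volunteers:

* an activation matrix A (13 poses x 8 muscles in [0, 1], rest all zero) in
  which each active pose is dominated by one or two muscles plus a uniform
  cocontraction floor (real volunteers cannot isolate facial muscles);
* lip kinematics X = X_rest + L a + Q (a (x) a) + noise, with a linear map L
  (mm per unit activation), a small quadratic map Q, and marker-placement
  noise sigma_X;
* sEMG as band-limited (15-500 Hz) Gaussian carrier noise amplitude-
  modulated by activation, mixed through a diagonally dominant crosstalk
  matrix, with shared common-mode noise and per-electrode baseline noise;
  two electrodes per muscle are emitted so unipolar and bipolar
  configurations derive from the same recording.  The envelope is constant
  within a pose (poses are treated as stationary);
* a stereo rig (two projective cameras, ~600 mm from the face) and a
  10x10x10 cm calibration cube with 27 lattice nodes; pixel observations
  carry selection noise sigma_px, and two independent selection runs are
  produced so the intraobserver error can be measured exactly as in a real
  session.

All randomness flows from a single integer seed through a documented
`numpy.random.SeedSequence` splitting scheme: volunteer i uses
``SeedSequence([seed, i])``, which is split into independent streams for
anatomy, pose geometry, stereo selection runs, and one stream per EMG
record.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation as _Rotation

from . import signal_features as sf
from . import stereo_geometry as sg
from .evaluation import FeatureSetting, VolunteerDataset, intraobserver_error
from .signal_features import EMGRecording, quadratic_terms

__all__ = [
    "SyntheticVolunteer",
    "VolunteerBundle",
    "make_volunteer",
    "generate_poses",
    "generate_emg",
    "configure_recording",
    "default_cameras",
    "cube_nodes",
    "generate_stereo",
    "simulate_volunteer",
    "reconstruct_markers",
    "extract_dataset",
    "build_volunteer_dataset",
    "analytic_feature_vector",
    "build_exact_dataset",
]

N_POSES = 13  # rest + 12 active
N_REPS = 5
_ELECTRODE_PICKUPS = (1.0, 0.55)  # relative pickup of the two electrodes


@dataclass
class SyntheticVolunteer:
    """Generative parameters of one synthetic volunteer."""

    activation: np.ndarray  # (13, 8) in [0, 1]; row 0 (rest) all zeros
    L: np.ndarray  # (30, 8) mm displacement per unit activation
    Q: np.ndarray  # (30, 36) mm quadratic map (small by default)
    crosstalk: np.ndarray  # (8, 8), ones on the diagonal, dominant
    gains: np.ndarray  # (8,) carrier amplitude per channel, mV
    rest_lip: np.ndarray  # (10, 3) mm, face frame
    rest_head: np.ndarray  # (6, 3) mm, face frame
    sigma_x: float  # marker placement noise, mm
    sigma_px: float  # pixel selection noise, px
    baseline_mv: float  # per-electrode baseline noise, mV
    common_mode_mv: float  # shared common-mode noise, mV
    seed: int
    index: int = 0

    def __post_init__(self) -> None:
        a = np.asarray(self.activation, dtype=float)
        if a.shape != (N_POSES, 8) or np.any(a < 0) or np.any(a > 1):
            raise ValueError("activation must be (13, 8) within [0, 1]")
        if np.any(a[0] != 0):
            raise ValueError("rest pose (row 0) must have zero activation")
        C = np.asarray(self.crosstalk, dtype=float)
        off = C - np.diag(np.diag(C))
        if np.any(np.abs(off).sum(axis=1) >= np.diag(C)):
            raise ValueError("crosstalk matrix must be diagonally dominant")

    def seed_sequence(self) -> np.random.SeedSequence:
        return np.random.SeedSequence([self.seed, self.index])


def make_volunteer(
    seed: int,
    index: int = 0,
    *,
    sigma_x: float = 0.5,
    sigma_px: float = 0.5,
    c_max: float = 0.2,
    noise_scale: float = 1.0,
    quadratic_scale: float = 0.2,
    cocontraction: float = 0.1,
) -> SyntheticVolunteer:
    """Draw a volunteer's anatomy and acquisition parameters.

    ``noise_scale`` multiplies every *noise* source (marker placement,
    pixel selection, EMG baseline and common mode) without touching the
    signal path, so estimation error can be studied as noise shrinks.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, index, 0]))

    activation = np.zeros((N_POSES, 8))
    for p in range(1, N_POSES):
        primary = (p - 1) % 8
        activation[p, primary] = rng.uniform(0.7, 1.0)
        if p > 8:  # vowel-like poses blend a second muscle
            secondary = (primary + rng.integers(1, 8)) % 8
            activation[p, secondary] = rng.uniform(0.35, 0.6)
        activation[p] = np.clip(activation[p] + cocontraction, 0, 1)

    # lip markers on a mouth-shaped ellipse; head markers around the orbits
    theta = np.linspace(0, 2 * np.pi, 10, endpoint=False)
    rest_lip = np.column_stack(
        [28 * np.cos(theta), 13 * np.sin(theta) - 30, 8 * np.cos(theta) ** 2]
    )
    rest_head = np.array(
        [
            [-32.0, 18.0, 4.0],
            [32.0, 18.0, 4.0],  # infraorbital
            [-36.0, 52.0, 0.0],
            [36.0, 52.0, 0.0],  # supraorbital
            [-12.0, 34.0, 16.0],
            [12.0, 34.0, 16.0],  # nose
        ]
    )

    # per-muscle displacement fields: coherent direction, per-marker falloff
    L = np.zeros((30, 8))
    for j in range(8):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        magnitude = rng.uniform(6.0, 12.0)
        weights = rng.uniform(0.3, 1.0, size=10)
        field3 = weights[:, None] * direction[None, :] * magnitude
        field3 += rng.normal(scale=0.15 * magnitude, size=(10, 3))
        L[:, j] = field3.reshape(30)
    Q = rng.normal(scale=quadratic_scale, size=(30, 36))

    crosstalk = np.eye(8)
    off = rng.uniform(0.0, c_max, size=(8, 8))
    np.fill_diagonal(off, 0.0)
    row_sums = off.sum(axis=1)
    too_big = row_sums > 0.9
    off[too_big] *= (0.9 / row_sums[too_big])[:, None]
    crosstalk += off

    gains = rng.uniform(30.0, 60.0, size=8)

    return SyntheticVolunteer(
        activation=activation,
        L=L,
        Q=Q,
        crosstalk=crosstalk,
        gains=gains,
        rest_lip=rest_lip,
        rest_head=rest_head,
        sigma_x=sigma_x * noise_scale,
        sigma_px=sigma_px * noise_scale,
        baseline_mv=2.0 * noise_scale,
        common_mode_mv=1.5 * noise_scale,
        seed=seed,
        index=index,
    )


def _pose_displacement(vol: SyntheticVolunteer, pose_id: int) -> np.ndarray:
    a = vol.activation[pose_id]
    return vol.L @ a + vol.Q @ quadratic_terms(a)


def generate_poses(
    vol: SyntheticVolunteer,
    head_motion_deg: float = 1.5,
    head_motion_mm: float = 3.0,
) -> dict[tuple[int, int], sg.MarkerSet]:
    """Physical marker positions for all 13 poses x 5 repetitions.

    Lip markers get placement noise sigma_X; each (pose, repetition) adds a
    small rigid head motion (rotation + translation) to all 16 markers,
    which downstream registration must undo.  Deterministic per volunteer.
    """
    rng = np.random.default_rng(vol.seed_sequence().spawn(1)[0])
    out: dict[tuple[int, int], sg.MarkerSet] = {}
    for r in range(1, N_REPS + 1):
        for p in range(N_POSES):
            lip = vol.rest_lip + _pose_displacement(vol, p).reshape(10, 3)
            lip = lip + rng.normal(scale=vol.sigma_x, size=(10, 3)) \
                if vol.sigma_x > 0 else lip
            head = vol.rest_head
            rotvec = rng.normal(scale=np.deg2rad(head_motion_deg), size=3)
            shift = rng.normal(scale=head_motion_mm, size=3)
            R = _Rotation.from_rotvec(rotvec).as_matrix()
            out[(p, r)] = sg.MarkerSet(
                lip=lip @ R.T + shift,
                head=head @ R.T + shift,
                pose_id=p,
                repetition_id=r,
            )
    return out


def _bandlimited_noise(rng: np.random.Generator, shape, fs: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to 15-500 Hz."""
    from scipy import signal as _signal

    sos = _signal.butter(4, [15.0, 500.0], btype="band", fs=fs, output="sos")
    x = _signal.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    return x / x.std(axis=-1, keepdims=True)


def generate_emg(
    vol: SyntheticVolunteer,
    pose_id: int,
    repetition_id: int = 1,
    duration: float = 4.0,
    fs: float = 2048.0,
    rng: np.random.Generator | None = None,
) -> EMGRecording:
    """One 16-electrode unipolar sEMG record (two electrodes per muscle).

    Electrode k over muscle i picks up ``pickup_k * mix_i(t)`` plus the
    shared common-mode noise and its own baseline noise, where
    ``mix_i = sum_j C_ij a_j gain_j n_j(t)`` mixes the per-muscle
    band-limited carriers through the crosstalk matrix.  The bipolar
    derivation therefore cancels the common mode while retaining
    ``(pickup_1 - pickup_2) * mix_i``.
    """
    if rng is None:
        ss = vol.seed_sequence()
        child = np.random.SeedSequence(
            entropy=ss.entropy, spawn_key=(2, pose_id, repetition_id)
        )
        rng = np.random.default_rng(child)
    n = int(round(duration * fs))
    a = vol.activation[pose_id]
    carriers = _bandlimited_noise(rng, (8, n), fs)
    mix = (vol.crosstalk * (a * vol.gains)[None, :]) @ carriers  # (8, n)
    common = vol.common_mode_mv * _bandlimited_noise(rng, (1, n), fs)
    samples = np.empty((16, n))
    labels = []
    for i, muscle in enumerate(sf.MUSCLES):
        for k, pickup in enumerate(_ELECTRODE_PICKUPS):
            noise = vol.baseline_mv * rng.standard_normal(n)
            samples[2 * i + k] = pickup * mix[i] + common[0] + noise
            labels.append(f"{muscle}_{k + 1}")
    return EMGRecording(
        samples=samples,
        fs=fs,
        configuration="unipolar",
        channel_labels=tuple(labels),
        pose_id=pose_id,
        repetition_id=repetition_id,
    )


def configure_recording(rec16: EMGRecording, configuration: str) -> EMGRecording:
    """Reduce a 16-electrode record to the 8-channel configuration:
    unipolar keeps the first electrode of each pair, bipolar differences
    the pairs."""
    if configuration == "bipolar":
        return sf.derive_bipolar(rec16)
    if configuration != "unipolar":
        raise ValueError("configuration must be 'unipolar' or 'bipolar'")
    from dataclasses import replace

    return replace(
        rec16,
        samples=rec16.samples[0::2].copy(),
        channel_labels=sf.MUSCLES,
        configuration="unipolar",
    )


def _look_at_camera(position: np.ndarray, focal_px: float = 1200.0) -> sg.CameraModel:
    position = np.asarray(position, dtype=float)
    forward = -position / np.linalg.norm(position)  # towards the origin
    up = np.array([0.0, 1.0, 0.0])
    right = np.cross(up, forward)
    right /= np.linalg.norm(right)
    down = np.cross(forward, right)
    R = np.vstack([right, down, forward])
    K = np.array([[focal_px, 0, 640.0], [0, focal_px, 480.0], [0, 0, 1.0]])
    P = K @ np.hstack([R, (-R @ position)[:, None]])
    return sg.CameraModel(projection=P / np.linalg.norm(P), image_size=(1280, 960))


def default_cameras(
    baseline_mm: float = 300.0, distance_mm: float = 600.0
) -> tuple[sg.CameraModel, sg.CameraModel]:
    """Converging stereo pair in front of the face (origin)."""
    half = baseline_mm / 2.0
    return (
        _look_at_camera([-half, 0.0, -distance_mm]),
        _look_at_camera([half, 0.0, -distance_mm]),
    )


def cube_nodes(edge_mm: float = 100.0) -> np.ndarray:
    """27 nodes on the 3 x 3 x 3 lattice of a wireframe calibration cube,
    centred on the origin (the volunteer's face position)."""
    g = np.array([-edge_mm / 2, 0.0, edge_mm / 2])
    return np.array([[x, y, z] for x in g for y in g for z in g])


def generate_stereo(
    cameras: tuple[sg.CameraModel, sg.CameraModel],
    points: np.ndarray,
    sigma_px: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Project points through both cameras and add pixel selection noise."""
    pix = []
    for cam in cameras:
        p = sg.project(cam, points)
        if sigma_px > 0:
            p = p + rng.normal(scale=sigma_px, size=p.shape)
        pix.append(p)
    return pix[0], pix[1]


@dataclass
class VolunteerBundle:
    """Raw synthetic acquisition for one volunteer (pre-analysis)."""

    volunteer: SyntheticVolunteer
    cameras: tuple[sg.CameraModel, sg.CameraModel]
    cube: np.ndarray  # (27, 3) true node positions
    cube_pixels: tuple[np.ndarray, np.ndarray]  # noisy (27, 2) per camera
    physical: dict[tuple[int, int], sg.MarkerSet]
    # (pose, rep, selection_run) -> (pixels_cam_a, pixels_cam_b); rows are
    # the 10 lip markers followed by the 6 head markers
    pixel_obs: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]]
    recordings: dict[tuple[int, int], EMGRecording]
    fs: float = 2048.0
    _registered: dict = field(default_factory=dict, repr=False)


def simulate_volunteer(
    vol: SyntheticVolunteer,
    duration: float = 4.0,
    fs: float = 2048.0,
    active_poses_only: bool = True,
) -> VolunteerBundle:
    """Run the full synthetic acquisition: poses, stereo images of every
    pose in two selection runs, cube calibration images, and sEMG."""
    ss = vol.seed_sequence()
    stereo_rng = np.random.default_rng(
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=(3,))
    )
    cameras = default_cameras()
    cube = cube_nodes()
    cube_pixels = generate_stereo(cameras, cube, vol.sigma_px, stereo_rng)
    physical = generate_poses(vol)
    pixel_obs: dict[tuple[int, int, int], tuple[np.ndarray, np.ndarray]] = {}
    for run in (1, 2):
        for (p, r), ms in physical.items():
            pts = np.vstack([ms.lip, ms.head])
            pixel_obs[(p, r, run)] = generate_stereo(
                cameras, pts, vol.sigma_px, stereo_rng
            )
    recordings: dict[tuple[int, int], EMGRecording] = {}
    poses = range(1, N_POSES) if active_poses_only else range(N_POSES)
    for r in range(1, N_REPS + 1):
        for p in poses:
            recordings[(p, r)] = generate_emg(vol, p, r, duration=duration, fs=fs)
    return VolunteerBundle(
        volunteer=vol,
        cameras=cameras,
        cube=cube,
        cube_pixels=cube_pixels,
        physical=physical,
        pixel_obs=pixel_obs,
        recordings=recordings,
        fs=fs,
    )


def reconstruct_markers(bundle: VolunteerBundle):
    """Calibrate, triangulate and register both selection runs.

    Returns ``(markers_run1, markers_run2, e_obs)`` where each markers dict
    maps (pose, repetition) to a registered :class:`MarkerSet` and e_obs is
    the intraobserver error over the 13 poses of repetition 1.  The
    reference frame is the rest pose of repetition 1, selection run 1.
    Results are cached on the bundle.
    """
    if bundle._registered:
        return (
            bundle._registered["run1"],
            bundle._registered["run2"],
            bundle._registered["e_obs"],
        )
    cam_a = sg.calibrate_dlt(bundle.cube, bundle.cube_pixels[0])
    cam_b = sg.calibrate_dlt(bundle.cube, bundle.cube_pixels[1])
    raw: dict[int, dict[tuple[int, int], sg.MarkerSet]] = {1: {}, 2: {}}
    for (p, r, run), (pa, pb) in bundle.pixel_obs.items():
        pts = sg.triangulate_many(pa, pb, cam_a, cam_b)
        raw[run][(p, r)] = sg.MarkerSet(
            lip=pts[:10], head=pts[10:], pose_id=p, repetition_id=r
        )
    reference_head = raw[1][(0, 1)].head
    registered: dict[int, dict[tuple[int, int], sg.MarkerSet]] = {1: {}, 2: {}}
    for run in (1, 2):
        for key, ms in raw[run].items():
            registered[run][key], _ = sg.register_to_reference(ms, reference_head)
    sel1 = np.array([registered[1][(p, 1)].x_vector for p in range(N_POSES)])
    sel2 = np.array([registered[2][(p, 1)].x_vector for p in range(N_POSES)])
    e_obs = intraobserver_error(sel1, sel2)
    bundle._registered = {"run1": registered[1], "run2": registered[2], "e_obs": e_obs}
    return registered[1], registered[2], e_obs


def extract_dataset(
    bundle: VolunteerBundle,
    setting: FeatureSetting,
    include_series: bool = True,
    truncate_to: int = sf.TARGET_FEATURE_SAMPLES,
) -> VolunteerDataset:
    """Assemble the cross-validation dataset at one feature/window setting."""
    from .pipeline import featureize_recording

    markers, _, e_obs = reconstruct_markers(bundle)
    X = np.empty((12, N_REPS, 30))
    rest = np.empty((N_REPS, 30))
    gbar = np.empty((12, N_REPS, 8))
    gaug = np.empty((12, N_REPS, 44))
    series = np.empty((12, N_REPS, truncate_to, 8)) if include_series else None
    for r in range(1, N_REPS + 1):
        rest[r - 1] = markers[(0, r)].x_vector
        for p in range(1, N_POSES):
            X[p - 1, r - 1] = markers[(p, r)].x_vector
            fv, fseries = featureize_recording(
                bundle.recordings[(p, r)], setting, truncate_to=truncate_to
            )
            gbar[p - 1, r - 1] = fv.gbar
            gaug[p - 1, r - 1] = fv.gbar_aug
            if include_series:
                series[p - 1, r - 1] = fseries.values.T
    return VolunteerDataset(
        X=X,
        rest=rest,
        gbar=gbar,
        gbar_aug=gaug,
        e_obs=e_obs,
        series=series,
        volunteer_id=bundle.volunteer.index,
        setting=setting,
    )


def build_volunteer_dataset(
    seed: int,
    index: int = 0,
    setting: FeatureSetting | None = None,
    *,
    noise_scale: float = 1.0,
    duration: float = 4.0,
    include_series: bool = True,
    **volunteer_kwargs,
) -> VolunteerDataset:
    """One-call convenience: volunteer -> acquisition -> dataset."""
    if setting is None:
        setting = FeatureSetting("unipolar", "WAMP", 300, 10.0)
    vol = make_volunteer(seed, index, noise_scale=noise_scale, **volunteer_kwargs)
    bundle = simulate_volunteer(vol, duration=duration)
    return extract_dataset(bundle, setting, include_series=include_series)


def analytic_feature_vector(
    vol: SyntheticVolunteer, pose_id: int, configuration: str = "unipolar"
) -> np.ndarray:
    """Deterministic infinite-data limit of the RMS feature vector.

    For the stationary Gaussian signal model the per-channel RMS feature
    converges to the channel's amplitude envelope; this closed form is the
    oracle used for noiseless estimator-recovery tests.
    """
    a = vol.activation[pose_id]
    mix_var = np.sum((vol.crosstalk * (a * vol.gains)[None, :]) ** 2, axis=1)
    if configuration == "unipolar":
        var = mix_var + vol.baseline_mv**2 + vol.common_mode_mv**2
    elif configuration == "bipolar":
        dp = _ELECTRODE_PICKUPS[0] - _ELECTRODE_PICKUPS[1]
        var = dp**2 * mix_var + 2 * vol.baseline_mv**2
    else:
        raise ValueError("configuration must be 'unipolar' or 'bipolar'")
    return np.sqrt(var)


def build_exact_dataset(
    vol: SyntheticVolunteer,
    configuration: str = "unipolar",
    series_length: int = 4,
) -> VolunteerDataset:
    """Noiseless dataset from the analytic feature oracle.

    Marker positions come straight from the generative map (no stereo
    chain, no placement noise beyond the volunteer's own sigma_x = 0
    expectation), features from :func:`analytic_feature_vector`, and the
    feature 'series' is the constant vector repeated (so GRNN covariances
    are zero and similarity is driven by the gamma stabiliser).
    """
    X = np.empty((12, N_REPS, 30))
    rest = np.tile(vol.rest_lip.reshape(30), (N_REPS, 1))
    gbar = np.empty((12, N_REPS, 8))
    for p in range(1, N_POSES):
        x = vol.rest_lip.reshape(30) + _pose_displacement(vol, p)
        g = analytic_feature_vector(vol, p, configuration)
        X[p - 1, :] = x
        gbar[p - 1, :] = g
    gaug = np.apply_along_axis(sf.augment_quadratic, 2, gbar)
    series = np.broadcast_to(
        gbar[:, :, None, :], (12, N_REPS, series_length, 8)
    ).copy()
    return VolunteerDataset(
        X=X,
        rest=rest,
        gbar=gbar,
        gbar_aug=gaug,
        e_obs=0.0,
        series=series,
        volunteer_id=vol.index,
        setting=FeatureSetting(configuration, "RMS", 300),
    )
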