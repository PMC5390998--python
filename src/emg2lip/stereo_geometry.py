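"""Stereo landmark geometry: DLT calibration, triangulation, registration.

Two consumer cameras are calibrated with a 10x10x10 cm wireframe cube
carrying 27 nodes at known positions.  Marker pixel pairs are triangulated
into millimetre 3D coordinates, and every pose is registered to a common
reference frame with a rigid (rotation + translation, no scaling) transform
fitted on six facial head markers, correcting for head motion.

The camera model is a plain projective 3x4 matrix (direct linear transform,
no lens distortion); image coordinates are 0-based pixel centres.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "CameraModel",
    "MarkerSet",
    "CalibrationDegeneracyError",
    "RegistrationError",
    "IllConditionedTriangulation",
    "project",
    "calibrate_dlt",
    "calibrate_stereo",
    "reprojection_rms",
    "triangulate",
    "triangulate_many",
    "loo_calibration_rms",
    "rigid_fit",
    "register_to_reference",
]


class CalibrationDegeneracyError(ValueError):
    """Calibration points insufficient or (near-)coplanar."""


class RegistrationError(ValueError):
    """Head markers degenerate (collinear) for rigid registration."""


class IllConditionedTriangulation(UserWarning):
    """Viewing rays nearly parallel; triangulated depth is unreliable."""


@dataclass
class CameraModel:
    """Projective camera: pixel = dehomogenise(P @ [X; 1])."""

    projection: np.ndarray  # 3 x 4
    image_size: tuple[int, int] | None = None
    reprojection_rms: float | None = None

    def __post_init__(self) -> None:
        self.projection = np.asarray(self.projection, dtype=float)
        if self.projection.shape != (3, 4):
            raise ValueError("projection must be 3x4")
        if np.linalg.matrix_rank(self.projection) != 3:
            raise ValueError("projection must have rank 3")


@dataclass
class MarkerSet:
    """Ten lip markers and six head markers (mm) for one (pose, repetition)."""

    lip: np.ndarray  # 10 x 3
    head: np.ndarray  # 6 x 3
    pose_id: int = 0
    repetition_id: int = 1

    def __post_init__(self) -> None:
        self.lip = np.asarray(self.lip, dtype=float)
        self.head = np.asarray(self.head, dtype=float)
        if self.lip.shape != (10, 3):
            raise ValueError("expected exactly 10 lip markers with 3 coordinates")
        if self.head.shape != (6, 3):
            raise ValueError("expected exactly 6 head markers with 3 coordinates")
        if not (np.all(np.isfinite(self.lip)) and np.all(np.isfinite(self.head))):
            raise ValueError("marker coordinates must be finite")

    @property
    def x_vector(self) -> np.ndarray:
        """Flattened 30-coordinate lip vector X(p, r)."""
        return self.lip.reshape(30)


def project(camera: CameraModel, points: np.ndarray) -> np.ndarray:
    """Project (M, 3) world points (mm) to (M, 2) pixel coordinates."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    hom = camera.projection @ np.hstack([pts, np.ones((pts.shape[0], 1))]).T
    depth = hom[2]
    if np.any(depth <= 0):
        raise ValueError("point behind camera (non-positive projective depth)")
    return (hom[:2] / depth).T


def _normalise_points(pts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Similarity transform putting the centroid at 0 and the mean distance
    at sqrt(dim); returns (transformed points, homogeneous transform)."""
    pts = np.asarray(pts, dtype=float)
    dim = pts.shape[1]
    centroid = pts.mean(axis=0)
    dist = np.linalg.norm(pts - centroid, axis=1).mean()
    scale = np.sqrt(dim) / dist if dist > 0 else 1.0
    T = np.eye(dim + 1)
    T[:dim, :dim] *= scale
    T[:dim, dim] = -scale * centroid
    return (pts - centroid) * scale, T


def calibrate_dlt(nodes3d: np.ndarray, pixels: np.ndarray) -> CameraModel:
    """Direct-linear-transform calibration from 2D-3D correspondences.

    Minimises the algebraic reprojection residual over all 3x4 projections
    (with Hartley point normalisation for conditioning).  Requires at least
    6 non-coplanar correspondences.
    """
    nodes3d = np.asarray(nodes3d, dtype=float)
    pixels = np.asarray(pixels, dtype=float)
    m = nodes3d.shape[0]
    if m < 6 or pixels.shape[0] != m:
        raise CalibrationDegeneracyError(
            "need at least 6 matching 3D-2D correspondences"
        )
    spread = np.linalg.svd(nodes3d - nodes3d.mean(axis=0), compute_uv=False)
    if spread[2] < 1e-9 * max(spread[0], 1.0):
        raise CalibrationDegeneracyError("calibration points are (near-)coplanar")

    Xn, T3 = _normalise_points(nodes3d)
    xn, T2 = _normalise_points(pixels)
    A = np.zeros((2 * m, 12))
    Xh = np.hstack([Xn, np.ones((m, 1))])
    A[0::2, 0:4] = Xh
    A[0::2, 8:12] = -xn[:, [0]] * Xh
    A[1::2, 4:8] = Xh
    A[1::2, 8:12] = -xn[:, [1]] * Xh
    _, _, vt = np.linalg.svd(A)
    Pn = vt[-1].reshape(3, 4)
    P = np.linalg.inv(T2) @ Pn @ T3
    # fix overall sign so projective depths are positive
    hom = P @ np.hstack([nodes3d, np.ones((m, 1))]).T
    if np.median(hom[2]) < 0:
        P = -P
    P /= np.linalg.norm(P)
    cam = CameraModel(projection=P)
    cam.reprojection_rms = reprojection_rms(cam, nodes3d, pixels)
    return cam


def reprojection_rms(camera: CameraModel, nodes3d: np.ndarray, pixels: np.ndarray) -> float:
    """RMS pixel distance between projected points and observed pixels."""
    res = project(camera, nodes3d) - np.asarray(pixels, dtype=float)
    return float(np.sqrt(np.mean(np.sum(res**2, axis=1))))


def calibrate_stereo(
    nodes3d: np.ndarray, pixels_a: np.ndarray, pixels_b: np.ndarray
) -> tuple[CameraModel, CameraModel]:
    """Calibrate both cameras of the stereo rig from the same cube nodes."""
    return calibrate_dlt(nodes3d, pixels_a), calibrate_dlt(nodes3d, pixels_b)


def triangulate(
    pixel_pair: np.ndarray, camera_a: CameraModel, camera_b: CameraModel
) -> np.ndarray:
    """Linear least-squares triangulation of one pixel pair into 3D (mm).

    ``pixel_pair`` is ((u_a, v_a), (u_b, v_b)).  Warns when the two viewing
    rays are nearly parallel (e.g. identical cameras: no parallax).
    """
    (ua, va), (ub, vb) = np.asarray(pixel_pair, dtype=float)
    # scale each projection so the rotational part of its third row is a
    # unit vector: the row weighting then survives rigid world transforms
    Pa = camera_a.projection / np.linalg.norm(camera_a.projection[2, :3])
    Pb = camera_b.projection / np.linalg.norm(camera_b.projection[2, :3])
    A = np.vstack(
        [
            ua * Pa[2] - Pa[0],
            va * Pa[2] - Pa[1],
            ub * Pb[2] - Pb[0],
            vb * Pb[2] - Pb[1],
        ]
    )
    # inhomogeneous linear LS (w = 1): exactly equivariant under rigid
    # transforms of the world frame, unlike the unit-norm homogeneous form
    M, rhs = A[:, :3], -A[:, 3]
    s = np.linalg.svd(M, compute_uv=False)
    if s[2] < 1e-10 * s[0]:
        warnings.warn(
            "triangulation ill-conditioned: viewing rays nearly parallel",
            IllConditionedTriangulation,
        )
    X, *_ = np.linalg.lstsq(M, rhs, rcond=None)
    return X


def triangulate_many(
    pixels_a: np.ndarray, pixels_b: np.ndarray, camera_a: CameraModel, camera_b: CameraModel
) -> np.ndarray:
    """Triangulate (M, 2) pixel arrays from both cameras into (M, 3) mm."""
    pixels_a = np.atleast_2d(pixels_a)
    pixels_b = np.atleast_2d(pixels_b)
    return np.array(
        [
            triangulate((pa, pb), camera_a, camera_b)
            for pa, pb in zip(pixels_a, pixels_b)
        ]
    )


def loo_calibration_rms(
    nodes3d: np.ndarray, pixels_a: np.ndarray, pixels_b: np.ndarray
) -> float:
    """Leave-one-node-out calibration error of the stereo rig (mm).

    Each node in turn is held out, both cameras are recalibrated on the
    remaining nodes, the held-out node is triangulated from its pixel pair,
    and its Euclidean distance to the true position is recorded.  Returns
    the RMS of the per-node distances (27 for the full cube).
    """
    nodes3d = np.asarray(nodes3d, dtype=float)
    m = nodes3d.shape[0]
    sq = np.empty(m)
    for k in range(m):
        keep = np.arange(m) != k
        cam_a = calibrate_dlt(nodes3d[keep], pixels_a[keep])
        cam_b = calibrate_dlt(nodes3d[keep], pixels_b[keep])
        est = triangulate((pixels_a[k], pixels_b[k]), cam_a, cam_b)
        sq[k] = np.sum((est - nodes3d[k]) ** 2)
    return float(np.sqrt(sq.mean()))


def rigid_fit(source: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) with R @ source_i + t ~ target_i.

    Kabsch/orthogonal-Procrustes with reflections disallowed (det R = +1).
    Raises when the source points are (near-)collinear, which leaves the
    rotation about the line undetermined.
    """
    src = np.asarray(source, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if src.shape != tgt.shape or src.shape[1] != 3:
        raise ValueError("source and target must both be (M, 3)")
    mu_s, mu_t = src.mean(axis=0), tgt.mean(axis=0)
    H = (src - mu_s).T @ (tgt - mu_t)
    spread = np.linalg.svd(src - mu_s, compute_uv=False)
    if spread[1] < 1e-8 * max(spread[0], 1.0):
        raise RegistrationError("registration points are (near-)collinear")
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = mu_t - R @ mu_s
    return R, t


def register_to_reference(
    markers: MarkerSet, reference_head: np.ndarray
) -> tuple[MarkerSet, float]:
    """Register a marker set to the reference frame via its head markers.

    The rigid transform is fitted on the six head markers only and applied
    to all sixteen points.  Returns the registered set and the residual
    head-marker RMS (mm) after registration.
    """
    reference_head = np.asarray(reference_head, dtype=float)
    R, t = rigid_fit(markers.head, reference_head)
    head = markers.head @ R.T + t
    lip = markers.lip @ R.T + t
    residual = float(np.sqrt(np.mean(np.sum((head - reference_head) ** 2, axis=1))))
    return replace(markers, lip=lip, head=head), residual
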