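"""Delimited-text and model serialisation formats.

All tabular formats are plain delimited text (CSV) with a single header
row; binary arrays of fitted models go into an NPZ container next to a
JSON header.  sEMG records are a CSV (one column per channel, header row
of channel labels) with a JSON sidecar carrying the sampling rate,
configuration and pose/repetition labels.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import grnn_regression as grnn
from . import pca_regression as pca
from .signal_features import EMGRecording
from .stereo_geometry import CameraModel, MarkerSet

__all__ = [
    "write_emg",
    "read_emg",
    "write_cube_nodes",
    "read_cube_nodes",
    "write_cube_pixels",
    "read_cube_pixels",
    "write_marker_pixels",
    "read_marker_pixels",
    "write_markers3d",
    "read_markers3d",
    "write_cameras",
    "read_cameras",
    "save_pca_model",
    "load_pca_model",
    "save_grnn_model",
    "load_grnn_model",
    "file_checksum",
    "update_manifest",
]

_FLOAT_FMT = "%.8g"


def write_emg(path: Path, recording: EMGRecording) -> None:
    path = Path(path)
    df = pd.DataFrame(recording.samples.T, columns=list(recording.channel_labels))
    df.to_csv(path, index=False, float_format="%.5f")
    sidecar = {
        "fs": recording.fs,
        "configuration": recording.configuration,
        "pose_id": recording.pose_id,
        "repetition_id": recording.repetition_id,
        "channel_labels": list(recording.channel_labels),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_emg(path: Path) -> EMGRecording:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    return EMGRecording(
        samples=df.to_numpy().T,
        fs=meta["fs"],
        configuration=meta["configuration"],
        channel_labels=tuple(meta["channel_labels"]),
        pose_id=meta["pose_id"],
        repetition_id=meta["repetition_id"],
    )


def write_cube_nodes(path: Path, nodes3d: np.ndarray) -> None:
    df = pd.DataFrame(nodes3d, columns=["x", "y", "z"])
    df.insert(0, "node_id", np.arange(len(df)))
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_cube_nodes(path: Path) -> np.ndarray:
    return pd.read_csv(path).sort_values("node_id")[["x", "y", "z"]].to_numpy()


def write_cube_pixels(path: Path, pixels_a: np.ndarray, pixels_b: np.ndarray) -> None:
    rows = []
    for cam_id, pix in ((0, pixels_a), (1, pixels_b)):
        for node_id, (u, v) in enumerate(pix):
            rows.append((node_id, cam_id, u, v))
    pd.DataFrame(rows, columns=["node_id", "camera_id", "u", "v"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_cube_pixels(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    out = []
    for cam_id in (0, 1):
        sub = df[df.camera_id == cam_id].sort_values("node_id")
        out.append(sub[["u", "v"]].to_numpy())
    return out[0], out[1]


_ROLES = ["lip"] * 10 + ["head"] * 6


def write_marker_pixels(
    path: Path, pixels_a: np.ndarray, pixels_b: np.ndarray
) -> None:
    """Marker pixel file: rows 0-9 are lip markers, 10-15 head markers."""
    rows = []
    for cam_id, pix in ((0, pixels_a), (1, pixels_b)):
        for marker_id, (u, v) in enumerate(pix):
            rows.append((marker_id, _ROLES[marker_id], cam_id, u, v))
    pd.DataFrame(rows, columns=["marker_id", "role", "camera_id", "u", "v"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


def read_marker_pixels(path: Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    out = []
    for cam_id in (0, 1):
        sub = df[df.camera_id == cam_id].sort_values("marker_id")
        out.append(sub[["u", "v"]].to_numpy())
    return out[0], out[1]


def write_markers3d(path: Path, markers: dict[tuple[int, int], MarkerSet]) -> None:
    rows = []
    for (p, r), ms in sorted(markers.items()):
        pts = np.vstack([ms.lip, ms.head])
        for marker_id, (x, y, z) in enumerate(pts):
            rows.append((p, r, marker_id, _ROLES[marker_id], x, y, z))
    pd.DataFrame(
        rows, columns=["pose_id", "repetition_id", "marker_id", "role", "x", "y", "z"]
    ).to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_markers3d(path: Path) -> dict[tuple[int, int], MarkerSet]:
    df = pd.read_csv(path)
    out: dict[tuple[int, int], MarkerSet] = {}
    for (p, r), sub in df.groupby(["pose_id", "repetition_id"]):
        sub = sub.sort_values("marker_id")
        pts = sub[["x", "y", "z"]].to_numpy()
        out[(int(p), int(r))] = MarkerSet(
            lip=pts[:10], head=pts[10:], pose_id=int(p), repetition_id=int(r)
        )
    return out


def write_cameras(path: Path, cam_a: CameraModel, cam_b: CameraModel) -> None:
    data = {}
    for name, cam in (("camera_a", cam_a), ("camera_b", cam_b)):
        data[name] = {
            "projection": cam.projection.tolist(),
            "reprojection_rms": cam.reprojection_rms,
        }
    Path(path).write_text(json.dumps(data, indent=1))


def read_cameras(path: Path) -> tuple[CameraModel, CameraModel]:
    data = json.loads(Path(path).read_text())
    cams = []
    for name in ("camera_a", "camera_b"):
        cam = CameraModel(projection=np.array(data[name]["projection"]))
        cam.reprojection_rms = data[name]["reprojection_rms"]
        cams.append(cam)
    return cams[0], cams[1]


def save_pca_model(stem: Path, model: pca.PCAModel) -> None:
    """JSON header (D, sigma_v) + NPZ arrays (mean, var, Y, lambdas)."""
    stem = Path(stem)
    stem.with_suffix(".json").write_text(
        json.dumps({"kind": "pca", "D": model.D, "sigma_v": model.sigma_v}, indent=1)
    )
    np.savez(
        stem.with_suffix(".npz"),
        mean=model.mean,
        var=model.var,
        Y=model.Y,
        lambdas=model.lambdas,
        all_lambdas=model.all_lambdas if model.all_lambdas is not None else model.lambdas,
    )


def load_pca_model(stem: Path) -> pca.PCAModel:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    arrays = np.load(stem.with_suffix(".npz"))
    return pca.PCAModel(
        mean=arrays["mean"],
        var=arrays["var"],
        Y=arrays["Y"],
        lambdas=arrays["lambdas"],
        sigma_v=meta["sigma_v"],
        all_lambdas=arrays["all_lambdas"],
    )


def save_grnn_model(stem: Path, model: grnn.GRNNModel) -> None:
    stem = Path(stem)
    stem.with_suffix(".json").write_text(
        json.dumps(
            {"kind": "grnn", "alpha": model.alpha, "gamma": model.gamma}, indent=1
        )
    )
    np.savez(stem.with_suffix(".npz"), mu=model.mu, cov=model.cov, X=model.X)


def load_grnn_model(stem: Path) -> grnn.GRNNModel:
    stem = Path(stem)
    meta = json.loads(stem.with_suffix(".json").read_text())
    arrays = np.load(stem.with_suffix(".npz"))
    return grnn.GRNNModel(
        mu=arrays["mu"],
        cov=arrays["cov"],
        X=arrays["X"],
        alpha=meta["alpha"],
        gamma=meta["gamma"],
    )


def file_checksum(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def update_manifest(out_dir: Path, command: str, params: dict, outputs: list[Path]) -> None:
    """Append a reproducibility record to the run manifest."""
    from . import __version__

    out_dir = Path(out_dir)
    manifest_path = out_dir / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"runs": []}
    )
    manifest["runs"].append(
        {
            "command": command,
            "version": __version__,
            "params": params,
            "outputs": {
                str(Path(p).relative_to(out_dir)): file_checksum(p) for p in outputs
            },
        }
    )
    manifest_path.write_text(json.dumps(manifest, indent=1))
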