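"""File formats: multi-page TIFF pullbacks with JSON sidecars, CSV ground
truth and en-face maps, processed A-line matrices, model checkpoints, and
PNG renderings."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from PIL import Image

from . import nets as nets_mod
from .sim import GroundTruth, Pullback, LABEL_NAMES

__all__ = [
    "write_pullback",
    "read_pullback",
    "write_ground_truth",
    "read_ground_truth",
    "write_enface_csv",
    "read_enface_csv",
    "write_processed",
    "read_processed",
    "save_model",
    "load_model",
    "label_map_png",
    "saliency_overlay_png",
]

_REQUIRED_META = ("pullback_id", "axial_um_per_px", "frame_pitch_mm")

# Fig.-style palette: red, green, blue, black.
PALETTE = {0: (214, 39, 40), 1: (44, 160, 44), 2: (31, 119, 180), 3: (0, 0, 0)}


def write_pullback(pb: Pullback, tiff_path, json_path, extra_meta: dict | None = None) -> None:
    tiff_path, json_path = Path(tiff_path), Path(json_path)
    frames = np.asarray(pb.frames, dtype=np.uint16)
    tifffile.imwrite(tiff_path, frames, photometric="minisblack")
    meta = {
        "pullback_id": pb.pullback_id,
        "axial_um_per_px": pb.axial_um_per_px,
        "frame_pitch_mm": pb.frame_pitch_mm,
        "n_frames": int(frames.shape[0]),
        "depth_px": int(frames.shape[1]),
        "n_alines": int(frames.shape[2]),
    }
    if extra_meta:
        meta.update(extra_meta)
    json_path.write_text(json.dumps(meta, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"cannot serialize {type(o)}")


def read_pullback(tiff_path, json_path) -> Pullback:
    meta = json.loads(Path(json_path).read_text())
    for key in _REQUIRED_META:
        if key not in meta:
            raise ValueError(f"metadata missing required key {key!r}")
    frames = tifffile.imread(tiff_path)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3:
        raise ValueError("TIFF pages must share a single 2-D shape")
    return Pullback(
        frames=frames,
        pullback_id=meta["pullback_id"],
        axial_um_per_px=float(meta["axial_um_per_px"]),
        frame_pitch_mm=float(meta["frame_pitch_mm"]),
    )


def write_ground_truth(gt: GroundTruth, path) -> None:
    n_alines, n_frames = gt.labels.shape
    aline, frame = np.meshgrid(np.arange(n_alines), np.arange(n_frames), indexing="ij")
    df = pd.DataFrame(
        {
            "frame_index": frame.ravel(),
            "aline_index": aline.ravel(),
            "label": [LABEL_NAMES[v] for v in gt.labels.ravel()],
            "lumen_radius_px": gt.lumen.ravel(),
            "is_guidewire": gt.guidewire_mask.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path)
    n_alines = int(df["aline_index"].max()) + 1
    n_frames = int(df["frame_index"].max()) + 1
    labels = np.empty((n_alines, n_frames), dtype=np.int64)
    lumen = np.empty((n_alines, n_frames), dtype=np.int64)
    gw = np.zeros((n_alines, n_frames), dtype=bool)
    name_to_code = {name: i for i, name in enumerate(LABEL_NAMES)}
    a = df["aline_index"].to_numpy()
    f = df["frame_index"].to_numpy()
    labels[a, f] = df["label"].map(name_to_code).to_numpy()
    lumen[a, f] = df["lumen_radius_px"].to_numpy()
    gw[a, f] = df["is_guidewire"].to_numpy().astype(bool)
    return GroundTruth(labels=labels, lumen=lumen, guidewire_mask=gw)


def write_enface_csv(probs: np.ndarray, valid: np.ndarray, path) -> None:
    n_alines, n_frames = valid.shape
    aline, frame = np.meshgrid(np.arange(n_alines), np.arange(n_frames), indexing="ij")
    df = pd.DataFrame(
        {
            "aline": aline.ravel(),
            "frame": frame.ravel(),
            "p_fc": probs[..., 0].ravel(),
            "p_fl": probs[..., 1].ravel(),
            "p_other": probs[..., 2].ravel(),
            "valid": valid.ravel().astype(int),
        }
    )
    df.to_csv(path, index=False)


def read_enface_csv(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    n_alines = int(df["aline"].max()) + 1
    n_frames = int(df["frame"].max()) + 1
    probs = np.zeros((n_alines, n_frames, 3))
    valid = np.zeros((n_alines, n_frames), dtype=bool)
    a = df["aline"].to_numpy()
    f = df["frame"].to_numpy()
    probs[a, f, 0] = df["p_fc"].to_numpy()
    probs[a, f, 1] = df["p_fl"].to_numpy()
    probs[a, f, 2] = df["p_other"].to_numpy()
    valid[a, f] = df["valid"].to_numpy().astype(bool)
    return probs, valid


def write_processed(X: np.ndarray, index: pd.DataFrame, matrix_path, index_path) -> None:
    """Flat float32 matrix + CSV index (pullback_id, frame, aline, label)."""
    np.asarray(X, dtype=np.float32).tofile(matrix_path)
    index.to_csv(index_path, index=False)


def read_processed(matrix_path, index_path, n_features: int = 200):
    index = pd.read_csv(index_path)
    X = np.fromfile(matrix_path, dtype=np.float32).reshape(len(index), n_features)
    return X, index


def save_model(trained: nets_mod.TrainedModel, path) -> None:
    """Single-file archive: JSON header + raw parameter blobs (npz)."""
    header = {
        "config": nets_mod.config_to_dict(trained.config),
        "history": trained.history,
        "best_epoch": trained.best_epoch,
        "has_featurewise_stats": bool(trained.stand_stats),
    }
    arrays = {"__header__": np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)}
    for i, layer in enumerate(trained.model.layers):
        for k, v in layer.params.items():
            arrays[f"layer{i}__{k}"] = v
    if trained.stand_stats:
        arrays["stand_mean"] = trained.stand_stats["mean"]
        arrays["stand_std"] = trained.stand_stats["std"]
    np.savez(path, **arrays)


def load_model(path) -> nets_mod.TrainedModel:
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        cfg = nets_mod.NetConfig(**header["config"])
        model = nets_mod.build_model(cfg)
        for i, layer in enumerate(model.layers):
            for k in layer.params:
                layer.params[k] = data[f"layer{i}__{k}"]
        stats = {}
        if header.get("has_featurewise_stats"):
            stats = {"mean": data["stand_mean"], "std": data["stand_std"]}
    return nets_mod.TrainedModel(
        model=model,
        config=cfg,
        stand_stats=stats,
        history=header["history"],
        best_epoch=header["best_epoch"],
    )


def label_map_png(labels: np.ndarray, path) -> None:
    """Indexed-colour en-face label rendering (red/green/blue/black)."""
    rgb = np.zeros(labels.shape + (3,), dtype=np.uint8)
    for code, colour in PALETTE.items():
        rgb[labels == code] = colour
    Image.fromarray(rgb).save(path)


def saliency_overlay_png(frame: np.ndarray, sal: np.ndarray, path) -> None:
    """Saliency in red over the grayscale processed frame."""
    f = np.asarray(frame, dtype=float)
    f = (f - f.min()) / (np.ptp(f) or 1.0)
    s = np.asarray(sal, dtype=float)
    s = s / (s.max() or 1.0)
    rgb = np.stack([f, f, f], axis=-1)
    rgb[..., 0] = np.clip(rgb[..., 0] + s, 0, 1)
    Image.fromarray((rgb * 255).astype(np.uint8)).save(path)
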