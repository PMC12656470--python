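"""Readers and writers: images, feature maps, match tables, result bundles.

All text outputs are UTF-8 with LF line endings and 6-decimal floats; match
tables round-trip exactly at that precision.  Coordinates are written in both
the visible frame and the native infrared frame.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .filters import FeatureMap
from .matching import Match, RegistrationResult, Transform

logger = logging.getLogger("gocao")

__all__ = [
    "load_image",
    "save_feature_map",
    "write_matches_tsv",
    "read_matches_tsv",
    "write_result",
    "write_truth_tsv",
    "read_truth_tsv",
]

_MATCH_COLUMNS = ["ir_x", "ir_y", "vis_x", "vis_y", "distance", "stage", "inlier"]


def load_image(path: str | Path) -> np.ndarray:
    """Read PNG/TIFF/JPEG as single-channel float in [0, 1].

    Multi-channel images are converted by luminance average; 16-bit inputs
    are scaled by their dtype range.
    """
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., :3].mean(axis=2)
    if arr.dtype == np.uint8:
        arr = arr / 255.0
    elif arr.dtype == np.uint16:
        arr = arr / 65535.0
    else:
        arr = arr.astype(float)
        if arr.max() > 1.0:
            arr = arr / arr.max()
    return arr.astype(float)


def save_feature_map(fmap: FeatureMap, path: str | Path) -> None:
    """Export a feature map as 32-bit float TIFF for inspection."""
    import tifffile

    tifffile.imwrite(Path(path), fmap.values.astype(np.float32))


def _matches_frame(matches: list[Match], resolution_ratio: float = 1.0) -> pd.DataFrame:
    rows = []
    for m in matches:
        rows.append(
            {
                "ir_x": m.ir_point[0] / resolution_ratio,
                "ir_y": m.ir_point[1] / resolution_ratio,
                "vis_x": m.vis_point[0],
                "vis_y": m.vis_point[1],
                "distance": m.distance,
                "stage": m.stage,
                "inlier": int(m.inlier),
            }
        )
    return pd.DataFrame(rows, columns=_MATCH_COLUMNS)


def write_matches_tsv(matches: list[Match], path: str | Path, resolution_ratio: float = 1.0) -> None:
    """Write matches as TSV; IR coordinates are stored in the native IR frame."""
    frame = _matches_frame(matches, resolution_ratio)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def read_matches_tsv(path: str | Path) -> list[Match]:
    frame = pd.read_csv(path, sep="\t")
    missing = [c for c in _MATCH_COLUMNS if c not in frame.columns]
    if missing:
        raise ParameterError(f"matches table missing columns {missing}")
    return [
        Match(
            ir_point=(float(r.ir_x), float(r.ir_y)),
            vis_point=(float(r.vis_x), float(r.vis_y)),
            distance=float(r.distance),
            stage=str(r.stage),
            inlier=bool(r.inlier),
        )
        for r in frame.itertuples()
    ]


def write_truth_tsv(control_points: np.ndarray, path: str | Path) -> None:
    """Ground-truth control points as TSV (ir_x, ir_y, vis_x, vis_y)."""
    frame = pd.DataFrame(
        np.asarray(control_points, dtype=float).reshape(-1, 4),
        columns=["ir_x", "ir_y", "vis_x", "vis_y"],
    )
    frame.to_csv(path, sep="\t", index=False, float_format="%.6f", lineterminator="\n")


def read_truth_tsv(path: str | Path) -> np.ndarray:
    frame = pd.read_csv(path, sep="\t")
    need = ["ir_x", "ir_y", "vis_x", "vis_y"]
    missing = [c for c in need if c not in frame.columns]
    if missing:
        raise ParameterError(f"truth table missing columns {missing}")
    return frame[need].to_numpy(dtype=float)


def _overlay_png(
    result: RegistrationResult, visible: np.ndarray, infrared: np.ndarray, path: Path
) -> None:
    """Match-line overlay: green inlier lines, purple rejected bilateral ones."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    h, w = visible.shape
    ih, iw = infrared.shape
    scale = h / ih
    fig, ax = plt.subplots(figsize=(2 * w / 100.0, h / 100.0), dpi=100)
    canvas = np.concatenate([visible, np.kron(infrared, np.ones((int(scale), int(scale))))[:h, :w]], axis=1)
    ax.imshow(canvas, cmap="gray")
    rough_ids = {(m.ir_index, m.vis_index) for m in result.matches if m.stage == "rough"}
    for m in result.matches:
        if m.stage != "bilateral":
            continue
        good = (m.ir_index, m.vis_index) in rough_ids
        color = "lime" if good else "magenta"
        ax.plot(
            [m.vis_point[0], w + m.ir_point[0]],
            [m.vis_point[1], m.ir_point[1]],
            color=color,
            lw=0.8,
            alpha=0.9,
        )
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)


def write_result(
    result: RegistrationResult,
    out_dir: str | Path,
    visible: np.ndarray | None = None,
    infrared: np.ndarray | None = None,
    report: dict | None = None,
) -> dict:
    """Write transform.json, matches.tsv, optional report.json and overlay.png.

    Returns the mapping of artifact name to path.  report.json is omitted
    (and noted in the log) when no ground truth was supplied.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}

    tf = {
        "transform_upsampled": result.transform.as_dict(),
        "transform_native_ir": result.composite_transform.as_dict(),
        "resolution_ratio": result.resolution_ratio,
        "refined": result.refined,
        "log": result.log,
    }
    p = out_dir / "transform.json"
    p.write_text(json.dumps(tf, indent=2) + "\n")
    paths["transform"] = p

    p = out_dir / "matches.tsv"
    write_matches_tsv(result.matches, p, result.resolution_ratio)
    paths["matches"] = p

    if report is not None:
        p = out_dir / "report.json"
        p.write_text(json.dumps(report, indent=2) + "\n")
        paths["report"] = p
    else:
        logger.info("no ground truth supplied; report.json omitted")

    if visible is not None and infrared is not None:
        p = out_dir / "overlay.png"
        _overlay_png(result, visible, infrared, p)
        paths["overlay"] = p

    for stage in ("contours", "keypoints", "descriptors", "bilateral", "rough", "fine"):
        for key, val in result.log.items():
            if stage in key:
                logger.info("%s: %s", key, val)
    return paths
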