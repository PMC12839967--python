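"""TIFF / CSV input-output and projection preprocessing.

Images travel as plain TIFF plus a JSON sidecar (``<file>.json``) holding
the physical pixel spacing in µm (axis order z,y,x), because TIFF itself
carries no reliable spacing for these data. Tracks and cell tables are
plain CSV with the column layout documented in the functions below.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import ImageStack, Track, VesselMask

__all__ = [
    "save_stack",
    "load_stack",
    "save_mask",
    "load_mask",
    "max_project",
    "read_tracks",
    "write_tracks",
]

logger = logging.getLogger(__name__)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_stack(path, stack: ImageStack) -> None:
    """Write an :class:`ImageStack` as TIFF with a JSON spacing sidecar."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(stack.data), photometric="minisblack")
    meta = {
        "spacing_um": list(stack.spacing),
        "axes": "zyx" if stack.ndim == 3 else "yx",
        "channel": stack.channel,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_stack(path, spacing=None, channel: str | None = None) -> ImageStack:
    """Load a TIFF image stack.

    ``spacing`` (µm per axis) overrides the sidecar when given; without
    either source of pixel size the call fails — downstream distances are
    meaningless without it.
    """
    path = Path(path)
    data = tifffile.imread(path)
    sidecar = _sidecar_path(path)
    meta = {}
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if spacing is None:
        if "spacing_um" not in meta:
            raise ValueError(
                f"no pixel size for {path}: supply spacing= or provide sidecar {sidecar.name}"
            )
        spacing = meta["spacing_um"]
    if channel is None:
        channel = meta.get("channel", "")
    return ImageStack(data=data, spacing=spacing, channel=channel)


def save_mask(path, mask: VesselMask) -> None:
    path = Path(path)
    tifffile.imwrite(path, mask.data.astype(np.uint8))
    meta = {"spacing_um": list(mask.spacing), "axes": "zyx" if mask.data.ndim == 3 else "yx"}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def load_mask(path, spacing=None) -> VesselMask:
    path = Path(path)
    data = tifffile.imread(path)
    if spacing is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(f"no pixel size for {path}: supply spacing= or a sidecar")
        spacing = json.loads(sidecar.read_text())["spacing_um"]
    return VesselMask(data=data > 0, spacing=spacing)


def max_project(stack: ImageStack, z_range: slice | None = None) -> ImageStack:
    """Maximum-intensity projection of a 3-D stack along z.

    Mirrors the acquisition preprocessing for whole-mount gradient images:
    20–40 plane stacks at 1 µm z-step are collapsed to one 2-D image before
    distance profiling. ``z_range`` selects a sub-range of planes.
    """
    if stack.ndim != 3:
        raise ValueError("max_project expects a 3-D stack; pass 2-D images straight through")
    z_range = z_range if z_range is not None else slice(None)
    planes = stack.data[z_range]
    if planes.ndim != 3 or planes.shape[0] < 1:
        raise ValueError("z_range selects no plane")
    return ImageStack(
        data=planes.max(axis=0), spacing=stack.spacing[1:], channel=stack.channel
    )


_TRACK_COLS = ["track_id", "t_s", "x_um", "y_um"]


def write_tracks(path, tracks) -> None:
    rows = []
    for tr in tracks:
        for k in range(tr.n_points):
            row = {
                "track_id": tr.track_id,
                "t_s": tr.t[k],
                "x_um": tr.positions[k, 0],
                "y_um": tr.positions[k, 1],
            }
            if tr.is_3d:
                row["z_um"] = tr.positions[k, 2]
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_tracks(path, dt_expected: float | None = None, assay: str = "") -> list[Track]:
    """Read a track CSV (columns track_id,t_s,x_um,y_um[,z_um]) into Tracks.

    Rows are grouped by id and sorted by time, so the row order of the file
    does not matter. Tracks with a single point cannot yield any metric and
    are dropped with a warning. When ``dt_expected`` is given, a >1%
    deviation of the observed median frame interval triggers a warning —
    a common symptom of unit mix-ups (s vs min) in exported tables.
    """
    df = pd.read_csv(path)
    missing = [c for c in _TRACK_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"track table missing columns: {missing}")
    has_z = "z_um" in df.columns
    if df.duplicated(subset=["track_id", "t_s"]).any():
        dupes = df[df.duplicated(subset=["track_id", "t_s"])]["track_id"].unique()
        raise ValueError(f"duplicate (track_id, t) rows for tracks: {list(dupes)}")

    tracks: list[Track] = []
    n_dropped = 0
    for tid, g in df.groupby("track_id", sort=True):
        g = g.sort_values("t_s")
        if len(g) < 2:
            n_dropped += 1
            continue
        cols = ["x_um", "y_um"] + (["z_um"] if has_z else [])
        tracks.append(
            Track(
                track_id=str(tid),
                t=g["t_s"].to_numpy(),
                positions=g[cols].to_numpy(),
                assay=assay,
            )
        )
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} track(s) with <2 points", stacklevel=2)
        logger.info("read_tracks: dropped %d single-point track(s)", n_dropped)
    if dt_expected is not None and tracks:
        dts = np.concatenate([np.diff(tr.t) for tr in tracks])
        med = float(np.median(dts))
        if abs(med - dt_expected) > 0.01 * dt_expected:
            warnings.warn(
                f"observed median frame interval {med:g}s deviates >1% from expected "
                f"{dt_expected:g}s",
                stacklevel=2,
            )
    return tracks
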