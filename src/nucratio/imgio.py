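"""Image-stack, ROI-table, measurement-table and config I/O.

Conventions used throughout the package:

* coordinates are 0-based ``(y, x)`` row/column order with pixel centers at
  integer positions (plain array indexing; note this differs from FIJI's
  0.5-px-offset convention);
* label images use 0 for background and positive integers for nucleus ids;
* stacks are 5-D ``(T, C, Z, Y, X)`` arrays; multi-page TIFFs are written
  with pages ordered T, then C, then Z.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

#: fixed measurement-CSV column order
MEASUREMENT_COLUMNS = [
    "root_id", "t_min", "nucleus_id", "tissue", "phase", "area_px",
    "raw_target", "raw_standard", "bg_target", "bg_standard",
    "int_target", "int_standard", "ratio", "qc_flags",
]
_MEASUREMENT_KEY = ["root_id", "t_min", "nucleus_id"]


@dataclass
class ImageStack:
    """A 5-D (T, C, Z, Y, X) voxel array with acquisition metadata."""

    voxels: np.ndarray
    channel_roles: dict[int, str] = field(default_factory=dict)
    pixel_size_xy: float = 0.2   # µm
    z_step: float = 0.5          # µm
    time_interval: float = 0.0   # min

    def __post_init__(self) -> None:
        if self.voxels.ndim != 5:
            raise ValueError("voxels must be 5-D (T, C, Z, Y, X)")
        if min(self.voxels.shape) < 1:
            raise ValueError("all stack dimensions must be >= 1")
        roles = list(self.channel_roles.values())
        for role in roles:
            if roles.count(role) > 1:
                raise ValueError(f"more than one channel with role {role!r}")

    @property
    def n_t(self) -> int:
        return self.voxels.shape[0]

    def channel_index(self, role: str) -> int:
        for idx, r in self.channel_roles.items():
            if r == role:
                return idx
        raise KeyError(f"no channel with role {role!r}")


def write_stack(stack: ImageStack, path: str | Path) -> None:
    """Write a stack as a multi-page TIFF, pages in T->C->Z order."""
    t, c, z, h, w = stack.voxels.shape
    desc = json.dumps({
        "axes": "TCZYX", "shape": [t, c, z, h, w],
        "channel_roles": {str(k): v for k, v in stack.channel_roles.items()},
        "pixel_size_xy_um": stack.pixel_size_xy,
        "z_step_um": stack.z_step,
        "time_interval_min": stack.time_interval,
    })
    tifffile.imwrite(str(path), stack.voxels.reshape(t * c * z, h, w),
                     photometric="minisblack", description=desc)


def read_stack(
    path: str | Path,
    channel_role_map: dict[int, str] | None = None,
    n_c: int | None = None,
    n_z: int | None = None,
) -> ImageStack:
    """Read a multi-page TIFF into a (T, C, Z, Y, X) stack.

    Dimensions come from the JSON description written by
    :func:`write_stack` when present; otherwise ``n_c`` and ``n_z`` must
    be supplied and T is inferred from the page count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.asarray()
        raw_desc = tif.pages[0].description or ""
    if pages.ndim == 2:
        pages = pages[np.newaxis]
    if pages.dtype not in (np.uint8, np.uint16):
        raise ValueError(f"unsupported bit depth: {pages.dtype}")
    meta: dict = {}
    if raw_desc:
        try:
            meta = json.loads(raw_desc)
        except (json.JSONDecodeError, TypeError):
            meta = {}
    if meta.get("axes") == "TCZYX":
        t, c, z, h, w = meta["shape"]
    else:
        if n_c is None or n_z is None:
            raise ValueError(
                "page layout is ambiguous: supply n_c and n_z "
                "(channel and Z-plane counts) to interpret this file")
        c, z = n_c, n_z
        n_pages = pages.shape[0]
        if n_pages % (c * z) != 0:
            raise ValueError(
                f"{n_pages} pages are not divisible by C*Z = {c * z}")
        t = n_pages // (c * z)
        h, w = pages.shape[1:]
    roles = channel_role_map
    if roles is None:
        roles = {int(k): v
                 for k, v in meta.get("channel_roles", {}).items()}
    return ImageStack(
        voxels=pages.reshape(t, c, z, h, w),
        channel_roles=roles or {},
        pixel_size_xy=float(meta.get("pixel_size_xy_um", 0.2)),
        z_step=float(meta.get("z_step_um", 0.5)),
        time_interval=float(meta.get("time_interval_min", 0.0)),
    )


def write_label_mask(labels: np.ndarray, path: str | Path) -> None:
    """Write a label image as a 16-bit TIFF (0 = background)."""
    if labels.max() > 65535:
        raise ValueError("more than 65535 labels")
    tifffile.imwrite(str(path), labels.astype(np.uint16))


def read_label_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


# ---------------------------------------------------------------------------
# measurement tables
# ---------------------------------------------------------------------------

def write_measurements(table: pd.DataFrame, path: str | Path) -> None:
    """Write a measurement table with the fixed schema.

    Columns are reordered to :data:`MEASUREMENT_COLUMNS`; floats are
    written with 6 significant digits.  Duplicate
    (root_id, t_min, nucleus_id) keys are rejected.
    """
    df = table.copy()
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan if col != "qc_flags" else ""
    df = df[MEASUREMENT_COLUMNS]
    if len(df):
        dup = df.duplicated(subset=_MEASUREMENT_KEY, keep=False)
        if dup.any():
            key = tuple(
                v.item() if hasattr(v, "item") else v
                for v in df.loc[dup.idxmax(), _MEASUREMENT_KEY])
            raise ValueError(f"duplicate measurement key {key}")
    df.to_csv(path, index=False, float_format="%.6g")


def read_measurements(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"qc_flags": str},
                     keep_default_na=True)
    df["qc_flags"] = df["qc_flags"].fillna("")
    return df


# ---------------------------------------------------------------------------
# ROI tables
# ---------------------------------------------------------------------------

def format_polygon(vertices: np.ndarray) -> str:
    """Serialize an (n, 2) array of (y, x) vertices as 'y1 x1;y2 x2;...'."""
    return ";".join(f"{y:g} {x:g}" for y, x in np.asarray(vertices))


def parse_polygon(text: str) -> np.ndarray:
    verts = np.array([[float(v) for v in pair.split()]
                      for pair in text.split(";") if pair.strip()])
    if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
        raise ValueError("polygon needs >= 3 (y, x) vertices")
    return verts


ROI_COLUMNS = ["t_min", "nucleus_id", "polygon", "tissue", "phase", "root_id"]


def write_rois(rois: pd.DataFrame, path: str | Path) -> None:
    df = rois.copy()
    for col in ROI_COLUMNS:
        if col not in df.columns:
            df[col] = ""
    df[ROI_COLUMNS].to_csv(path, index=False)


def read_rois(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df[["t_min", "nucleus_id"]].duplicated().any():
        raise ValueError("ROI ids must be unique per frame")
    for poly in df["polygon"]:
        parse_polygon(poly)  # validates on read
    return df


# ---------------------------------------------------------------------------
# scene-truth tables and config
# ---------------------------------------------------------------------------

TRUTH_COLUMNS = ["id", "t_min", "y_px", "x_px", "radius_px", "tissue",
                 "phase", "s_tot", "true_ratio"]


def write_scene_truth(scenes, base_params, path: str | Path) -> pd.DataFrame:
    """Serialize ground truth (one row per nucleus per timepoint) to CSV."""
    rows = []
    for scene in scenes:
        for n in scene.nuclei:
            rows.append({
                "id": n.id, "t_min": scene.t_min, "y_px": n.y, "x_px": n.x,
                "radius_px": n.radius_px, "tissue": n.tissue,
                "phase": n.phase, "s_tot": n.s_tot,
                "true_ratio": scene.true_ratio(base_params, n),
            })
    df = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    df.to_csv(path, index=False, float_format="%.8g")
    return df


def read_scene_truth(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def save_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
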