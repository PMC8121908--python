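"""Per-nucleus intensity integration, ratios, and normalization schemes.

The core measurement is the background-corrected integrated intensity of
each channel over a nuclear mask, and their ratio

    r = int_target / int_standard

which reports the nuclear enrichment of the probe relative to the
chromatin-bound standard and hence the modification level of the cell.

Three normalizations mirror the downstream analyses:

* per-root scaling by the reference-tissue (epidermis) median, roots
  normalized independently before pooling;
* control-line correction: dividing each tissue's values by the same
  tissue's median in a non-binding control line;
* mitotic-to-interphase (M/I) relative ratio against the mean of nearby
  interphase neighbours, tracked across frames by nearest centroid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .detectseg import (FilterBankConfig, LabelMask, QCRules, detect_nuclei,
                        estimate_background, qc_filter, segment_nuclei,
                        sum_project)
from .imgio import MEASUREMENT_COLUMNS, ImageStack


def integrate_intensity(
    projection: np.ndarray, mask: LabelMask, label: int, background: float
) -> float:
    """Background-corrected integrated intensity over one label.

    Sum of projected counts in the label minus area times the background
    level.  The result is *not* floored at zero; callers flag negative
    values instead of hiding them.
    """
    region = mask.labels == label
    area = int(region.sum())
    if area == 0:
        raise KeyError(f"label {label} not present in mask")
    return float(np.asarray(projection, dtype=np.float64)[region].sum()
                 - area * background)


def compute_ratio(int_target: float, int_standard: float) -> float | None:
    """Target/standard ratio; ``None`` when the standard is non-positive."""
    if int_standard <= 0:
        return None
    return int_target / int_standard


def measure_frame(
    stack: ImageStack,
    mask: LabelMask,
    t: int = 0,
    t_min: float = 0.0,
    root_id: int | str = 0,
    labels_meta: pd.DataFrame | None = None,
    qc_flags: dict[int, list[str]] | None = None,
    bg_dilation_px: int = 15,
) -> pd.DataFrame:
    """Measure every label of one frame into measurement-table rows.

    ``labels_meta`` (optional) maps label id to tissue/phase annotations;
    ``qc_flags`` carries flags from :func:`~nucratio.detectseg.qc_filter`.
    Background is estimated per channel as the median outside the dilated
    mask union.
    """
    proj = {role: sum_project(stack, t, stack.channel_index(role))
            for role in ("target", "standard")}
    bg = {role: estimate_background(proj[role], mask, bg_dilation_px)
          for role in proj}
    meta: dict[int, dict] = {}
    if labels_meta is not None:
        meta = {int(r["nucleus_id"]): dict(r)
                for _, r in labels_meta.iterrows()}
    rows = []
    for lab in mask.ids:
        flags = list(qc_flags.get(lab, [])) if qc_flags else []
        region = mask.labels == lab
        area = int(region.sum())
        raw_t = float(np.asarray(proj["target"], float)[region].sum())
        raw_s = float(np.asarray(proj["standard"], float)[region].sum())
        int_t = raw_t - area * bg["target"]
        int_s = raw_s - area * bg["standard"]
        if int_t < 0 or int_s < 0:
            flags.append("negative_intensity")
        ratio = compute_ratio(int_t, int_s)
        if ratio is None:
            flags.append("standard_nonpositive")
        m = meta.get(lab, {})
        rows.append({
            "root_id": root_id, "t_min": t_min, "nucleus_id": lab,
            "tissue": m.get("tissue", "none"),
            "phase": m.get("phase", "interphase"),
            "area_px": area, "raw_target": raw_t, "raw_standard": raw_s,
            "bg_target": bg["target"], "bg_standard": bg["standard"],
            "int_target": int_t, "int_standard": int_s,
            "ratio": np.nan if ratio is None else ratio,
            "qc_flags": ";".join(flags),
        })
    return pd.DataFrame(rows, columns=MEASUREMENT_COLUMNS)


def measure_stack_auto(
    stack: ImageStack,
    t: int = 0,
    t_min: float = 0.0,
    root_id: int | str = 0,
    bank: FilterBankConfig = FilterBankConfig(),
    qc_rules: QCRules | None = None,
    labels_meta: pd.DataFrame | None = None,
    labels_meta_fn=None,
    seg_smoothing_sigma: float = 0.5,
) -> tuple[pd.DataFrame, LabelMask]:
    """Detect, segment, QC and measure one frame automatically.

    Detection and segmentation run on the standard channel; measurement
    covers both channels.  Returns the measurement rows and the label
    mask (labels indexed by detection order).  ``labels_meta_fn``, if
    given, is called with the computed mask and must return a labels-meta
    frame (used to annotate labels from ground truth or an ROI table).
    """
    std = sum_project(stack, t, stack.channel_index("standard"))
    detections = detect_nuclei(std, bank)
    mask = segment_nuclei(std, detections,
                          smoothing_sigma=seg_smoothing_sigma)
    if qc_rules is None:
        n_z = stack.voxels.shape[2]
        qc_rules = QCRules(saturation_level=n_z * 65535)
    tgt = sum_project(stack, t, stack.channel_index("target"))
    flags = qc_filter(mask, {"target": tgt, "standard": std}, qc_rules)
    if labels_meta_fn is not None:
        labels_meta = labels_meta_fn(mask)
    table = measure_frame(stack, mask, t=t, t_min=t_min, root_id=root_id,
                          labels_meta=labels_meta, qc_flags=flags)
    return table, mask


def qc_clean(table: pd.DataFrame) -> pd.DataFrame:
    """Rows with no QC flags and a finite ratio."""
    flags = table["qc_flags"].fillna("")
    return table[(flags == "") & np.isfinite(table["ratio"])]


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def normalize_by_reference_tissue(
    table: pd.DataFrame, reference: str = "epidermis"
) -> pd.DataFrame:
    """Divide each root's ratios by that root's reference-tissue median.

    Each root is normalized on its own scale before roots are pooled, so
    the reference tissue has median exactly 1 within every root.  A root
    without any clean reference-tissue record is an error.
    """
    clean = qc_clean(table)
    out = table.copy()
    out["norm_ratio"] = np.nan
    for root, sub in clean.groupby("root_id"):
        ref = sub.loc[sub["tissue"] == reference, "ratio"]
        if ref.empty:
            raise ValueError(
                f"root {root!r} has no clean {reference!r} record")
        med = float(ref.median())
        idx = out.index[out["root_id"] == root]
        out.loc[idx, "norm_ratio"] = out.loc[idx, "ratio"] / med
    return out


def control_correct(
    target_table: pd.DataFrame, control_table: pd.DataFrame
) -> pd.DataFrame:
    """Divide normalized ratios by the control line's per-tissue median.

    Both tables must already carry ``norm_ratio`` (reference-tissue
    normalized).  Applying a table to itself yields per-tissue median 1.
    """
    for df, name in ((target_table, "target"), (control_table, "control")):
        if "norm_ratio" not in df.columns:
            raise ValueError(f"{name} table lacks norm_ratio: normalize "
                             "by reference tissue first")
    out = target_table.copy()
    if out.empty:
        out["corrected_ratio"] = pd.Series(dtype=float)
        return out
    ctrl = qc_clean(control_table)
    med = ctrl.groupby("tissue")["norm_ratio"].median()
    missing = set(out["tissue"].unique()) - set(med.index)
    if missing:
        raise ValueError(
            f"tissues missing from control table: {sorted(missing)}")
    out["corrected_ratio"] = out["norm_ratio"] / out["tissue"].map(med)
    return out


def per_root_average(
    table: pd.DataFrame, by: tuple[str, ...] = ("root_id", "t_min")
) -> pd.DataFrame:
    """Mean clean ratio per root per timepoint (one row per group)."""
    clean = qc_clean(table)
    out = (clean.groupby(list(by))["ratio"].agg(["mean", "count"])
           .reset_index()
           .rename(columns={"mean": "mean_ratio", "count": "n_nuclei"}))
    return out


# ---------------------------------------------------------------------------
# tracking and M/I relative ratio
# ---------------------------------------------------------------------------

def track_nearest_centroid(
    prev: pd.DataFrame, curr: pd.DataFrame, max_displacement: float = 15.0
) -> dict[int, int]:
    """Link objects across frames by nearest centroid.

    ``prev``/``curr`` need columns (nucleus_id, y, x).  Returns a mapping
    previous id -> current id; objects with no candidate within
    ``max_displacement`` px are dropped from the mapping.  Greedy on
    ascending distance, one-to-one.
    """
    pairs = []
    for _, p in prev.iterrows():
        for _, c in curr.iterrows():
            d = math.hypot(p["y"] - c["y"], p["x"] - c["x"])
            if d <= max_displacement:
                pairs.append((d, int(p["nucleus_id"]), int(c["nucleus_id"])))
    pairs.sort()
    used_prev: set[int] = set()
    used_curr: set[int] = set()
    link = {}
    for _, pid, cid in pairs:
        if pid in used_prev or cid in used_curr:
            continue
        link[pid] = cid
        used_prev.add(pid)
        used_curr.add(cid)
    return link


def mphase_relative_ratio(
    m_records: pd.DataFrame,
    interphase_records: pd.DataFrame,
    neighbor_radius: float = 60.0,
    max_displacement: float = 15.0,
) -> pd.DataFrame:
    """Mitotic object's ratio relative to nearby interphase neighbours.

    ``m_records`` holds one row per timepoint for the mitotic object
    (columns t_min, ratio, y, x; telophase daughters may contribute
    several rows per timepoint, in which case their clean ratios are
    averaged).  The interphase neighbour set is fixed at the first
    timepoint (all interphase objects within ``neighbor_radius`` of the
    mitotic centroid) and tracked across frames by nearest centroid.

    Returns a frame with columns (t_min, m_ratio, interphase_mean,
    m_over_i, n_neighbors).  A timepoint with no tracked neighbour is an
    error.
    """
    times = sorted(m_records["t_min"].unique())
    if not times:
        raise ValueError("no mitotic records")
    t0 = times[0]
    m0 = m_records[m_records["t_min"] == t0].iloc[0]
    i0 = interphase_records[interphase_records["t_min"] == t0]
    d0 = np.hypot(i0["y"] - m0["y"], i0["x"] - m0["x"])
    neighbors = i0.loc[d0 <= neighbor_radius]
    if neighbors.empty:
        raise ValueError(
            f"no interphase neighbour within {neighbor_radius} px at t={t0}")
    tracked = {int(i): int(i) for i in neighbors["nucleus_id"]}

    rows = []
    prev_t = t0
    for t in times:
        it = interphase_records[interphase_records["t_min"] == t]
        if t != prev_t:
            prev = interphase_records[
                (interphase_records["t_min"] == prev_t)
                & interphase_records["nucleus_id"].isin(tracked.values())]
            link = track_nearest_centroid(prev, it, max_displacement)
            tracked = {orig: link[cur]
                       for orig, cur in tracked.items() if cur in link}
            prev_t = t
        cur_ids = set(tracked.values())
        neigh = it[it["nucleus_id"].isin(cur_ids)]
        neigh = neigh[np.isfinite(neigh["ratio"])]
        if neigh.empty:
            raise ValueError(f"no interphase neighbour at t={t}")
        mt = m_records[m_records["t_min"] == t]
        m_ratio = float(mt["ratio"][np.isfinite(mt["ratio"])].mean())
        i_mean = float(neigh["ratio"].mean())
        rows.append({"t_min": t, "m_ratio": m_ratio,
                     "interphase_mean": i_mean,
                     "m_over_i": m_ratio / i_mean,
                     "n_neighbors": len(neigh)})
        prev_t = t
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# time-course model fit
# ---------------------------------------------------------------------------

def fit_exponential_decay(
    t: np.ndarray, y: np.ndarray
) -> dict[str, float]:
    """Fit ``y(t) = c + a * exp(-t / tau)`` by least squares.

    Used to recover the treatment-decay time constant from per-root mean
    ratio time courses.  Returns ``tau``, ``half_time`` (= tau * ln 2),
    the amplitude ``a`` and the plateau ``c``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 3:
        raise ValueError("need at least 3 timepoints to fit a decay")
    span = max(t.max() - t.min(), 1e-9)
    a0 = y[np.argmin(t)] - y[np.argmax(t)]
    p0 = (y[np.argmax(t)], a0 if abs(a0) > 1e-12 else 1e-3, span / 3.0)
    popt, _ = curve_fit(
        lambda tt, c, a, tau: c + a * np.exp(-tt / tau),
        t, y, p0=p0,
        bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, 1e6]),
        maxfev=20000)
    c, a, tau = popt
    return {"tau": float(tau), "half_time": float(tau * math.log(2)),
            "amplitude": float(a), "plateau": float(c)}
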