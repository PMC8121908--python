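"""Intensity integration, ratios, normalizations and M/I relative ratio."""

import math

import numpy as np
import pandas as pd
import pytest

from nucratio.detectseg import LabelMask
from nucratio.imgio import MEASUREMENT_COLUMNS
from nucratio.ratiometry import (compute_ratio, control_correct,
                                 fit_exponential_decay, integrate_intensity,
                                 measure_stack_auto, mphase_relative_ratio,
                                 normalize_by_reference_tissue,
                                 per_root_average, qc_clean,
                                 track_nearest_centroid)
from nucratio.synthgen import NoiseModel, render_scene
from tests.conftest import BASE_PARAMS


def _mask_with_square(shape=(16, 16), label=1, y0=3, size=3):
    labels = np.zeros(shape, dtype=int)
    labels[y0:y0 + size, y0:y0 + size] = label
    return LabelMask(labels)


def _table(rows):
    df = pd.DataFrame(rows)
    for col in MEASUREMENT_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col == "qc_flags" else np.nan
    return df


def _rec(root, tissue, ratio, nid, t=0.0, flags="", phase="interphase"):
    return {"root_id": root, "t_min": t, "nucleus_id": nid,
            "tissue": tissue, "phase": phase, "ratio": ratio,
            "qc_flags": flags}


# ---------------------------------------------------------------------------
# integration and ratio
# ---------------------------------------------------------------------------

def test_integrate_constant_region():
    img = np.full((16, 16), 5.0)
    mask = _mask_with_square()  # 9 px... area from mask
    area = (mask.labels == 1).sum()
    assert integrate_intensity(img, mask, 1, background=0.0) == 5.0 * area
    assert integrate_intensity(img, mask, 1, background=5.0) == 0.0


def test_integrate_missing_label_errors():
    with pytest.raises(KeyError):
        integrate_intensity(np.zeros((8, 8)), _mask_with_square(), 9, 0.0)


def test_integration_tracks_poisson_truth(single_nucleus_scene):
    """Estimated photon sum within 4*sqrt(P) of truth in >=99% of renders.

    Pure shot noise (no PSF, no read noise, no offset) so the standard
    channel's integral over the true footprint is a Poisson(P) draw.
    """
    from nucratio.synthgen import truth_label_mask
    from nucratio.detectseg import sum_project
    scene = single_nucleus_scene(radius=6.0, s_tot=0.0, shape=(48, 48),
                                 budget=1e4)
    noise = NoiseModel(psf_sigma_xy=0.0, psf_sigma_z=0.0,
                       read_noise_sigma=0.0, camera_offset=0.0)
    mask = LabelMask(truth_label_mask(scene))
    hits = 0
    for seed in range(100):
        stack = render_scene(scene, BASE_PARAMS, noise, n_z=2, seed=seed)
        est = integrate_intensity(sum_project(stack, 0, 1), mask, 1, 0.0)
        if abs(est - 1e4) <= 4 * math.sqrt(1e4):
            hits += 1
    assert hits >= 99


def test_compute_ratio_cases():
    assert compute_ratio(100.0, 100.0) == 1.0
    assert compute_ratio(0.0, 50.0) == 0.0
    assert compute_ratio(10.0, 0.0) is None
    assert compute_ratio(10.0, -2.0) is None


def test_ratio_invariances():
    """Ratio invariant to common scaling; linear in target-only scaling."""
    img_t = np.random.default_rng(0).uniform(10, 50, (16, 16))
    img_s = np.random.default_rng(1).uniform(10, 50, (16, 16))
    mask = _mask_with_square()
    it = integrate_intensity(img_t, mask, 1, 0.0)
    is_ = integrate_intensity(img_s, mask, 1, 0.0)
    base = compute_ratio(it, is_)
    for k in (0.5, 3.0):
        both = compute_ratio(
            integrate_intensity(k * img_t, mask, 1, 0.0),
            integrate_intensity(k * img_s, mask, 1, 0.0))
        assert both == pytest.approx(base, rel=1e-12)
        tgt_only = compute_ratio(
            integrate_intensity(k * img_t, mask, 1, 0.0), is_)
        assert tgt_only == pytest.approx(k * base, rel=1e-12)


def test_measured_negative_intensity_flagged(rendered_small):
    table, _ = measure_stack_auto(rendered_small)
    assert {"root_id", "ratio", "qc_flags"} <= set(table.columns)
    # sanity: clean rows have positive integrals
    clean = qc_clean(table)
    assert (clean["int_standard"] > 0).all()


# ---------------------------------------------------------------------------
# normalizations
# ---------------------------------------------------------------------------

def test_reference_normalization_single_root():
    table = _table([_rec("r0", "epidermis", 2.0, i) for i in (1, 2, 3)]
                   + [_rec("r0", "cortex", 1.0, 4)])
    out = normalize_by_reference_tissue(table)
    assert out.loc[out["tissue"] == "epidermis", "norm_ratio"].tolist() \
        == [1.0, 1.0, 1.0]
    assert out.loc[out["tissue"] == "cortex", "norm_ratio"].tolist() == [0.5]


def test_reference_normalization_median_by_hand():
    table = _table([_rec("r0", "epidermis", r, i)
                    for i, r in enumerate([1.0, 2.0, 3.0], 1)]
                   + [_rec("r0", "pericycle", 4.0, 9)])
    out = normalize_by_reference_tissue(table)
    assert out.loc[out["tissue"] == "pericycle", "norm_ratio"].iloc[0] \
        == pytest.approx(2.0)


def test_reference_normalization_pools_roots_on_common_scale():
    """Two roots with different scales, same structure: identical pooled."""
    rows = []
    for root, scale in (("a", 1.0), ("b", 7.0)):
        rows += [_rec(root, "epidermis", scale * r, i)
                 for i, r in enumerate([0.9, 1.0, 1.1], 1)]
        rows += [_rec(root, "cortex", scale * r, i + 10)
                 for i, r in enumerate([0.5, 0.6], 1)]
    out = normalize_by_reference_tissue(_table(rows))
    a = out[out["root_id"] == "a"].sort_values("nucleus_id")
    b = out[out["root_id"] == "b"].sort_values("nucleus_id")
    assert np.allclose(a["norm_ratio"].values, b["norm_ratio"].values)
    # per-root reference median is exactly 1 before pooling
    for root in ("a", "b"):
        ref = out[(out["root_id"] == root)
                  & (out["tissue"] == "epidermis")]["norm_ratio"]
        assert ref.median() == 1.0


def test_reference_normalization_missing_reference_errors():
    table = _table([_rec("r1", "cortex", 1.0, 1)])
    with pytest.raises(ValueError, match="r1"):
        normalize_by_reference_tissue(table)


def test_control_correct_self_identity():
    rows = [_rec("r0", t, r, i)
            for i, (t, r) in enumerate(
                [("epidermis", 1.0), ("epidermis", 1.2), ("cortex", 0.7),
                 ("cortex", 0.9), ("pericycle", 1.4), ("pericycle", 1.6)], 1)]
    ctrl = normalize_by_reference_tissue(_table(rows))
    out = control_correct(ctrl, ctrl)
    med = out.groupby("tissue")["corrected_ratio"].median()
    assert (med == 1.0).all()


def test_control_correct_by_hand():
    tgt = normalize_by_reference_tissue(_table(
        [_rec("r0", "epidermis", 1.0, 1),
         _rec("r0", "cortex", 0.8, 2), _rec("r0", "cortex", 1.2, 3)]))
    ctrl = normalize_by_reference_tissue(_table(
        [_rec("c0", "epidermis", 1.0, 1),
         _rec("c0", "cortex", 0.8, 2)]))
    out = control_correct(tgt, ctrl)
    cortex = sorted(out.loc[out["tissue"] == "cortex", "corrected_ratio"])
    assert cortex == pytest.approx([1.0, 1.5])


def test_control_correct_empty_target():
    ctrl = normalize_by_reference_tissue(_table(
        [_rec("c0", "epidermis", 1.0, 1)]))
    empty = ctrl.iloc[0:0]
    assert control_correct(empty, ctrl).empty


def test_control_correct_missing_tissue_errors():
    tgt = normalize_by_reference_tissue(_table(
        [_rec("r0", "epidermis", 1.0, 1), _rec("r0", "endodermis", 0.5, 2)]))
    ctrl = normalize_by_reference_tissue(_table(
        [_rec("c0", "epidermis", 1.0, 1)]))
    with pytest.raises(ValueError, match="endodermis"):
        control_correct(tgt, ctrl)


# ---------------------------------------------------------------------------
# per-root averages and tracking
# ---------------------------------------------------------------------------

def test_per_root_average_basic():
    table = _table([_rec("r0", "cortex", r, i)
                    for i, r in enumerate([1.0, 2.0, 3.0], 1)])
    out = per_root_average(table)
    assert len(out) == 1
    assert out["mean_ratio"].iloc[0] == pytest.approx(2.0)


def test_per_root_average_excludes_flagged_and_splits_roots():
    table = _table([
        _rec("r0", "cortex", 1.0, 1), _rec("r0", "cortex", 3.0, 2),
        _rec("r0", "cortex", 99.0, 3, flags="saturated"),
        _rec("r1", "cortex", 5.0, 1),
    ])
    out = per_root_average(table)
    assert len(out) == 2
    r0 = out[out["root_id"] == "r0"]
    assert r0["mean_ratio"].iloc[0] == pytest.approx(2.0)
    assert r0["n_nuclei"].iloc[0] == 2


def test_nearest_centroid_tracking_with_gate():
    prev = pd.DataFrame({"nucleus_id": [1, 2], "y": [10.0, 40.0],
                         "x": [10.0, 40.0]})
    curr = pd.DataFrame({"nucleus_id": [5, 6, 7], "y": [12.0, 41.0, 80.0],
                         "x": [10.0, 39.0, 80.0]})
    link = track_nearest_centroid(prev, curr, max_displacement=5.0)
    assert link == {1: 5, 2: 6}


# ---------------------------------------------------------------------------
# M/I relative ratio
# ---------------------------------------------------------------------------

def _mi_records(m_ratio, neighbor_ratios, t=0.0):
    m = pd.DataFrame([{"t_min": t, "nucleus_id": 99, "ratio": m_ratio,
                       "y": 50.0, "x": 50.0}])
    inter = pd.DataFrame([
        {"t_min": t, "nucleus_id": i, "ratio": r,
         "y": 50.0 + 10 * (i + 1), "x": 50.0}
        for i, r in enumerate(neighbor_ratios)])
    return m, inter


def test_mi_ratio_unity_for_matched_neighbours():
    m, inter = _mi_records(1.0, [1.0, 1.0])
    out = mphase_relative_ratio(m, inter, neighbor_radius=60.0)
    assert out["m_over_i"].iloc[0] == pytest.approx(1.0)


def test_mi_ratio_uses_neighbour_mean():
    m, inter = _mi_records(0.4, [0.8, 1.2])
    out = mphase_relative_ratio(m, inter, neighbor_radius=60.0)
    assert out["m_over_i"].iloc[0] == pytest.approx(0.4)
    assert out["n_neighbors"].iloc[0] == 2


def test_mi_ratio_without_neighbours_errors():
    m, inter = _mi_records(0.4, [0.8])
    with pytest.raises(ValueError, match="neighbour"):
        mphase_relative_ratio(m, inter, neighbor_radius=5.0)


def test_mi_ratio_tracks_moving_neighbours():
    rows_m, rows_i = [], []
    for k, t in enumerate([0.0, 5.0, 10.0]):
        rows_m.append({"t_min": t, "nucleus_id": 99, "ratio": 0.5,
                       "y": 50.0, "x": 50.0})
        # neighbour drifts 3 px per frame and gets a fresh id each frame
        rows_i.append({"t_min": t, "nucleus_id": 10 + k, "ratio": 1.0 + k,
                       "y": 70.0 + 3 * k, "x": 50.0})
        # distractor far away
        rows_i.append({"t_min": t, "nucleus_id": 50 + k, "ratio": 9.0,
                       "y": 200.0, "x": 200.0})
    out = mphase_relative_ratio(pd.DataFrame(rows_m), pd.DataFrame(rows_i),
                                neighbor_radius=30.0, max_displacement=5.0)
    assert out["m_over_i"].tolist() == pytest.approx([0.5, 0.25, 0.5 / 3])


# ---------------------------------------------------------------------------
# decay fitting
# ---------------------------------------------------------------------------

def test_fit_exponential_recovers_time_constant():
    t = np.arange(0, 70, 10, dtype=float)
    y = 0.3 + 0.8 * np.exp(-t / 22.0)
    fit = fit_exponential_decay(t, y)
    assert fit["tau"] == pytest.approx(22.0, rel=1e-6)
    assert fit["half_time"] == pytest.approx(22.0 * math.log(2), rel=1e-6)
    assert fit["plateau"] == pytest.approx(0.3, abs=1e-6)


def test_measured_medians_track_partition_curve_monotonically():
    """Median measured ratio is strictly ordered across site-abundance
    levels, i.e. Spearman rho = 1 against the generating curve."""
    from nucratio import pipeline as pl
    from nucratio.synthgen import make_scatter_scene, render_scene
    levels = [1.0, 2.5, 4.0, 6.0]
    medians = []
    for i, s in enumerate(levels):
        scene = make_scatter_scene(15, s_tot_mean=s, s_tot_sd=0.0,
                                   shape=(320, 320), seed=40 + i)
        stack = render_scene(scene, BASE_PARAMS, NoiseModel(), n_z=3,
                             seed=500 + i)
        clean = qc_clean(measure_stack_auto(stack)[0])
        medians.append(float(clean["ratio"].median()))
    from scipy.stats import spearmanr
    rho, _ = spearmanr(levels, medians)
    assert rho == 1.0
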