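"""End-to-end pipeline: simulate -> detect -> segment -> measure -> stats.

One :class:`PipelineConfig` (a validated nested mapping mirroring the YAML
config schema) drives a deterministic run: a single global seed is fanned
out to per-stage child seeds by stable derivation, every stage writes its
outputs before the next starts, and a manifest records a content hash for
every file.

Four scenario presets reproduce the study designs at desk scale:

``root_layers``
    Concentric tissue layers with tissue-dependent site abundance,
    measured, epidermis-normalized per root, and compared pairwise.
``control_line``
    Same layout with a non-binding probe (site abundance 0 everywhere):
    the free probe distributes uniformly, so all tissues share one true
    ratio and the measured dispersion is the shot-noise floor.
``fp_timecourse``
    Kinase-inhibitor decay (optionally with washout recovery) sampled
    over an hour, with per-root mean ratios and an exponential fit.
``mphase``
    A mitosis at 5-min frame intervals with the M/I relative-ratio
    analysis against tracked interphase neighbours.
"""

from __future__ import annotations

import copy
import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import imgio, ratiometry, stats, synthgen
from .detectseg import (FilterBankConfig, QCRules, detect_nuclei, qc_filter,
                        segment_nuclei, sum_project)

log = logging.getLogger("nucratio")

PRESETS = ("root_layers", "fp_timecourse", "mphase", "control_line")

_DEFAULTS: dict = {
    "scenario": "root_layers",
    "seed": 0,
    "simulate": {
        "shape": [448, 448],
        "n_z": 5,
        "n_roots": 3,
        "standard_budget": 1.0e4,
        "partition": {"m_tot": 20.0, "kd": 1.0, "v_n": 1.0, "v_c": 19.0,
                      "alpha": 3000.0},
        "noise": {"psf_sigma_xy": 0.5, "psf_sigma_z": 0.6,
                  "read_noise_sigma": 2.0, "camera_offset": 100.0,
                  "gain": 1.0, "bit_depth": 16},
        "layers": {"n_per_layer": [12, 10, 10, 8],
                   "s_tot_means": [5.0, 4.0, 2.5, 5.0],
                   "s_tot_cv": 0.08, "pericycle_var_factor": 10.0},
        "fp": {"s0": 5.0, "tau_decay": 25.0, "t_wash": None,
               "tau_recovery": 60.0,
               "timepoints": [0, 10, 20, 30, 40, 50, 60],
               "n_nuclei": 40},
        "mphase": {"n_nuclei": 8, "s_tot": 5.0, "frame_interval": 5.0,
                   "schedule": ["interphase", "prometaphase", "metaphase",
                                "metaphase", "anaphase", "telophase",
                                "telophase", "telophase", "telophase"]},
    },
    "detect": {"radii": [4, 6, 8, 10, 12], "response_threshold": 0.7,
               "min_separation_factor": 1.5, "smoothing_sigma": 1.0,
               "seg_smoothing_sigma": 0.5},
    "measure": {"bg_dilation_px": 15},
    "normalize": {"reference_tissue": "epidermis"},
    "stats": {"alpha": 0.05},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (config-file overrides defaults)."""

    scenario: str = "root_layers"
    seed: int = 0
    out_dir: str = "pipeline_out"
    sections: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scenario not in PRESETS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; valid presets: "
                f"{', '.join(PRESETS)}")
        merged = copy.deepcopy(_DEFAULTS)
        _deep_update(merged, self.sections)
        unknown = set(merged) - set(_DEFAULTS)
        if unknown:
            raise ValueError(f"unknown config sections: {sorted(unknown)}")
        self.sections = merged
        self.sections["scenario"] = self.scenario
        self.sections["seed"] = int(self.seed)

    def __getitem__(self, key: str):
        return self.sections[key]

    def partition_params(self, **overrides) -> synthgen.PartitionParams:
        p = dict(self["simulate"]["partition"])
        p.update(overrides)
        return synthgen.PartitionParams(s_tot=p.pop("s_tot", 0.0), **p)

    def noise_model(self) -> synthgen.NoiseModel:
        return synthgen.NoiseModel(**self["simulate"]["noise"])

    def filter_bank(self) -> FilterBankConfig:
        d = self["detect"]
        return FilterBankConfig(
            radii=tuple(d["radii"]),
            response_threshold=d["response_threshold"],
            min_separation_factor=d["min_separation_factor"],
            smoothing_sigma=d["smoothing_sigma"])


def _deep_update(base: dict, extra: dict) -> None:
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def scenario_presets(name: str, seed: int = 0,
                     out_dir: str = "pipeline_out") -> PipelineConfig:
    """Fully populated config for one of the named scenario presets."""
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {', '.join(PRESETS)}")
    return PipelineConfig(scenario=name, seed=seed, out_dir=out_dir)


def child_seed(seed: int, *path: int | str) -> int:
    """Stable per-stage seed derivation from the global seed."""
    ent = [int(seed)]
    for p in path:
        if isinstance(p, str):
            ent.append(int.from_bytes(hashlib.sha256(
                p.encode()).digest()[:4], "big"))
        else:
            ent.append(int(p))
    return int(np.random.SeedSequence(ent).generate_state(1)[0] % (2 ** 31))


def match_labels_to_truth(
    mask, scene: synthgen.SceneTruth, max_dist: float = 10.0
) -> pd.DataFrame:
    """Assign segmented labels to ground-truth nuclei by nearest centroid.

    Returns a labels-meta frame (nucleus_id = segmentation label, plus the
    matched truth id, tissue, phase and true s_tot); labels with no truth
    nucleus within ``max_dist`` px are left unmatched (truth_id = -1).
    One-to-one greedy matching on ascending distance.
    """
    cents = mask.centroids()
    pairs = []
    for lab, (cy, cx) in cents.items():
        for n in scene.nuclei:
            d = float(np.hypot(cy - n.y, cx - n.x))
            if d <= max_dist:
                pairs.append((d, lab, n.id))
    pairs.sort()
    used_lab: set[int] = set()
    used_truth: set[int] = set()
    match: dict[int, int] = {}
    for _, lab, tid in pairs:
        if lab in used_lab or tid in used_truth:
            continue
        match[lab] = tid
        used_lab.add(lab)
        used_truth.add(tid)
    truth = {n.id: n for n in scene.nuclei}
    rows = []
    for lab in cents:
        tid = match.get(lab, -1)
        n = truth.get(tid)
        rows.append({
            "nucleus_id": lab, "truth_id": tid,
            "tissue": n.tissue if n else "none",
            "phase": n.phase if n else "interphase",
            "s_tot": n.s_tot if n else np.nan,
            "y": cents[lab][0], "x": cents[lab][1],
        })
    return pd.DataFrame(rows)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _build_scenes(cfg: PipelineConfig) -> dict[str, list[synthgen.SceneTruth]]:
    """Ground-truth scenes per root for the configured scenario."""
    sim = cfg["simulate"]
    shape = tuple(sim["shape"])
    scenario = cfg.scenario
    scenes: dict[str, list[synthgen.SceneTruth]] = {}
    if scenario in ("root_layers", "control_line"):
        lay = sim["layers"]
        spec = synthgen.default_layer_spec(
            n_per_layer=tuple(lay["n_per_layer"]),
            s_tot_means=tuple(lay["s_tot_means"]),
            s_tot_cv=lay["s_tot_cv"],
            pericycle_var_factor=lay["pericycle_var_factor"])
        if scenario == "control_line":
            # non-binding probe: identical (zero) site abundance everywhere
            spec = {t: synthgen.LayerSpec(n=s.n, s_tot_mean=0.0, s_tot_sd=0.0,
                                          radius_mean=s.radius_mean,
                                          radius_sd=s.radius_sd)
                    for t, s in spec.items()}
        for r in range(sim["n_roots"]):
            scene = synthgen.make_root_layers_scene(
                spec, shape=shape,
                seed=child_seed(cfg.seed, "scene", r),
                standard_budget=sim["standard_budget"])
            scenes[f"root{r}"] = [scene]
    elif scenario == "fp_timecourse":
        fp = sim["fp"]
        scenario_obj = synthgen.FPScenario(
            s0=fp["s0"], tau_decay=fp["tau_decay"],
            t_wash=fp["t_wash"], tau_recovery=fp["tau_recovery"],
            timepoints=tuple(float(t) for t in fp["timepoints"]))
        for r in range(sim.get("n_roots", 5)):
            base = synthgen.make_scatter_scene(
                n=fp["n_nuclei"], s_tot_mean=fp["s0"],
                s_tot_sd=0.08 * fp["s0"], shape=shape,
                seed=child_seed(cfg.seed, "scene", r),
                standard_budget=sim["standard_budget"])
            scenes[f"root{r}"] = synthgen.make_fp_timecourse(
                scenario_obj, base)
    elif scenario == "mphase":
        mp = sim["mphase"]
        base = synthgen.make_scatter_scene(
            n=mp["n_nuclei"], s_tot_mean=mp["s_tot"], s_tot_sd=0.0,
            shape=shape, seed=child_seed(cfg.seed, "scene", 0),
            standard_budget=sim["standard_budget"])
        # mitotic cell: the nucleus closest to the frame centre
        cy, cx = (shape[0] - 1) / 2, (shape[1] - 1) / 2
        mitotic = min(base.nuclei,
                      key=lambda n: (n.y - cy) ** 2 + (n.x - cx) ** 2)
        dt = mp["frame_interval"]
        schedule = [(i * dt, phase)
                    for i, phase in enumerate(mp["schedule"])]
        scenes["root0"] = synthgen.make_mphase_sequence(
            base, mitotic.id, schedule,
            seed=child_seed(cfg.seed, "mphase", 0))
    return scenes


def run_pipeline(cfg: PipelineConfig, out_dir: str | Path | None = None
                 ) -> dict:
    """Run the full pipeline for one config; returns the manifest dict.

    Deterministic given (config, seed).  Outputs: per-frame stack TIFFs,
    truth CSVs, label-mask TIFFs, detection CSVs, a pooled measurement
    CSV, scenario-specific analysis CSVs, a stats CSV, the resolved
    config, a run log, and ``manifest.json`` with a sha256 per file.
    """
    out = Path(out_dir if out_dir is not None else cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    files: list[Path] = []
    try:
        log.info("scenario=%s seed=%d", cfg.scenario, cfg.seed)
        imgio.save_config(cfg.sections, out / "resolved_config.yaml")
        files.append(out / "resolved_config.yaml")

        base_params = cfg.partition_params()
        noise = cfg.noise_model()
        bank = cfg.filter_bank()
        sim = cfg["simulate"]

        scenes = _build_scenes(cfg)
        tables = []
        for root, frames in scenes.items():
            truth_path = out / f"{root}_truth.csv"
            imgio.write_scene_truth(frames, base_params, truth_path)
            files.append(truth_path)
            for fi, scene in enumerate(frames):
                stack = synthgen.render_scene(
                    scene, base_params, noise, n_z=sim["n_z"],
                    seed=child_seed(cfg.seed, "render", root, fi))
                tif = out / f"{root}_t{fi:02d}.tif"
                imgio.write_stack(stack, tif)
                files.append(tif)
                std = sum_project(stack, 0, stack.channel_index("standard"))
                tgt = sum_project(stack, 0, stack.channel_index("target"))
                detections = detect_nuclei(std, bank)
                mask = segment_nuclei(
                    std, detections,
                    smoothing_sigma=cfg["detect"]["seg_smoothing_sigma"])
                rules = QCRules(saturation_level=sim["n_z"] * 65535)
                flags = qc_filter(mask, {"target": tgt, "standard": std},
                                  rules)
                meta = match_labels_to_truth(mask, scene)
                table = ratiometry.measure_frame(
                    stack, mask, t=0, t_min=scene.t_min, root_id=root,
                    labels_meta=meta, qc_flags=flags,
                    bg_dilation_px=cfg["measure"]["bg_dilation_px"])
                table = table.merge(
                    meta[["nucleus_id", "truth_id", "y", "x"]],
                    on="nucleus_id", how="left")
                mask_path = out / f"{root}_t{fi:02d}_mask.tif"
                imgio.write_label_mask(mask.labels, mask_path)
                files.append(mask_path)
                tables.append(table)
            log.info("measured %s (%d frames)", root, len(frames))
        pooled = pd.concat(tables, ignore_index=True)
        meas_path = out / "measurements.csv"
        extra = pooled[["root_id", "t_min", "nucleus_id",
                        "truth_id", "y", "x"]]
        imgio.write_measurements(
            pooled[imgio.MEASUREMENT_COLUMNS], meas_path)
        files.append(meas_path)
        pos_path = out / "positions.csv"
        extra.to_csv(pos_path, index=False, float_format="%.6g")
        files.append(pos_path)

        stat_rows = []
        if cfg.scenario in ("root_layers", "control_line"):
            normed = ratiometry.normalize_by_reference_tissue(
                pooled, cfg["normalize"]["reference_tissue"])
            normed_clean = ratiometry.qc_clean(normed)
            norm_path = out / "normalized.csv"
            normed_clean.to_csv(norm_path, index=False, float_format="%.6g")
            files.append(norm_path)
            results = stats.pairwise_tissue_tests(
                normed_clean, synthgen.TISSUES, value_col="norm_ratio",
                alpha=cfg["stats"]["alpha"])
            for r in results:
                stat_rows.append({
                    "test": r.test, "statistic": r.statistic,
                    "p_value": r.p_value, "adjusted_p": r.adjusted_p,
                    "n1": r.n1, "n2": r.n2, "method": r.method})
            cvs = (normed_clean.groupby("tissue")["norm_ratio"]
                   .apply(stats.coefficient_of_variation))
            cv_path = out / "tissue_cv.csv"
            cvs.rename("cv").to_csv(cv_path, float_format="%.6g")
            files.append(cv_path)
        elif cfg.scenario == "fp_timecourse":
            means = ratiometry.per_root_average(pooled)
            tc_path = out / "ratio_timecourse.csv"
            means.to_csv(tc_path, index=False, float_format="%.6g")
            files.append(tc_path)
            grand = means.groupby("t_min")["mean_ratio"].mean()
            fit = ratiometry.fit_exponential_decay(
                grand.index.to_numpy(), grand.to_numpy())
            fit_path = out / "decay_fit.json"
            fit_path.write_text(json.dumps(fit, indent=2, sort_keys=True))
            files.append(fit_path)
            clean = ratiometry.qc_clean(pooled)
            t_first, t_last = clean["t_min"].min(), clean["t_min"].max()
            r = stats.wilcoxon_rank_sum(
                clean.loc[clean["t_min"] == t_first, "ratio"],
                clean.loc[clean["t_min"] == t_last, "ratio"])
            stat_rows.append({
                "test": f"wilcoxon_rank_sum[t={t_first} vs t={t_last}]",
                "statistic": r.statistic, "p_value": r.p_value,
                "adjusted_p": None, "n1": r.n1, "n2": r.n2,
                "method": r.method})
        elif cfg.scenario == "mphase":
            clean = pooled[np.isfinite(pooled["ratio"])]
            m_rec = clean[clean["phase"] != "interphase"]
            i_rec = clean[clean["phase"] == "interphase"]
            # keep only timepoints where the mitotic object was matched
            rel = ratiometry.mphase_relative_ratio(
                m_rec, i_rec,
                neighbor_radius=0.5 * min(tuple(sim["shape"])))
            rel_path = out / "mphase_relative_ratio.csv"
            rel.to_csv(rel_path, index=False, float_format="%.6g")
            files.append(rel_path)
        if stat_rows:
            stats_path = out / "stats.csv"
            pd.DataFrame(stat_rows).to_csv(stats_path, index=False,
                                           float_format="%.6g")
            files.append(stats_path)

        manifest = {
            "scenario": cfg.scenario,
            "seed": cfg.seed,
            "created": datetime.now(timezone.utc).isoformat(),
            "files": {p.name: _sha256(p) for p in sorted(files)},
        }
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        log.info("wrote %d files", len(files))
        return manifest
    finally:
        log.removeHandler(handler)
        handler.close()
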