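"""End-to-end pipeline: simulate/load -> preprocess -> detect -> track -> metrics -> stats.

A single structured config drives every step so that any result bundle can be
reproduced bit-identically from its config echo.  Each condition (e.g. a
perturbed enhancer vs control) contributes one or more movies, either
simulated (a ``simulate`` block of generator parameters) or loaded from TIFF;
per-movie failures are logged and the remaining movies still run.

The statistical unit for condition comparisons is the movie (embryo) by
default — per-track pooling is available but labeled exploratory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .detection import DetectionParams, detect_movie, dots_to_table, normalize_stage
from .metrics import (frame_metrics, frame_metrics_table, stage_metrics,
                      track_features_table)
from .preprocess import (Movie2D, MovieStack, StagePartition, bleach_correct,
                         max_project, split_stages, to_uint8)
from .simulate import SimConfig, render_movie, simulate_telegraph
from .stats import mann_whitney_u, permutation_test, t_test_auto, variance_compare
from .tracking import TrackingParams, link_frames, tracks_to_table

logger = logging.getLogger("burstquant")

STAGE_METRIC_COLUMNS = ["t_first_dot_s", "t_first_peak_s", "t_all_dots_s",
                        "max_n_dots", "avg_transcription_rate",
                        "init_total_pixels", "init_active_nuclei",
                        "intensity_peak_sd"]
TRACK_METRIC_COLUMNS = ["start_time_s", "n_frames_present", "avg_size_px",
                        "avg_brightness", "max_brightness", "n_bursts",
                        "mean_on_run_s", "mean_off_gap_s", "n_transitions"]


class PipelineConfig:
    """Validated pipeline configuration (typically loaded from YAML)."""

    def __init__(self, raw: dict):
        self.raw = raw
        self.seed = int(raw.get("seed", 0))
        self.output_dir = raw.get("output_dir")
        self.conditions = raw.get("conditions", {})
        if not self.conditions:
            raise ValueError("config must define at least one condition")
        self.detection = DetectionParams(**raw.get("detection", {}))
        self.tracking = TrackingParams(**raw.get("tracking", {}))
        self.bleach = {"channel": "green", "method": "simple_ratio",
                       **raw.get("bleach", {})}
        self.metrics = {"init_window_frac": 0.25, "smooth_w": 3,
                        **raw.get("metrics", {})}
        self.stats = {"alpha": 0.05, "n_permutations": 10_000, "unit": "movie",
                      **raw.get("stats", {})}
        part = raw.get("stage_partition")
        self.stage_partition = (
            StagePartition([(e["label"], e["start"], e["end"]) for e in part])
            if part else None)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(yaml.safe_load(Path(path).read_text()))

    def param_hash(self) -> str:
        blob = json.dumps(self.raw, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _movie_seed(base_seed: int, cond_idx: int, movie_idx: int) -> int:
    ss = np.random.SeedSequence([base_seed, cond_idx, movie_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def process_movie(stack: MovieStack, partition: StagePartition,
                  detection: DetectionParams, tracking: TrackingParams,
                  metrics_opts: dict | None = None,
                  bleach_opts: dict | None = None) -> dict:
    """Run one movie through preprocessing, detection, tracking, and metrics.

    Returns ``{stage_label: {"dots": per-frame lists, "tracks": [...],
    "frame_metrics": DataFrame, "stage_metrics": StageMetrics,
    "track_features": DataFrame}}``.
    """
    metrics_opts = {"init_window_frac": 0.25, "smooth_w": 3, **(metrics_opts or {})}
    bleach_opts = {"channel": "green", "method": "simple_ratio", **(bleach_opts or {})}

    flat = max_project(stack)
    flat = bleach_correct(flat, channel=bleach_opts["channel"],
                          method=bleach_opts["method"])
    results = {}
    for stage in split_stages(flat, partition):
        gi, ri = stage.channel("green"), stage.channel("red")
        green8 = np.stack([to_uint8(stage.pixels[t, :, :, gi], stage.bit_depth)
                           for t in range(stage.n_frames)])
        red8 = np.stack([to_uint8(stage.pixels[t, :, :, ri], stage.bit_depth)
                         for t in range(stage.n_frames)])
        dots = detect_movie(green8, detection, stage_label=stage.stage_label,
                            red_frames=red8 if detection.use_nuclear_mask else None)
        dots = normalize_stage(dots)
        tracks = link_frames(dots, tracking)
        fm = frame_metrics(dots)
        sm = stage_metrics(fm, tracks, stage.frame_interval_s,
                           init_window_frac=metrics_opts["init_window_frac"],
                           smooth_w=metrics_opts["smooth_w"],
                           stage_label=stage.stage_label)
        tf = track_features_table(tracks, stage.frame_interval_s)
        results[stage.stage_label] = {
            "dots": dots, "tracks": tracks,
            "frame_metrics": frame_metrics_table(fm),
            "stage_metrics": sm,
            "track_features": tf,
        }
        logger.info("stage %s: %d dots, %d tracks, max %d dots/frame",
                    stage.stage_label, sum(len(d) for d in dots), len(tracks),
                    sm.max_n_dots)
    return results


def _condition_movies(name: str, spec: dict, cond_idx: int, base_seed: int):
    """Yield (movie_id, MovieStack, StagePartition) for one condition."""
    if "simulate" in spec:
        sim_kwargs = dict(spec["simulate"])
        n_movies = int(sim_kwargs.pop("n_movies", 1))
        if "stage_labels" in sim_kwargs:
            sim_kwargs["stage_labels"] = tuple(sim_kwargs["stage_labels"])
        for m in range(n_movies):
            cfg = SimConfig(**{**sim_kwargs,
                               "seed": _movie_seed(base_seed, cond_idx, m)})
            truth = simulate_telegraph(cfg)
            stack = render_movie(truth, cfg)
            yield f"{name}_{m}", stack, cfg.stage_partition()
    elif "movies" in spec:
        for m, entry in enumerate(spec["movies"]):
            pixels = tifffile.imread(entry["tiff"])
            if pixels.ndim == 4:
                pixels = pixels[:, None]
            stack = MovieStack(pixels=pixels,
                               frame_interval_s=float(entry.get("frame_interval_s", 1.77)),
                               bit_depth=int(entry.get("bit_depth", 8)))
            part = StagePartition([(e["label"], e["start"], e["end"])
                                   for e in entry["stages"]])
            yield f"{name}_{m}", stack, part
    else:
        raise ValueError(f"condition {name!r} needs a 'simulate' or 'movies' block")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every condition's movies through the pipeline and collect bundles.

    Returns ``{condition: bundle}`` where a bundle has tidy ``stage_metrics``,
    ``track_features``, ``frame_metrics`` and ``dots`` DataFrames plus a
    manifest.  If an output directory is configured, all tables, the config
    echo, and the manifest are written there.  Per-movie failures are logged
    and recorded in the manifest; the pipeline continues over the remaining
    movies and reports failures in the returned bundles.
    """
    out_root = Path(config.output_dir) if config.output_dir else None
    bundles = {}
    for cond_idx, (name, spec) in enumerate(sorted(config.conditions.items())):
        sm_rows, tf_frames, fm_frames, dot_frames, failures = [], [], [], [], []
        for movie_id, stack, default_part in _condition_movies(
                name, spec, cond_idx, config.seed):
            partition = config.stage_partition or default_part
            try:
                res = process_movie(stack, partition, config.detection,
                                    config.tracking, config.metrics, config.bleach)
            except Exception as exc:  # keep processing remaining movies
                logger.error("movie %s failed: %s", movie_id, exc)
                failures.append({"movie": movie_id, "error": str(exc)})
                continue
            for stage_label, r in res.items():
                row = {"movie": movie_id, "stage": stage_label}
                row.update({k: getattr(r["stage_metrics"], k)
                            for k in STAGE_METRIC_COLUMNS})
                sm_rows.append(row)
                tf = r["track_features"].copy()
                tf.insert(0, "stage", stage_label)
                tf.insert(0, "movie", movie_id)
                tf_frames.append(tf)
                fm = r["frame_metrics"].copy()
                fm.insert(0, "stage", stage_label)
                fm.insert(0, "movie", movie_id)
                fm_frames.append(fm)
                dt = dots_to_table(r["dots"])
                dt.insert(0, "movie", movie_id)
                dot_frames.append(dt)
        bundle = {
            "condition": name,
            "stage_metrics": pd.DataFrame(sm_rows),
            "track_features": (pd.concat(tf_frames, ignore_index=True)
                               if tf_frames else pd.DataFrame()),
            "frame_metrics": (pd.concat(fm_frames, ignore_index=True)
                              if fm_frames else pd.DataFrame()),
            "dots": (pd.concat(dot_frames, ignore_index=True)
                     if dot_frames else pd.DataFrame()),
            "manifest": {
                "condition": name,
                "version": __version__,
                "python": platform.python_version(),
                "seed": config.seed,
                "param_hash": config.param_hash(),
                "failures": failures,
            },
        }
        bundles[name] = bundle
        if out_root is not None:
            cdir = out_root / name
            cdir.mkdir(parents=True, exist_ok=True)
            for key in ("stage_metrics", "track_features", "frame_metrics", "dots"):
                bundle[key].to_csv(cdir / f"{key}.csv", index=False)
            (cdir / "manifest.json").write_text(
                json.dumps(bundle["manifest"], indent=2, sort_keys=True) + "\n")
    if out_root is not None:
        out_root.mkdir(parents=True, exist_ok=True)
        (out_root / "config_echo.json").write_text(
            json.dumps(config.raw, indent=2, sort_keys=True, default=str) + "\n")
    return bundles


def _values_per_unit(bundle: dict, stage: str, metric: str, unit: str) -> np.ndarray:
    """Metric values for one stage at the requested statistical unit."""
    if metric in STAGE_METRIC_COLUMNS:
        df = bundle["stage_metrics"]
        vals = df.loc[df["stage"] == stage, metric]
    else:
        df = bundle["track_features"]
        sub = df[df["stage"] == stage]
        if unit == "movie":
            vals = sub.groupby("movie")[metric].mean()
        else:
            vals = sub[metric]
    return vals.dropna().to_numpy(dtype=float)


def compare_conditions(case_bundle: dict, control_bundle: dict,
                       stats_opts: dict | None = None) -> pd.DataFrame:
    """Run the full test battery on every metric x stage shared by two bundles.

    For each stage present in both conditions and each stage- and track-level
    metric, applies Mann-Whitney U, the permutation test, the auto-switching
    t-test, and the F variance comparison.  Stages present in only one
    condition are skipped with a warning; returns one row per
    metric x stage x method.
    """
    opts = {"alpha": 0.05, "n_permutations": 10_000, "unit": "movie", "seed": 0,
            **(stats_opts or {})}
    case_stages = set(case_bundle["stage_metrics"].get("stage", pd.Series(dtype=str)))
    ctrl_stages = set(control_bundle["stage_metrics"].get("stage", pd.Series(dtype=str)))
    for missing in sorted(case_stages ^ ctrl_stages):
        logger.warning("stage %s present in only one condition; skipped", missing)
    rows = []
    for stage in sorted(case_stages & ctrl_stages):
        for metric in STAGE_METRIC_COLUMNS + TRACK_METRIC_COLUMNS:
            case = _values_per_unit(case_bundle, stage, metric, opts["unit"])
            control = _values_per_unit(control_bundle, stage, metric, opts["unit"])
            if len(case) == 0 or len(control) == 0:
                continue
            results = []
            try:
                results.append(mann_whitney_u(case, control))
            except ValueError as exc:
                logger.warning("MWU failed for %s/%s: %s", stage, metric, exc)
            results.append(permutation_test(
                case, control, n_permutations=opts["n_permutations"],
                seed=opts["seed"]))
            if len(case) >= 2 and len(control) >= 2:
                try:
                    results.append(t_test_auto(case, control, alpha=opts["alpha"]))
                    results.append(variance_compare(case, control, method="F"))
                except ValueError as exc:
                    logger.warning("t/variance test failed for %s/%s: %s",
                                   stage, metric, exc)
            for r in results:
                rows.append({
                    "metric": metric, "stage": stage, "method": r.method,
                    "statistic": r.statistic, "p": r.p_value,
                    "sidedness": r.sidedness,
                    "p_two_sided": r.p_two_sided,
                    "n_case": r.n_case, "n_control": r.n_control,
                    "n_permutations": r.n_permutations,
                    "seed": r.seed, "stars": r.stars,
                })
    return pd.DataFrame(rows, columns=["metric", "stage", "method", "statistic",
                                       "p", "sidedness", "p_two_sided", "n_case",
                                       "n_control", "n_permutations", "seed",
                                       "stars"])


def run_and_compare(config: PipelineConfig, case: str, control: str) -> pd.DataFrame:
    """Convenience: run the pipeline and compare two named conditions."""
    bundles = run_pipeline(config)
    stats_opts = dict(config.stats)
    stats_opts.setdefault("seed", config.seed)
    table = compare_conditions(bundles[case], bundles[control], stats_opts)
    if config.output_dir:
        table.to_csv(Path(config.output_dir) / "stats_results.csv", index=False)
    return table
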