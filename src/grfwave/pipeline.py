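"""End-to-end orchestration: simulate -> preprocess -> metrics -> stats -> pca.

A single YAML (or in-memory dict) configuration drives every stage; all
defaults are echoed into the run manifest so no silent defaults exist.
Stage outputs are pure functions of (inputs, config, seed): CSV floats
are printed at full precision and JSON keys sorted, so re-running with
the same seed reproduces every output byte for byte (the manifest's
timestamps aside).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, SegmentationError
from .metrics import find_peaks, valr_for_stance
from .pca import WaveformPCA, build_matrix, extract_regions
from .preprocess import (
    StanceCurve,
    average_steps,
    detect_stance_events,
    lowpass_filter,
    normalize_stance,
    write_curves,
)
from .recording import CHANNELS, ForceRecording, SubjectMeta, read_recording
from .simulate import Cohort, CohortConfig, WaveformTemplate, generate_cohort, write_cohort
from .stats import results_to_frame, sex_ttest, speed_rm_anova

#: Channels the PCA stage models (medial-lateral is noise by design).
PCA_CHANNELS = ("vertical", "ant_post")


@dataclass
class PipelineConfig:
    """Validated full-run configuration; unknown keys are rejected."""

    seed: int = 42
    out_dir: str = "results"
    input_dir: str | None = None  # raw recordings; None -> simulate
    simulate: dict = field(default_factory=dict)  # CohortConfig overrides
    cutoff: float = 50.0
    threshold: float = 20.0
    min_contact: float = 0.100
    interpolation: str = "cubic"
    alpha: float = 0.05
    coverage: float = 0.95
    k_max: int = 4
    region_epsilon: float = 0.05
    make_plots: bool = False

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        allowed = {f.name for f in dataclasses.fields(cls)}
        unknown = sorted(set(raw) - allowed)
        if unknown:
            raise ConfigError(f"unknown config key(s): {unknown}")
        cfg = cls(**raw)
        sim_allowed = {f.name for f in dataclasses.fields(CohortConfig)}
        sim_unknown = sorted(set(cfg.simulate) - sim_allowed)
        if sim_unknown:
            raise ConfigError(f"unknown simulate key(s): {sim_unknown}")
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(raw)

    def cohort_config(self) -> CohortConfig:
        over = dict(self.simulate)
        over.setdefault("seed", self.seed)
        over.setdefault("threshold", self.threshold)
        if "template" in over and isinstance(over["template"], dict):
            over["template"] = WaveformTemplate(**over["template"])
        return CohortConfig(**over)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _jsonify(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(
    config: PipelineConfig | dict | str | Path,
) -> dict:
    """Execute all stages and return the run manifest (also written to disk).

    Stages: (1) simulate a synthetic cohort unless ``input_dir`` points at
    real recordings; (2) preprocess every recording into averaged stance
    curves; (3) compute per-condition discrete metrics (per-step VALR
    averaged over steps, plus the four peaks); (4) sex t-tests per speed
    and within-sex repeated-measures ANOVA with Tukey contrasts;
    (5) per-sex, per-channel waveform PCA with limit curves and regions.
    """
    if isinstance(config, (str, Path)):
        config = PipelineConfig.from_yaml(config)
    elif isinstance(config, dict):
        config = PipelineConfig.from_dict(config)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "software": {"name": "grfwave", "version": __version__},
        "config": dataclasses.asdict(config),
        "seed": config.seed,
        "started": _time.strftime("%Y-%m-%dT%H:%M:%S"),
        "stages": {},
        "outputs": {},
    }

    # -- stage 1: obtain recordings ----------------------------------------
    if config.input_dir is None:
        cohort = generate_cohort(config.cohort_config())
        raw_dir = out / "raw"
        write_cohort(cohort, raw_dir)
        recordings = cohort.recordings
        manifest["stages"]["simulate"] = {
            "n_recordings": len(recordings),
            "dir": str(raw_dir),
        }
    else:
        recordings = load_recordings(config.input_dir)
        manifest["stages"]["simulate"] = {"skipped": True}
        manifest["inputs"] = {
            "dir": config.input_dir,
            "n_recordings": len(recordings),
        }

    # -- stage 2 + 3: preprocess and per-condition metrics ------------------
    averaged: list[StanceCurve] = []
    metric_rows = []
    for rec in recordings:
        filtered = lowpass_filter(rec, config.cutoff)
        events = detect_stance_events(filtered, config.threshold, config.min_contact)
        if not events:
            raise SegmentationError(
                f"no stance detected for {rec.meta.subject_id} @{rec.meta.speed}"
            )
        step_curves = [
            normalize_stance(filtered, ev, interpolation=config.interpolation)
            for ev in events
        ]
        cond = {
            ch: average_steps([sc[ch] for sc in step_curves]) for ch in CHANNELS
        }
        averaged.extend(cond.values())
        metric_rows.append(_condition_metrics(filtered, events, cond))
    curves_path = out / "curves.csv"
    write_curves(curves_path, averaged)
    metrics = pd.DataFrame(metric_rows).sort_values(
        ["sex", "speed", "subject_id"], kind="stable"
    )
    metrics_path = out / "metrics.csv"
    metrics.to_csv(metrics_path, index=False, float_format="%.17g")
    manifest["stages"]["preprocess"] = {"n_curves": len(averaged)}
    manifest["stages"]["metrics"] = {"n_conditions": len(metrics)}

    # -- stage 4: group statistics ------------------------------------------
    stat_results = []
    speeds = sorted(metrics["speed"].unique())
    for speed in speeds:
        sel = metrics[metrics["speed"] == speed]
        f = sel[sel["sex"] == "female"]["valr_bw_s"].to_numpy()
        m = sel[sel["sex"] == "male"]["valr_bw_s"].to_numpy()
        if f.size >= 2 and m.size >= 2:
            stat_results.append(sex_ttest(f, m, speed=speed, alpha=config.alpha))
    for sex in ("female", "male"):
        sel = metrics[metrics["sex"] == sex]
        if sel.empty or sel["speed"].nunique() < 2:
            continue
        table = sel.rename(columns={"valr_bw_s": "value"})[
            ["subject_id", "speed", "value"]
        ]
        for r in speed_rm_anova(table, alpha=config.alpha):
            stat_results.append(
                dataclasses.replace(r, contrast=f"{r.contrast} within {sex}")
            )
    stats_path = out / "stats.csv"
    results_to_frame(stat_results).to_csv(
        stats_path, index=False, float_format="%.17g"
    )
    manifest["stages"]["stats"] = {"n_contrasts": len(stat_results)}

    # -- stage 5: per-sex, per-channel waveform PCA --------------------------
    pca_summary = {}
    for sex in ("female", "male"):
        for channel in PCA_CHANNELS:
            key = f"{sex}_{channel}"
            try:
                matrix = build_matrix(averaged, sex, channel)
            except Exception:
                continue
            model = WaveformPCA(
                coverage=config.coverage, k_max=config.k_max
            ).fit(matrix.X)
            model_obj = {
                "sex": sex,
                "channel": channel,
                "m": matrix.m,
                "mean_curve": model.mean_,
                "loadings": model.components_[: model.n_retained_],
                "scores": model.scores_[:, : model.n_retained_],
                "row_meta": matrix.row_meta.to_dict(orient="list"),
                "variance_fractions": model.explained_variance_ratio_,
                "k_retained": model.n_retained_,
                "coverage_achieved": model.coverage_achieved_,
                "config": {
                    "coverage": config.coverage,
                    "k_max": config.k_max,
                    "region_epsilon": config.region_epsilon,
                },
            }
            with open(out / f"pca_{key}.json", "w") as fh:
                json.dump(model_obj, fh, sort_keys=True, default=_jsonify)

            limit_rows, regions = [], {}
            for pc in range(1, model.n_retained_ + 1):
                rec_limits = extract_regions(
                    model.reconstruct_limits(pc), config.region_epsilon
                )
                raw_runs = extract_regions(model.reconstruct_limits(pc), 0.0)
                regions[f"pc{pc}"] = {
                    "variance_fraction": rec_limits.variance_fraction,
                    "upper_over_lower": rec_limits.regions_upper_over_lower,
                    "lower_over_upper": rec_limits.regions_lower_over_upper,
                    "sign_runs_upper": raw_runs.regions_upper_over_lower,
                    "sign_runs_lower": raw_runs.regions_lower_over_upper,
                }
                for p in range(len(rec_limits.mean)):
                    limit_rows.append(
                        {
                            "pc": pc,
                            "point_pct": p,
                            "mean": rec_limits.mean[p],
                            "upper": rec_limits.upper[p],
                            "lower": rec_limits.lower[p],
                        }
                    )
            pd.DataFrame(limit_rows).to_csv(
                out / f"limits_{key}.csv", index=False, float_format="%.17g"
            )
            with open(out / f"regions_{key}.json", "w") as fh:
                json.dump(regions, fh, sort_keys=True, default=_jsonify)
            if config.make_plots:
                from .plotting import plot_limit_curves

                plot_limit_curves(model, out / f"limits_{key}.png")
            pca_summary[key] = {
                "k_retained": model.n_retained_,
                "coverage_achieved": model.coverage_achieved_,
                "variance_fractions": [
                    float(v) for v in model.explained_variance_ratio_[:6]
                ],
            }
    manifest["stages"]["pca"] = pca_summary

    # -- manifest -------------------------------------------------------------
    for p in sorted(out.glob("*")):
        if p.is_file() and p.name != "manifest.json":
            manifest["outputs"][p.name] = _sha256(p)
    manifest["finished"] = _time.strftime("%Y-%m-%dT%H:%M:%S")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_jsonify)
    return manifest


def _condition_metrics(
    filtered: ForceRecording,
    events,
    cond: dict[str, StanceCurve],
) -> dict:
    """One metrics row: per-step VALR (averaged) plus the four peaks."""
    from .errors import NoImpactPeakError

    rec = filtered
    bw = rec.meta.body_mass * 9.8
    valrs = []
    for ev in events:
        seg = filtered.vertical[ev.strike_index : ev.toeoff_index] / bw
        t = np.arange(seg.size) / rec.sampling_rate
        try:
            valrs.append(valr_for_stance(np.maximum(seg, 0.0), t).valr)
        except NoImpactPeakError:
            # shoulder-type impact transient: step excluded from the average
            continue
    peaks = find_peaks(cond["vertical"], cond["ant_post"])
    return {
        "subject_id": rec.meta.subject_id,
        "sex": rec.meta.sex,
        "speed": rec.meta.speed,
        "n_steps": len(events),
        "n_valr_steps": len(valrs),
        "valr_bw_s": float(np.mean(valrs)) if valrs else np.nan,
        "first_peak_bw": peaks.first_peak.value,
        "first_peak_pct": peaks.first_peak.percent,
        "second_peak_bw": peaks.second_peak.value,
        "second_peak_pct": peaks.second_peak.percent,
        "braking_peak_bw": peaks.braking_peak.value,
        "propulsion_peak_bw": peaks.propulsion_peak.value,
        "contact_time_s": cond["vertical"].contact_time,
    }


def load_recordings(input_dir: str | Path) -> list[ForceRecording]:
    """Read a directory of trial CSVs described by its metadata.csv table."""
    input_dir = Path(input_dir)
    meta_path = input_dir / "metadata.csv"
    if not meta_path.exists():
        raise ConfigError(f"missing metadata table: {meta_path}")
    meta = pd.read_csv(meta_path, float_precision="round_trip")
    recordings = []
    for _, row in meta.iterrows():
        recordings.append(
            read_recording(
                input_dir / row["file"],
                SubjectMeta(
                    subject_id=str(row["subject_id"]),
                    sex=row["sex"],
                    body_mass=float(row["body_mass_kg"]),
                    speed=float(row["speed_mps"]),
                ),
            )
        )
    return recordings
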