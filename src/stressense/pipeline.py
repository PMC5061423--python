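"""End-to-end orchestration: simulate -> characterize -> correlate ->
timefreq -> classify -> report.

The pipeline is configuration-driven (YAML, schema-validated with
unknown keys rejected), deterministic under its seed, and caches each
stage by a content hash of that stage's configuration so reruns with
an unchanged config reuse existing outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from stressense import behavior, classify as cls, corrmap, timefreq
from stressense.behavior import LabelSpec
from stressense.characterize import characterization_frame, characterize_session
from stressense.series import ParameterSeries
from stressense.streams import align_streams, write_session
from stressense.synth import SimConfig, simulate_cohort

logger = logging.getLogger(__name__)

SHORT_SET = ("GSRsiginc", "Blinksiginc", "medianRRI", "alphaAsym")
LONG_SET = ("Blinkcount", "GSRSCL", "LFHF", "Meditation")

_SCHEMA = {
    "seed": int,
    "simulate": {
        "n_participants": int, "trials": int, "loops": int, "modality": str,
        "condition": str, "session_duration": (int, float), "n_events": int,
        "min_gap": (int, float), "vary_profiles": bool,
    },
    "correlate": {"set": str, "reference": str, "use_boxcox": bool},
    "timefreq": {"z_rule": str},
    "classify": {
        "grid": list, "methods": list, "feature_modes": list, "enabled": bool,
    },
}

_DEFAULTS = {
    "seed": 0,
    "simulate": {"n_participants": 3, "trials": 2, "loops": 1,
                 "modality": "autonomous", "condition": "wide",
                 "session_duration": 300.0, "n_events": 6, "min_gap": 15.0,
                 "vary_profiles": True},
    "correlate": {"set": "short", "reference": "lever", "use_boxcox": True},
    "timefreq": {"z_rule": "ge2"},
    "classify": {"grid": [{"source": "GSRsiginc", "interval_s": 2}],
                 "methods": ["LDA"], "feature_modes": ["all_channels"],
                 "enabled": True},
}


def _check_section(cfg: dict, schema: dict, path: str = "") -> None:
    for key, val in cfg.items():
        if key not in schema:
            raise ValueError(f"unknown config key '{path}{key}'")
        expected = schema[key]
        if isinstance(expected, dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key '{path}{key}' must be a mapping")
            _check_section(val, expected, f"{path}{key}.")
        elif not isinstance(val, expected):
            raise ValueError(
                f"config key '{path}{key}' has wrong type "
                f"{type(val).__name__} (expected {expected})"
            )


def _merge(defaults: dict, overrides: dict) -> dict:
    out = {}
    for k, v in defaults.items():
        if isinstance(v, dict):
            out[k] = _merge(v, overrides.get(k, {}))
        else:
            out[k] = overrides.get(k, v)
    return out


def validate_config(path_or_dict) -> dict:
    """Parse and schema-check a pipeline config; fill defaults.

    A missing seed gets the deterministic default (0) and is logged.
    Label grid entries are validated against the allowed
    (source, interval) pairs.
    """
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    else:
        raw = dict(path_or_dict)
    _check_section(raw, _SCHEMA)
    if "seed" not in raw:
        logger.info("no seed in config; using deterministic default 0")
    cfg = _merge(_DEFAULTS, raw)
    for entry in cfg["classify"]["grid"]:
        LabelSpec(entry["source"], entry["interval_s"])  # raises on bad pairs
    if cfg["correlate"]["set"] not in ("short", "long"):
        raise ValueError("correlate.set must be 'short' or 'long'")
    if cfg["timefreq"]["z_rule"] not in ("ge2", "lt2"):
        raise ValueError("timefreq.z_rule must be 'ge2' or 'lt2'")
    return cfg


def _stage_hash(cfg_section, seed: int) -> str:
    payload = json.dumps({"cfg": cfg_section, "seed": seed}, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _cached(stage_dir: Path, h: str) -> bool:
    marker = stage_dir / ".stage_hash"
    return marker.exists() and marker.read_text() == h and any(
        p.name != ".stage_hash" for p in stage_dir.iterdir()
    )


def _mark(stage_dir: Path, h: str) -> None:
    (stage_dir / ".stage_hash").write_text(h)


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run all stages in order; return the run report.

    Each stage writes CSV/JSON artifacts under ``out_dir/<stage>/``;
    the report lists every output file with its sha256 checksum, so two
    runs with the same config and seed produce identical reports.
    """
    cfg = validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = cfg["seed"]
    report: dict = {"seed": seed, "stages": {}, "files": {}, "warnings": []}

    # ---- simulate ------------------------------------------------------
    sim_dir = out / "simulate"
    sim_dir.mkdir(exist_ok=True)
    sim_cfg = SimConfig(seed=seed, **{
        k: cfg["simulate"][k] for k in
        ("n_participants", "trials", "loops", "modality", "condition",
         "n_events", "vary_profiles")
    }, session_duration=float(cfg["simulate"]["session_duration"]),
        min_gap=float(cfg["simulate"]["min_gap"]))
    sessions = []
    for raw in simulate_cohort(sim_cfg):
        aligned = align_streams(raw)
        aligned.schedule = getattr(raw, "schedule", None)
        aligned.profile = getattr(raw, "profile", None)
        sessions.append(aligned)
    h = _stage_hash(cfg["simulate"], seed)
    if not _cached(sim_dir, h):
        for s in sessions:
            write_session(s, sim_dir)
        _mark(sim_dir, h)
    report["stages"]["simulate"] = {"n_sessions": len(sessions), "hash": h}

    # ---- characterize --------------------------------------------------
    char_dir = out / "characterize"
    char_dir.mkdir(exist_ok=True)
    h = _stage_hash(cfg["simulate"], seed)
    all_series: dict[str, dict[str, ParameterSeries]] = {}
    for s in sessions:
        series = characterize_session(s)
        if "lever" in s.streams:
            series["lever"] = behavior.lever_preprocess(s.streams["lever"])
        if "joystick_y" in s.streams:
            series["JoystickR2"] = behavior.joystick_r2(s.streams["joystick_y"])
        all_series[s.meta.stem] = series
        if not _cached(char_dir, h):
            frame = characterization_frame(series, s.grid_rate)
            frame.to_csv(char_dir / f"{s.meta.stem}_characterization.csv",
                         index=False, float_format="%.9g")
    _mark(char_dir, h)
    report["stages"]["characterize"] = {"n_sessions": len(all_series), "hash": h}

    # ---- correlate -----------------------------------------------------
    corr_dir = out / "correlate"
    corr_dir.mkdir(exist_ok=True)
    which = SHORT_SET if cfg["correlate"]["set"] == "short" else LONG_SET
    reference = cfg["correlate"]["reference"]
    n_sig_ref = 0
    for stem, series in all_series.items():
        on_grid = _common_grid(series, which, reference)
        if on_grid is None:
            continue
        if cfg["correlate"]["use_boxcox"]:
            for name, s in list(on_grid.items()):
                v = s.dropna().values
                if v.size >= 20 and np.ptp(v) > 0:
                    _, p = corrmap.ks_normality(s)
                    if p < 0.05:
                        on_grid[name], _ = corrmap.boxcox_transform(s)
        cm = corrmap.spearman_map(on_grid, reference=reference if reference in on_grid else None)
        corrmap.render_map(cm, corr_dir / f"{stem}_map.json")
        if any(e.tier == "primary" for e in cm.edges):
            n_sig_ref += 1
    _mark(corr_dir, _stage_hash(cfg["correlate"], seed))
    report["stages"]["correlate"] = {"n_maps": len(all_series),
                                     "n_with_primary_edge": n_sig_ref}

    # ---- timefreq ------------------------------------------------------
    tf_dir = out / "timefreq"
    tf_dir.mkdir(exist_ok=True)
    datasets = []
    for s in sessions:
        rec: dict[str, dict[str, float]] = {}
        for ch, stream in s.eeg().items():
            bp = timefreq.eeg_bandpass(stream)
            spec = timefreq.spectrogram_01hz(bp)
            rec[ch] = {b: bs.variance for b, bs in timefreq.condense_bands(spec).items()}
        datasets.append((s.meta.condition, rec))
    by_cond: dict[str, int] = {}
    for c, _ in datasets:
        by_cond[c] = by_cond.get(c, 0) + 1
    if all(n >= 3 for n in by_cond.values()):
        table = timefreq.variance_count_table(datasets, z_rule=cfg["timefreq"]["z_rule"])
        table.to_csv(tf_dir / "variance_counts.csv")
        timefreq.hemisphere_pattern_summary(table).to_csv(tf_dir / "hemisphere_summary.csv")
        report["stages"]["timefreq"] = {"n_datasets": len(datasets)}
    else:
        report["stages"]["timefreq"] = {"skipped": "fewer than 3 datasets per condition"}
        report["warnings"].append("timefreq skipped: too few datasets")

    # ---- classify ------------------------------------------------------
    cls_dir = out / "classify"
    cls_dir.mkdir(exist_ok=True)
    grid = cfg["classify"]["grid"]
    if not cfg["classify"].get("enabled", True) or not grid:
        report["stages"]["classify"] = {"skipped": "empty classification grid"}
        report["warnings"].append("classification skipped: empty grid")
    else:
        records = []
        for s in sessions:
            series = all_series[s.meta.stem]
            pre = cls.eeg_preprocess_cls(s.eeg())
            for entry in grid:
                spec = LabelSpec(entry["source"], entry["interval_s"])
                src = "JoystickR2" if spec.source == "Joystick" else spec.source
                if src not in series:
                    continue
                p = series[src]
                if spec.source != "Meditation":
                    try:
                        p = behavior.normalize_series(p)
                    except ValueError:
                        continue
                try:
                    labels = behavior.build_labels(p, spec)
                    epochs = cls.epoch_by_labels(pre, labels)
                except ValueError:
                    continue
                for mode in cfg["classify"]["feature_modes"]:
                    X, y = cls.alpha_ratio_features(epochs, mode)
                    if np.unique(y).size < 2:
                        continue
                    for method in cfg["classify"]["methods"]:
                        res = cls.crossval_classify(X, y, method, seed=seed)
                        records.append({
                            "participant": s.meta.participant_id,
                            "source": spec.source, "interval_s": spec.interval_s,
                            "mode": mode, "method": method, "trial": s.meta.trial,
                            "loop": s.meta.loop, "accuracy": res.mean,
                        })
        if records:
            pd.DataFrame(records).to_csv(cls_dir / "cv_results.csv", index=False,
                                         float_format="%.6g")
            table = cls.build_accuracy_table(records)
            table.to_csv(cls_dir / "accuracy_table.csv", float_format="%.6g")
            report["stages"]["classify"] = {"n_results": len(records)}
        else:
            report["stages"]["classify"] = {"skipped": "no classifiable sessions"}

    # ---- report --------------------------------------------------------
    for p in sorted(out.rglob("*")):
        if p.is_file() and p.name not in (".stage_hash", "report.json"):
            report["files"][str(p.relative_to(out))] = _checksum(p)
    with open(out / "report.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def _common_grid(series: dict[str, ParameterSeries], which: tuple[str, ...],
                 reference: str) -> dict[str, ParameterSeries] | None:
    names = [n for n in which if n in series]
    if reference in series:
        names.append(reference)
    if len(names) < 2:
        return None
    frame = characterization_frame({n: series[n] for n in names})
    t = frame["t"].to_numpy()
    out = {}
    for n in names:
        col = n if n in frame.columns else None
        if col is None:  # auxiliary series (lever, JoystickR2) use hold projection
            s = series[n]
            idx = np.searchsorted(s.timestamps, t + 1e-12, side="right") - 1
            vals = np.full(t.size, np.nan)
            ok = idx >= 0
            vals[ok] = s.values[idx[ok]]
            out[n] = ParameterSeries(n, t, vals)
        else:
            out[n] = ParameterSeries(n, t, frame[col].to_numpy())
    return out
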