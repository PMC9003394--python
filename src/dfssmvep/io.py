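"""File formats, dataset manifests, and the end-to-end pipeline.

Trials travel as headered CSV (one column per channel, samples as rows)
with a JSON sidecar carrying the sampling rate and metadata; EDF recordings
are read through MNE.  A dataset manifest is a JSON file listing trial
files with subject/session/target metadata and the frequency plan.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .evaluation import confusion_and_indices, evaluate_windows
from .preprocessing import EEGTrial, bandpass_filter
from .simulate import SimulationConfig, simulate_dataset
from .stimulus import FrequencyPlan, assign_dual_frequencies

__all__ = [
    "read_trial", "write_trial", "write_dataset", "read_dataset",
    "load_manifest", "validate_manifest", "run_pipeline", "PipelineError",
]

logger = logging.getLogger(__name__)

MANIFEST_VERSION = 1
_META_KEYS = ("true_target", "subject", "session", "run")


def _sidecar_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".json")


def write_trial(trial: EEGTrial, path) -> Path:
    """Write a trial as CSV (header = channel labels) plus a JSON sidecar.

    Floats are written with 17 significant digits so a read round-trips
    bit-exactly.
    """
    path = Path(path)
    frame = pd.DataFrame(trial.data.T, columns=list(trial.channel_labels))
    frame.to_csv(path, index=False, float_format="%.17g")
    meta = {"fs": trial.fs, "onset": trial.onset, "units": "uV",
            "channel_labels": list(trial.channel_labels)}
    meta.update({k: getattr(trial, k) for k in _META_KEYS})
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _read_trial_csv(path: Path) -> EEGTrial:
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValueError(
            f"missing sidecar {sidecar.name}: the CSV format stores the "
            "sampling rate 'fs' in a JSON sidecar next to the trial file"
        )
    meta = json.loads(sidecar.read_text())
    if "fs" not in meta:
        raise ValueError(f"sidecar {sidecar.name} lacks required field 'fs'")
    frame = pd.read_csv(path, float_precision="round_trip")
    first = frame.columns[0].lower()
    if first in ("time", "t"):  # optional leading time column
        frame = frame.iloc[:, 1:]
    return EEGTrial(
        data=frame.to_numpy(dtype=float).T,
        fs=float(meta["fs"]),
        channel_labels=tuple(frame.columns),
        onset=float(meta.get("onset", 0.0)),
        **{k: meta.get(k) for k in _META_KEYS},
    )


def _read_trial_edf(path: Path) -> EEGTrial:
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("EDF support requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGTrial(
        data=raw.get_data() * 1e6,  # MNE loads volts; trials are in uV
        fs=float(raw.info["sfreq"]),
        channel_labels=tuple(raw.ch_names),
    )


def read_trial(path, fmt: str | None = None) -> EEGTrial:
    """Read an EEG trial from CSV (+sidecar) or EDF; format from extension."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = fmt or path.suffix.lstrip(".").lower()
    if fmt == "csv":
        return _read_trial_csv(path)
    if fmt == "edf":
        return _read_trial_edf(path)
    raise ValueError(f"unsupported trial format {fmt!r} (use 'csv' or 'edf')")


def write_dataset(dataset, outdir) -> Path:
    """Write all trials of a simulated dataset plus a manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records = []
    for idx, trial in enumerate(dataset.trials):
        name = f"trial_{idx:04d}.csv"
        write_trial(trial, outdir / name)
        records.append({
            "path": name, "subject": trial.subject, "session": trial.session,
            "run": trial.run, "target": trial.true_target,
            "pair": list(dataset.plan.pairs[trial.true_target]),
            "fs": trial.fs, "duration": trial.duration,
        })
    manifest = {"format_version": MANIFEST_VERSION,
                "plan": dataset.plan.to_dict(), "trials": records}
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return path


def validate_manifest(manifest: dict, base_dir: Path) -> FrequencyPlan:
    """Structural validation; returns the plan. Raises on any defect."""
    if manifest.get("format_version") != MANIFEST_VERSION:
        raise ValueError("unsupported or missing manifest format_version")
    if "plan" not in manifest or "trials" not in manifest:
        raise ValueError("manifest must contain 'plan' and 'trials'")
    plan = FrequencyPlan.from_dict(manifest["plan"])
    for rec in manifest["trials"]:
        target = rec.get("target")
        if target is None or not 0 <= int(target) < plan.n_targets:
            raise ValueError(
                f"trial {rec.get('path')}: target index {target!r} outside "
                f"plan (0..{plan.n_targets - 1})"
            )
        if not (base_dir / rec["path"]).exists():
            raise ValueError(f"trial file missing: {rec['path']}")
    return plan


def load_manifest(path) -> tuple[dict, FrequencyPlan]:
    path = Path(path)
    manifest = json.loads(path.read_text())
    plan = validate_manifest(manifest, path.parent)
    return manifest, plan


def read_dataset(manifest_path) -> tuple[list, FrequencyPlan]:
    """Load every trial referenced by a manifest."""
    manifest_path = Path(manifest_path)
    manifest, plan = load_manifest(manifest_path)
    trials = []
    for rec in manifest["trials"]:
        trial = read_trial(manifest_path.parent / rec["path"])
        trial = trial.replace(true_target=int(rec["target"]),
                              subject=rec.get("subject"),
                              session=rec.get("session"), run=rec.get("run"))
        trials.append(trial)
    return trials, plan


class PipelineError(RuntimeError):
    """Raised when a pipeline stage fails; message names the stage."""


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(f"stage '{name}' failed: {exc}") from exc
    return wrap


def _library_versions() -> dict:
    import scipy
    import sklearn
    return {"dfssmvep": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__,
            "scikit-learn": sklearn.__version__}


def run_pipeline(config, output_dir=None) -> dict:
    """Filter -> epoch -> decode -> evaluate, driven by a config mapping.

    ``config`` is a dict or a path to a YAML file with keys:

    - ``plan``: {"base_frequencies": [...]} or a path to a plan JSON
    - ``simulation``: SimulationConfig fields plus n_subjects/n_sessions/
      n_trials_per_target, or ``manifest``: path to a dataset manifest
    - ``method``: "cca" | "bcca"; ``nh``: harmonic count
    - ``windows``: list of epoch lengths in s (default [trial length])
    - ``bandpass``: {"low": .., "high": ..} or false to skip
    - ``output_dir``: where predictions.csv / report.json / run.log go

    Writes a deterministic report (identical config + seed => identical
    JSON bytes) and a log with the config hash, seed, library versions and
    wall-clock time.  Returns the report dict.
    """
    t_start = time.time()
    if not isinstance(config, dict):
        config = yaml.safe_load(Path(config).read_text())
    if not isinstance(config, dict):
        raise PipelineError("stage 'config' failed: config must be a mapping")
    config_hash = hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]
    outdir = Path(output_dir or config.get("output_dir", "."))
    outdir.mkdir(parents=True, exist_ok=True)

    # -- plan ---------------------------------------------------------------
    plan_cfg = config.get("plan")
    if plan_cfg is None:
        raise PipelineError("stage 'plan' failed: no plan in config")
    if isinstance(plan_cfg, str):
        if not Path(plan_cfg).exists():
            raise PipelineError(f"stage 'plan' failed: plan file {plan_cfg} missing")
        plan_cfg = json.loads(Path(plan_cfg).read_text())
    if "pairs" in plan_cfg:
        plan = _stage("plan")(FrequencyPlan.from_dict, plan_cfg)
    else:
        plan = _stage("plan")(assign_dual_frequencies, plan_cfg["base_frequencies"])

    # -- input trials -------------------------------------------------------
    seed = None
    if "simulation" in config:
        sim = dict(config["simulation"])
        shape = {k: sim.pop(k) for k in
                 ("n_subjects", "n_sessions", "n_trials_per_target") if k in sim}
        sim_config = _stage("simulate")(SimulationConfig, **sim)
        seed = sim_config.seed
        dataset = _stage("simulate")(simulate_dataset, sim_config, plan, **shape)
        trials = list(dataset.trials)
    elif "manifest" in config:
        trials, manifest_plan = _stage("load")(read_dataset, config["manifest"])
        plan = manifest_plan
    else:
        raise PipelineError("stage 'input' failed: need 'simulation' or 'manifest'")

    # -- preprocessing ------------------------------------------------------
    bp = config.get("bandpass", {})
    if bp is not False:
        bp = bp or {}
        trials = [_stage("filter")(bandpass_filter, t,
                                   bp.get("low", 2.0), bp.get("high", 40.0))
                  for t in trials]

    # -- decode + evaluate --------------------------------------------------
    method = config.get("method", "bcca")
    nh = int(config.get("nh", 2))
    windows = config.get("windows") or [min(t.duration for t in trials)]
    table = _stage("evaluate")(evaluate_windows, trials, plan, method, windows, nh)
    if table.empty:
        raise PipelineError("stage 'evaluate' failed: no usable window")

    full = float(table["window"].iloc[-1])
    from .decoding import decode_trials  # local import avoids cycle at import time
    from .preprocessing import epoch_window
    epochs = [epoch_window(t, 0.0, full) for t in trials]
    results = _stage("decode")(decode_trials, epochs, plan, method, nh)
    preds = pd.DataFrame({
        "subject": [t.subject for t in trials],
        "session": [t.session for t in trials],
        "run": [t.run for t in trials],
        "true_target": [t.true_target + 1 for t in trials],
        "predicted_target": [r.predicted + 1 for r in results],
        **{f"score_{i + 1}": [r.scores[i] for r in results]
           for i in range(plan.n_targets)},
    })
    preds.to_csv(outdir / "predictions.csv", index=False, float_format="%.10g")
    summary = confusion_and_indices(preds["true_target"], preds["predicted_target"],
                                    plan.n_targets)

    report = {
        "config_hash": config_hash,
        "seed": seed,
        "method": method,
        "nh": nh,
        "n_trials": len(trials),
        "plan": plan.to_dict(),
        "windows": table.to_dict(orient="records"),
        "overall_accuracy": summary.overall_accuracy,
        "per_class": {str(k): {c: (None if pd.isna(v) else float(v))
                               for c, v in row.items()}
                      for k, row in summary.per_class.iterrows()},
        "versions": _library_versions(),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    elapsed = time.time() - t_start
    log_lines = [
        f"config_hash={config_hash}", f"seed={seed}",
        f"versions={json.dumps(_library_versions(), sort_keys=True)}",
        f"wall_clock_s={elapsed:.2f}",
    ]
    (outdir / "run.log").write_text("\n".join(log_lines) + "\n")
    logger.info("pipeline done in %.2f s (accuracy %.3f)", elapsed,
                summary.overall_accuracy)
    return report
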