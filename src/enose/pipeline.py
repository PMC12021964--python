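"""End-to-end training pipeline and streaming inference.

``run_training_pipeline`` wires the stages together — load or simulate
sessions, preprocess, build indicator tables, optionally SMOTE-balance,
train and cross-validate the model suite — and writes every artifact plus a
manifest recording each parameter, seed and row count, so a run is
reproducible bit-for-bit from its manifest.

``run_inference_stream`` replays frames through the sliding-window smoother:
no prediction is possible until 51 frames are buffered (the smoother's
window), after which one prediction is emitted per incoming frame.
"""

from __future__ import annotations

import json
import logging
import shutil
from collections import deque
from pathlib import Path
from typing import Iterable, NamedTuple

import joblib
import numpy as np
import pandas as pd
import yaml

from . import frames as frames_io
from .augment import SmoteConfig, smote_augment
from .classify import (MODEL_NAMES, ModelSpec, build_indicator_table,
                       evaluate_cv, make_classifier)
from .frames import FEATURE_COLUMNS, OdorSignal, SensorFrame
from .indicators import TABLE_ORDER, build_feature_table, feature_matrix
from .preprocess import SavitzkyGolaySmoother, SmootherConfig, preprocess_session
from .simulate import (default_noise_schedule, default_signatures,
                       simulate_dataset)

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "data": {"simulate": {"n_campaigns": 5, "preset": "default"}},
    "preprocess": {
        "smoother": {"window": 51, "degree": 3},
        "drift": {"fit_window": 100},
        "normalize": True,
    },
    "granularity": "session",
    "models": list(MODEL_NAMES),
    "variant": "default",
    "folds": 5,
    "smote": {"enabled": False, "k_neighbors": 4, "target_ratio": 1.0,
              "mode": "fold"},
}


class PipelineConfigError(ValueError):
    """Raised before any computation when the config is invalid."""


def _validate_config(config: dict) -> dict:
    cfg = {**DEFAULT_CONFIG, **config}
    for key in ("smote", "preprocess", "data"):
        if key in config:
            cfg[key] = {**DEFAULT_CONFIG[key], **config[key]}
    if "indicators" not in cfg or not cfg["indicators"]:
        raise PipelineConfigError(
            "config must name a non-empty 'indicators' list"
        )
    bad = [m for m in cfg["models"] if m not in MODEL_NAMES]
    if bad:
        raise PipelineConfigError(
            f"unknown model(s) {bad}; valid: {list(MODEL_NAMES)}"
        )
    if cfg["granularity"] not in ("session", "timepoint"):
        raise PipelineConfigError("granularity must be session or timepoint")
    if not ({"simulate", "sessions_csv"} & set(cfg["data"])):
        raise PipelineConfigError(
            "data must give either 'simulate' parameters or a 'sessions_csv'"
        )
    return cfg


def _load_sessions(data_cfg: dict, seed: int) -> list:
    if "sessions_csv" in data_cfg:
        return frames_io.read_sessions(data_cfg["sessions_csv"])
    sim = data_cfg["simulate"]
    n_campaigns = sim.get("n_campaigns", 5)
    return simulate_dataset(
        default_signatures(),
        n_campaigns=n_campaigns,
        noise_schedule=default_noise_schedule(n_campaigns),
        seed=seed,
    )


def run_training_pipeline(config, out_dir) -> dict:
    """Execute the full training pipeline; return the artifact index.

    ``config`` is a dict or a YAML file path; ``out_dir`` receives feature
    tables, the accuracy table, trained models and ``manifest.json``.  On
    failure, partially written artifacts are removed.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = _validate_config(config or {})
    seed = int(cfg["seed"])

    out_dir = Path(out_dir)
    created_dir = not out_dir.exists()
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        return _run_stages(cfg, seed, out_dir, written)
    except Exception:
        if created_dir:
            shutil.rmtree(out_dir, ignore_errors=True)
        else:
            for p in written:
                p.unlink(missing_ok=True)
        raise


def _run_stages(cfg: dict, seed: int, out_dir: Path, written: list) -> dict:
    sessions = _load_sessions(cfg["data"], seed)
    pp = cfg["preprocess"]
    sm_cfg = SmootherConfig(pp["smoother"]["window"], pp["smoother"]["degree"])
    processed = [
        preprocess_session(s, sm_cfg, pp["drift"]["fit_window"],
                           normalize=pp["normalize"])
        for s in sessions
    ]

    specs = [ModelSpec(m, cfg["variant"]) for m in cfg["models"]]
    smote_cfg = None
    if cfg["smote"]["enabled"]:
        smote_cfg = SmoteConfig(
            cfg["smote"]["k_neighbors"], cfg["smote"]["target_ratio"], seed
        )

    manifest: dict = {
        "config": cfg,
        "seed": seed,
        "n_sessions": len(sessions),
        "session_lengths": sorted({s.n_samples for s in sessions}),
        "labels": sorted({s.label for s in sessions}),
        "tables": {},
        "smote_mode": cfg["smote"]["mode"] if smote_cfg else None,
    }

    artifacts = {"out_dir": str(out_dir)}
    models_dir = out_dir / "models"
    models_dir.mkdir(exist_ok=True)

    if cfg["granularity"] == "session":
        acc = build_indicator_table(
            processed, cfg["indicators"], specs, folds=cfg["folds"],
            seed=seed, smote=smote_cfg,
        )
        for ind in cfg["indicators"]:
            table = build_feature_table(processed, ind, "session")
            p = out_dir / f"table_{ind}.csv"
            table.to_csv(p, index=False, float_format="%.9g")
            written.append(p)
            manifest["tables"][ind] = len(table)
        # fitted models on the first-listed indicator's full table
        fit_table = build_feature_table(
            processed, cfg["indicators"][0], "session"
        )
    else:
        table = build_feature_table(processed, granularity="timepoint")
        if smote_cfg is not None:
            table = smote_augment(table, cfg=smote_cfg)
        p = out_dir / "table_raw.csv"
        table.to_csv(p, index=False, float_format="%.9g")
        written.append(p)
        manifest["tables"]["raw"] = len(table)
        manifest["n_synthetic_rows"] = int(
            (table["provenance"] == "synthetic").sum()
        )
        acc = pd.DataFrame({
            "raw": {
                spec.name: evaluate_cv(
                    table, spec, folds=cfg["folds"], seed=seed,
                    smote_mode=cfg["smote"]["mode"],
                )
                for spec in specs
            }
        })
        fit_table = table

    acc_path = out_dir / "accuracy.csv"
    acc.to_csv(acc_path, float_format="%.6f")
    written.append(acc_path)
    txt_path = out_dir / "accuracy.txt"
    txt_path.write_text(acc.round(3).to_string() + "\n")
    written.append(txt_path)
    artifacts["accuracy"] = acc

    for spec in specs:
        est = make_classifier(spec, seed=seed)
        est.fit(feature_matrix(fit_table), fit_table["label"].to_numpy())
        mp = models_dir / f"{spec.name}.joblib"
        joblib.dump(est, mp)
        written.append(mp)
    manifest["fitted_on"] = fit_table.attrs.get("indicator", "raw")

    man_path = out_dir / "manifest.json"
    man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    written.append(man_path)
    artifacts["manifest"] = manifest
    logger.info("training pipeline complete: %s", out_dir)
    return artifacts


# ---------------------------------------------------------------------------
# streaming inference

class StreamPrediction(NamedTuple):
    t_index: int
    label: object
    proba: np.ndarray | None


def _frame_features(frame) -> np.ndarray | None:
    """Coerce one incoming frame to a 15-vector; None if malformed."""
    if isinstance(frame, SensorFrame):
        try:
            return frames_io.map_sensors_to_features(frame)
        except ValueError:
            return None
    arr = np.asarray(frame, dtype=float)
    if arr.shape != (len(FEATURE_COLUMNS),) or not np.isfinite(arr).all():
        return None
    return arr


def smooth_window_tail(window_matrix: np.ndarray,
                       cfg: SmootherConfig = SmootherConfig()) -> np.ndarray:
    """Smoothed value at the newest sample of a full buffer (batch oracle)."""
    sm = SavitzkyGolaySmoother(cfg.window_length, cfg.poly_degree)
    return sm.fit(window_matrix).transform(window_matrix)[-1]


def run_inference_stream(
    model,
    frame_source: Iterable,
    window: int = 51,
    smoother: SmootherConfig | None = None,
):
    """Yield one prediction per frame once the warm-up buffer is full.

    ``frame_source`` yields :class:`SensorFrame` objects or 15-vectors in
    time order.  The first ``window - 1`` frames only fill the buffer
    (warm-up); from frame ``window`` onward the Savitzky-Golay smoother runs
    over the sliding buffer and the model classifies the newest smoothed
    sample.  Malformed frames are logged and skipped without disturbing the
    buffer.  Replaying a session therefore yields ``T - window + 1``
    predictions, identical to batch recomputation over the same windows.
    """
    cfg = smoother or SmootherConfig(window_length=window)
    if cfg.window_length != window:
        raise ValueError("smoother window must equal the buffer window")
    buffer: deque = deque(maxlen=window)
    has_proba = hasattr(model, "predict_proba")
    for t, frame in enumerate(frame_source):
        feats = _frame_features(frame)
        if feats is None:
            logger.warning("frame %d malformed; skipped", t)
            continue
        buffer.append(feats)
        if len(buffer) < window:
            logger.debug("warm-up: %d/%d frames buffered", len(buffer), window)
            continue
        tail = smooth_window_tail(np.asarray(buffer), cfg)[None, :]
        label = model.predict(tail)[0]
        proba = model.predict_proba(tail)[0] if has_proba else None
        yield StreamPrediction(t, label, proba)
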