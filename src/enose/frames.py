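"""Sensor frames, the channel-to-odor-feature mapping, and session CSV I/O.

The e-nose device reads a 66-length vector every ~1.8 s: 64 chemiresistor
channels (4 arrays of 16 single-walled carbon-nanotube sensors) plus
temperature and humidity.  Like-behaving channels are grouped into 15 odor
features f1..f15 by averaging; REF positions are reference channels excluded
from every feature.  A measurement session is a three-phase recording
(air / odor exposure / air) stored here as an :class:`OdorSignal`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

N_CHANNELS = 64
N_ARRAYS = 4
SENSORS_PER_ARRAY = 16
N_FEATURES = 15

#: Default sample period of the device, seconds per frame.
SAMPLE_PERIOD_S = 1.8

FEATURE_COLUMNS = [f"f{i}" for i in range(1, N_FEATURES + 1)]
RAW_COLUMNS = [
    f"a{a}_s{s:02d}"
    for a in range(1, N_ARRAYS + 1)
    for s in range(1, SENSORS_PER_ARRAY + 1)
]

# Manufacturer layout of the 4x16 sensor grid.  Within each array the
# positions S1..S16 carry either a feature id or REF (reference channel,
# never averaged into a feature).  Array 2 has more REF positions by
# construction.
_DEFAULT_LAYOUT = {
    1: ["REF", "REF", "f11", "f11", "f11", "f3", "f3", "f3",
        "f2", "f2", "f2", "f1", "f1", "f1", "REF", "REF"],
    2: ["REF", "REF", "REF", "REF", "REF", "f9", "f9", "f9",
        "f6", "f6", "f6", "f5", "f5", "f5", "REF", "REF"],
    3: ["REF", "REF", "f14", "f14", "f14", "f10", "f10", "f10",
        "f7", "f7", "f7", "f4", "f4", "f4", "REF", "REF"],
    4: ["REF", "REF", "f15", "f15", "f15", "f13", "f13", "f13",
        "f12", "f12", "f12", "f8", "f8", "f8", "REF", "REF"],
}


class MappingError(ValueError):
    """Raised when a FeatureMapping does not cover f1..f15 consistently."""


@dataclass(frozen=True)
class SensorFrame:
    """One 1.8 s reading: 64 resistances plus temperature and humidity.

    Resistances are stored array-major: array 1 S1..S16, then array 2, 3, 4.
    """

    resistances: np.ndarray
    temperature: float
    humidity: float
    timestamp_index: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.resistances, dtype=float)
        if r.shape != (N_CHANNELS,):
            raise ValueError(
                f"expected {N_CHANNELS} resistance values, got shape {r.shape}"
            )
        object.__setattr__(self, "resistances", r)
        if self.timestamp_index < 0:
            raise ValueError("timestamp_index must be non-negative")


@dataclass(frozen=True)
class FeatureMapping:
    """Assignment of the 64 sensor positions to REF or an odor feature.

    ``assignments`` is array-major (array 1 S1..S16, ..., array 4 S16); each
    entry is ``"REF"`` or one of ``"f1".."f15"``.
    """

    assignments: tuple = field(
        default_factory=lambda: tuple(
            _DEFAULT_LAYOUT[a][s] for a in range(1, 5) for s in range(16)
        )
    )

    def __post_init__(self) -> None:
        if len(self.assignments) != N_CHANNELS:
            raise MappingError(
                f"mapping must assign all {N_CHANNELS} positions, "
                f"got {len(self.assignments)}"
            )
        feats = {a for a in self.assignments if a != "REF"}
        expected = set(FEATURE_COLUMNS)
        if feats != expected:
            missing = sorted(expected - feats)
            extra = sorted(feats - expected)
            raise MappingError(
                f"mapping must cover exactly f1..f15; missing={missing} "
                f"unknown={extra}"
            )

    def members(self, feature: str) -> np.ndarray:
        """Flat channel indices contributing to ``feature``."""
        return np.flatnonzero(np.asarray(self.assignments) == feature)

    @property
    def ref_positions(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.assignments) == "REF")

    def to_dict(self) -> dict:
        return {
            f"array{a + 1}": list(self.assignments[a * 16:(a + 1) * 16])
            for a in range(N_ARRAYS)
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureMapping":
        flat = []
        for a in range(1, N_ARRAYS + 1):
            flat.extend(d[f"array{a}"])
        return cls(tuple(flat))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "FeatureMapping":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class OdorSignal:
    """A full measurement session: a T x 15 odor-feature matrix plus label.

    ``phase_bounds = (cut1, cut2)`` splits ``[0, T)`` into phase A
    (pre-exposure air), phase B (odor exposure) and phase C (post-exposure
    air).  The default protocol is T=300 with cuts at 100 and 200.
    """

    values: np.ndarray
    label: str
    phase_bounds: tuple = (100, 200)
    sample_period_s: float = SAMPLE_PERIOD_S
    # Filled by preprocessing: per-column baseline drift fits and, when the
    # final stage is normalization, the pre-normalization corrected matrix
    # (indicators with a physical scale are computed from the latter).
    drift_models: list | None = None
    corrected_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[1] != N_FEATURES:
            raise ValueError(
                f"session values must be (T, {N_FEATURES}), got {v.shape}"
            )
        self.values = v
        c1, c2 = self.phase_bounds
        if not (0 < c1 < c2 < v.shape[0]):
            raise ValueError(
                f"phase bounds must satisfy 0 < {c1} < {c2} < T={v.shape[0]}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sample_period_s

    def phase_slices(self) -> dict:
        c1, c2 = self.phase_bounds
        return {
            "A": slice(0, c1),
            "B": slice(c1, c2),
            "C": slice(c2, self.n_samples),
        }

    def phase_tags(self) -> np.ndarray:
        """Per-sample phase letter, shape (T,)."""
        tags = np.empty(self.n_samples, dtype="<U1")
        for name, sl in self.phase_slices().items():
            tags[sl] = name
        return tags

    def with_values(self, values: np.ndarray, **extra) -> "OdorSignal":
        return replace(self, values=np.asarray(values, dtype=float), **extra)


def map_sensors_to_features(
    frame: SensorFrame, mapping: FeatureMapping | None = None
) -> np.ndarray:
    """Collapse the 64 channels of one frame into the 15 odor features.

    Each feature is the arithmetic mean of its member channels; REF channels
    never contribute.  Raises on non-finite member values, naming the channel.
    """
    mapping = mapping or FeatureMapping()
    out = np.empty(N_FEATURES)
    for j, feat in enumerate(FEATURE_COLUMNS):
        idx = mapping.members(feat)
        vals = frame.resistances[idx]
        bad = ~np.isfinite(vals)
        if bad.any():
            ch = int(idx[np.flatnonzero(bad)[0]])
            raise ValueError(
                f"non-finite resistance in channel {RAW_COLUMNS[ch]} "
                f"(feature {feat})"
            )
        out[j] = vals.mean()
    return out


def _sessions_to_frame(signals: list) -> pd.DataFrame:
    rows = []
    for sid, sig in enumerate(signals):
        tags = sig.phase_tags()
        for t in range(sig.n_samples):
            row = {
                "session_id": sid,
                "label": sig.label,
                "t_index": t,
                "phase": tags[t],
            }
            row.update(dict(zip(FEATURE_COLUMNS, sig.values[t])))
            rows.append(row)
    return pd.DataFrame(rows)


def write_sessions(signals: list, path) -> str:
    """Write sessions as a long-format CSV.

    Columns: ``session_id, label, t_index, phase, f1..f15``; one data row per
    time point, row order = time order within each session.  Values are
    written with 9 significant digits.
    """
    if not signals:
        raise ValueError("no sessions to write")
    df = _sessions_to_frame(signals)
    df.to_csv(path, index=False, float_format="%.9g")
    return str(path)


def read_sessions(path, mapping: FeatureMapping | None = None) -> list:
    """Read sessions from CSV (long feature format or raw 64-channel format).

    A raw file (columns ``a1_s01..a4_s16``) is passed through
    :func:`map_sensors_to_features` row by row.  Phase bounds are recovered
    from the ``phase`` column when present, else default to thirds.
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty session file", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: empty session file", stacklevel=2)
        return []
    if "label" not in df.columns:
        raise ValueError(f"{path}: no 'label' column in header")

    is_raw = set(RAW_COLUMNS).issubset(df.columns)
    if not is_raw and not set(FEATURE_COLUMNS).issubset(df.columns):
        raise ValueError(
            f"{path}: header declares neither the 64 raw channel columns "
            f"nor the 15 feature columns"
        )

    if "session_id" not in df.columns:
        df = df.assign(session_id=0)

    signals = []
    for sid, grp in df.groupby("session_id", sort=True):
        grp = grp.sort_values("t_index") if "t_index" in grp.columns else grp
        labels = grp["label"].unique()
        if len(labels) != 1:
            raise ValueError(
                f"{path}: session {sid} carries multiple labels {list(labels)}"
            )
        if is_raw:
            mat = np.empty((len(grp), N_FEATURES))
            temps = grp.get("temp_c", pd.Series(np.nan, index=grp.index))
            hums = grp.get("rh_pct", pd.Series(np.nan, index=grp.index))
            for i, (ridx, row) in enumerate(grp.iterrows()):
                raw = row[RAW_COLUMNS].to_numpy(dtype=float)
                if raw.shape != (N_CHANNELS,) or not np.isfinite(raw).all():
                    raise ValueError(
                        f"{path}: malformed raw row at line {ridx + 2}"
                    )
                frame = SensorFrame(raw, float(temps.iloc[i]),
                                    float(hums.iloc[i]), i)
                mat[i] = map_sensors_to_features(frame, mapping)
        else:
            mat = grp[FEATURE_COLUMNS].to_numpy(dtype=float)
        T = mat.shape[0]
        if "phase" in grp.columns:
            ph = grp["phase"].to_numpy()
            c1 = int(np.searchsorted(ph != "A", True))
            c2 = int(T - np.searchsorted(ph[::-1] != "C", True))
        else:
            c1, c2 = T // 3, 2 * T // 3
        signals.append(
            OdorSignal(mat, label=str(labels[0]), phase_bounds=(c1, c2))
        )
    logger.info("read %d session(s) from %s", len(signals), path)
    return signals
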