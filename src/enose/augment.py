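"""SMOTE oversampling of the minority (exposure-phase) rows.

The three-phase measurement protocol yields twice as many air-phase samples
as exposure samples, so the timepoint dataset is imbalanced by design.
SMOTE synthesises new minority rows by interpolating between a minority row
``x`` and one of its k nearest minority neighbours ``x_nn``:

    x_new = x + u * (x_nn - x),   u ~ Uniform[0, 1]

Synthesis runs per substance within the minority selection so that the
per-class synthetic counts balance by construction (pooled-minority SMOTE
cannot guarantee an equal per-substance split).  Neighbour ties are broken
by row index, making the augmentation fully deterministic under a seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .indicators import FEATURE_COLUMNS, feature_matrix


@dataclass(frozen=True)
class SmoteConfig:
    k_neighbors: int = 4
    target_ratio: float = 1.0  # +100% synthetic minority rows by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.target_ratio <= 0:
            raise ValueError("target_ratio must be positive")


class SmoteAugmenter:
    """Per-substance SMOTE with deterministic neighbour tie-breaking.

    ``fit_resample(table)`` appends ``ceil(target_ratio * n)`` synthetic
    rows for each substance with ``n`` minority rows, marked
    ``provenance="synthetic"``.  Original rows are never modified.
    """

    def __init__(self, k_neighbors: int = 4, target_ratio: float = 1.0,
                 seed: int = 0):
        self.k_neighbors = k_neighbors
        self.target_ratio = target_ratio
        self.seed = seed

    def fit_resample(self, table: pd.DataFrame,
                     minority_mask=None) -> pd.DataFrame:
        cfg = SmoteConfig(self.k_neighbors, self.target_ratio, self.seed)
        return smote_augment(table, minority_mask, cfg)


def _minority_mask(table: pd.DataFrame, minority_selector) -> np.ndarray:
    if minority_selector is None:
        if "phase" in table.columns:
            return (table["phase"] == "B").to_numpy()
        return np.ones(len(table), dtype=bool)  # whole table is minority pool
    if callable(minority_selector):
        return np.asarray(minority_selector(table), dtype=bool)
    return np.asarray(minority_selector, dtype=bool)


def smote_augment(
    table: pd.DataFrame,
    minority_selector=None,
    cfg: SmoteConfig = SmoteConfig(),
) -> pd.DataFrame:
    """Append synthetic minority rows to a feature table.

    ``minority_selector`` picks the minority rows: a boolean mask, a callable
    ``table -> mask``, or ``None`` (default: exposure-phase rows when a
    ``phase`` column exists, else every row).  Within the minority pool,
    synthesis runs independently per ``label``.
    """
    mask = _minority_mask(table, minority_selector)
    if mask.shape[0] != len(table):
        raise ValueError("minority mask length does not match table")
    minority = table.loc[mask]
    if minority.empty:
        raise ValueError("minority selection is empty")

    rng = np.random.default_rng(cfg.seed)
    synth_frames = []
    for label in sorted(minority["label"].unique()):
        cls = minority.loc[minority["label"] == label]
        X = feature_matrix(cls)
        n = X.shape[0]
        if n < cfg.k_neighbors + 1:
            raise ValueError(
                f"class {label!r} has {n} minority rows; SMOTE with "
                f"k={cfg.k_neighbors} needs at least {cfg.k_neighbors + 1}"
            )
        # k nearest within the class, self excluded; stable argsort breaks
        # distance ties by row index
        D = cdist(X, X)
        np.fill_diagonal(D, np.inf)
        nn = np.argsort(D, axis=1, kind="stable")[:, : cfg.k_neighbors]

        n_synth = ceil(cfg.target_ratio * n)
        base_idx = rng.integers(0, n, size=n_synth)
        nn_choice = rng.integers(0, cfg.k_neighbors, size=n_synth)
        u = rng.uniform(0.0, 1.0, size=n_synth)
        base = X[base_idx]
        neigh = X[nn[base_idx, nn_choice]]
        new_X = base + u[:, None] * (neigh - base)

        proto = cls.iloc[base_idx].copy().reset_index(drop=True)
        proto[FEATURE_COLUMNS] = new_X
        proto["provenance"] = "synthetic"
        synth_frames.append(proto)

    out = pd.concat([table, *synth_frames], ignore_index=True)
    out.attrs.update(table.attrs)
    return out
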