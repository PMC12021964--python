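"""Phase-aware statistical indicators and classifier feature tables.

For each odor-feature column of a preprocessed session, a small set of
scalar statistics summarises the transient response to the stimulus:

* ``R``   — maximum of the exposure phase (phase B),
* ``R0``  — mean of the pre-exposure air phase (phase A),
* ``R10, R25, R50, R75`` — means over the leading 10/25/50/75 % of the
  exposure phase (cheaper to acquire: only that fraction of phase B is
  needed before classification),
* ``Ind1 = R - R0`` — absolute response amplitude,
* ``Ind2 = (R - R0) / R0`` — amplitude relative to baseline,
* ``Ind3`` — ``Ind2`` rescaled by the root-sum-square of the per-sample
  baseline-to-signal residuals ``(R0_i - R_i)/R0`` over the whole session
  (N samples), where ``R0_i`` is the fitted drift-line prediction and
  ``R_i`` the drift-corrected sample.

Each indicator evaluated per odor feature yields a fixed-width-15 vector —
the classifier input.  :func:`build_feature_table` assembles these vectors
(one row per session, "session" granularity) or the raw normalized samples
(one row per time point, "timepoint" granularity) into a labelled table.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import numpy as np
import pandas as pd

from .frames import FEATURE_COLUMNS, N_FEATURES, OdorSignal
from .preprocess import DriftModel

PHASE_STATS = ("R", "R0", "R10", "R25", "R50", "R75")
INDICATOR_NAMES = PHASE_STATS[2:] + ("R", "R0", "Ind1", "Ind2", "Ind3")
#: Column order of accuracy tables: partial-exposure means first (they need
#: the smallest latency budget), then the full-session statistics.
TABLE_ORDER = ("R10", "R25", "R50", "R75", "R", "Ind1", "Ind2", "Ind3")


@dataclass(frozen=True)
class IndicatorSet:
    """All scalar statistics of one odor-feature column of one session."""

    R: float
    R0: float
    R10: float
    R25: float
    R50: float
    R75: float
    Ind1: float
    Ind2: float
    Ind3: float

    def __getitem__(self, name: str) -> float:
        return getattr(self, name)


def compute_phase_statistics(column, phase_bounds) -> dict:
    """R, R0 and the partial-exposure means of one column.

    ``Rq`` is the mean of the exposure-phase prefix spanning the first
    ``q`` % of phase B (``ceil(q/100 * |B|)`` samples) — a prefix mean, not
    a point value, so a single noisy sample cannot dominate.
    """
    col = np.asarray(column, dtype=float)
    c1, c2 = phase_bounds
    if c1 <= 0:
        raise ValueError("phase A is empty")
    if c2 <= c1:
        raise ValueError("phase B (exposure) is empty")
    if c2 >= col.shape[0]:
        raise ValueError("phase C is empty")
    expo = col[c1:c2]
    stats = {"R": float(expo.max()), "R0": float(col[:c1].mean())}
    for q in (10, 25, 50, 75):
        k = ceil(q / 100 * expo.shape[0])
        stats[f"R{q}"] = float(expo[:k].mean())
    return stats


def compute_indicators(
    column,
    phase_bounds,
    drift: DriftModel,
    n_samples: int | None = None,
) -> IndicatorSet:
    """Full :class:`IndicatorSet` for one drift-corrected column.

    ``column`` must be the drift-corrected, pre-normalization signal so that
    ``R0`` keeps its physical scale and the Ind3 residuals compare the
    signal against the extrapolated drift line in the same units.  The Ind3
    sum runs over ``n_samples`` terms (default: the whole session, N=300
    under the standard protocol).
    """
    col = np.asarray(column, dtype=float)
    stats = compute_phase_statistics(col, phase_bounds)
    R, R0 = stats["R"], stats["R0"]
    ind1 = R - R0
    if R0 == 0:
        raise ValueError("baseline mean is zero; relative indicators undefined")
    ind2 = ind1 / R0
    if ind2 == 0.0:
        ind3 = 0.0  # zero response: zero numerator short-circuits 0/0
    else:
        N = col.shape[0] if n_samples is None else n_samples
        i = np.arange(N)
        resid = (drift.predict(i) - col[:N]) / R0
        denom = float(np.sqrt(np.sum(resid**2)))
        if denom == 0:
            raise ValueError(
                "zero residual sum in Ind3 denominator; indicator undefined"
            )
        ind3 = ind2 / denom
    return IndicatorSet(R=R, R0=R0, R10=stats["R10"], R25=stats["R25"],
                        R50=stats["R50"], R75=stats["R75"],
                        Ind1=ind1, Ind2=ind2, Ind3=ind3)


def session_indicator_vector(signal: OdorSignal, indicator: str) -> np.ndarray:
    """The chosen indicator evaluated on each of the 15 columns."""
    if indicator not in INDICATOR_NAMES:
        raise ValueError(
            f"unknown indicator {indicator!r}; choose from {INDICATOR_NAMES}"
        )
    values = (
        signal.corrected_values
        if signal.corrected_values is not None
        else signal.values
    )
    if indicator in PHASE_STATS:
        return np.array([
            compute_phase_statistics(values[:, j], signal.phase_bounds)[
                indicator
            ]
            for j in range(N_FEATURES)
        ])
    if signal.drift_models is None:
        raise ValueError(
            f"indicator {indicator} needs per-column drift models; "
            f"preprocess the session first"
        )
    return np.array([
        compute_indicators(
            values[:, j], signal.phase_bounds, signal.drift_models[j]
        )[indicator]
        for j in range(N_FEATURES)
    ])


def build_feature_table(
    signals: list,
    indicator: str = "R",
    granularity: str = "session",
) -> pd.DataFrame:
    """Assemble the width-15 classifier input table.

    ``session`` granularity: one row per session, cells = the chosen
    indicator per odor feature.  ``timepoint`` granularity: one row per
    sample of the normalized signal ("raw normalized data"), tagged with its
    phase so the exposure class can be balanced downstream.

    Returns a DataFrame with columns ``label, provenance, [phase,] f1..f15``
    and ``attrs["indicator"]`` recording the table's origin.
    """
    if not signals:
        raise ValueError("no sessions given")
    periods = {s.sample_period_s for s in signals}
    if len(periods) > 1:
        raise ValueError(f"mixed sample periods: {sorted(periods)}")
    if granularity == "session":
        rows = [session_indicator_vector(s, indicator) for s in signals]
        df = pd.DataFrame(np.vstack(rows), columns=FEATURE_COLUMNS)
        df.insert(0, "label", [s.label for s in signals])
        df.insert(1, "provenance", "real")
    elif granularity == "timepoint":
        mats, labels, phases = [], [], []
        for s in signals:
            mats.append(s.values)
            labels.extend([s.label] * s.n_samples)
            phases.extend(s.phase_tags())
        df = pd.DataFrame(np.vstack(mats), columns=FEATURE_COLUMNS)
        df.insert(0, "label", labels)
        df.insert(1, "provenance", "real")
        df.insert(2, "phase", phases)
    else:
        raise ValueError(
            f"granularity must be 'session' or 'timepoint', got {granularity!r}"
        )
    df.attrs["indicator"] = indicator if granularity == "session" else "raw"
    df.attrs["granularity"] = granularity
    return df


def feature_matrix(table: pd.DataFrame) -> np.ndarray:
    """The (n_rows, 15) numeric block of a feature table."""
    return table[FEATURE_COLUMNS].to_numpy(dtype=float)
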