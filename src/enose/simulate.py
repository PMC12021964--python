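"""Synthetic chemosensor sessions with the structure the pipeline assumes.

Real recordings of the 15 odor features show, per column: a slowly drifting
baseline in the leading air phase, a saturating rise when the stimulus
arrives, an exponential decay that does not return all the way to baseline
once the stimulus is removed (sensor saturation), and frame-to-frame noise.
Repeated measurement campaigns lose sensitivity across the day.

The generator models each feature column as first-order (exponential)
rise/decay kinetics on top of a linear baseline — the simplest dynamics
consistent with those shapes:

* phase A: ``baseline + drift_slope * t``
* phase B: adds ``sensitivity * amplitude_f * (1 - exp(-t_B / rise_tau))``
* phase C: the exposure plateau decays with ``decay_tau`` toward
  ``(1 - recovery_fraction) * plateau`` above baseline (incomplete recovery)
* i.i.d. Gaussian noise of sd ``noise_sd`` is added throughout.

The default presets mirror the study design: three "whiskey-like" classes
with overlapping 15-feature signatures (hard task) plus one well-separated
"acetone-like" class (easy task), measured over 5 campaigns of decreasing
sensitivity, 300 samples per session in three equal 100-sample phases.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .frames import N_FEATURES, SAMPLE_PERIOD_S, OdorSignal

DEFAULT_PHASE_LENGTHS = (100, 100, 100)


@dataclass(frozen=True)
class SignatureSpec:
    """Per-class response profile: steady-state amplitude per odor feature
    (resistance units) plus rise/decay time constants (samples) and the
    fraction of the response that recovers after exposure ends."""

    class_name: str
    amplitudes: tuple
    rise_tau: float = 15.0
    decay_tau: float = 40.0
    recovery_fraction: float = 0.8

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes, dtype=float)
        if amps.shape != (N_FEATURES,):
            raise ValueError(
                f"need {N_FEATURES} amplitudes, got shape {amps.shape}"
            )
        if not np.isfinite(amps).all():
            raise ValueError("amplitudes must be finite")
        if self.rise_tau <= 0 or self.decay_tau <= 0:
            raise ValueError("rise_tau and decay_tau must be positive")
        if not 0.0 <= self.recovery_fraction <= 1.0:
            raise ValueError("recovery_fraction must lie in [0, 1]")
        object.__setattr__(self, "amplitudes", tuple(amps))


@dataclass(frozen=True)
class SessionNoiseSpec:
    """Per-session measurement conditions: baseline level, linear drift
    slope (units/sample, typically negative — the resistance sags under
    continuous stimulation), noise sd, and a multiplicative sensitivity in
    (0, 1] modelling saturation across repeated measurements."""

    baseline: float = 1000.0
    drift_slope: float = -0.05
    noise_sd: float = 2.0
    sensitivity: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in (0, 1]")


def simulate_session(
    sig: SignatureSpec,
    noise: SessionNoiseSpec = SessionNoiseSpec(),
    phase_lengths=DEFAULT_PHASE_LENGTHS,
    period_s: float = SAMPLE_PERIOD_S,
) -> OdorSignal:
    """One labelled session of ``sum(phase_lengths)`` frames.

    Deterministic under ``noise.seed``.
    """
    nA, nB, nC = phase_lengths
    if min(nA, nB, nC) <= 0:
        raise ValueError(f"phase lengths must be positive, got {phase_lengths}")
    T = nA + nB + nC
    t = np.arange(T, dtype=float)
    amps = np.asarray(sig.amplitudes)

    # unit response profile shared by all features, scaled per amplitude
    resp = np.zeros(T)
    tb = np.arange(1, nB + 1, dtype=float)
    rise = 1.0 - np.exp(-tb / sig.rise_tau)
    resp[nA:nA + nB] = rise
    plateau = rise[-1]
    tc = np.arange(1, nC + 1, dtype=float)
    resp[nA + nB:] = plateau * (
        (1.0 - sig.recovery_fraction)
        + sig.recovery_fraction * np.exp(-tc / sig.decay_tau)
    )

    base = noise.baseline + noise.drift_slope * t
    values = base[:, None] + noise.sensitivity * resp[:, None] * amps[None, :]
    rng = np.random.default_rng(noise.seed)
    values = values + rng.normal(0.0, noise.noise_sd, size=values.shape)
    return OdorSignal(
        values, label=sig.class_name, phase_bounds=(nA, nA + nB),
        sample_period_s=period_s,
    )


def simulate_dataset(
    signatures: list,
    n_campaigns: int = 5,
    noise_schedule: list | None = None,
    seed: int = 0,
    phase_lengths=DEFAULT_PHASE_LENGTHS,
) -> list:
    """One session per (campaign, class), campaign conditions applied.

    ``noise_schedule`` gives one :class:`SessionNoiseSpec` per campaign
    (default: :func:`default_noise_schedule`, with sensitivity falling
    across campaigns).  Per-session noise seeds are spawned from ``seed``.
    """
    if not signatures:
        raise ValueError("need at least one signature")
    names = [s.class_name for s in signatures]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate class names in signatures: {names}")
    schedule = noise_schedule or default_noise_schedule(n_campaigns)
    if len(schedule) != n_campaigns:
        raise ValueError(
            f"noise_schedule has {len(schedule)} entries for "
            f"{n_campaigns} campaigns"
        )
    rng = np.random.default_rng(seed)
    sessions = []
    for campaign, base_noise in enumerate(schedule):
        for sig in signatures:
            child_seed = int(rng.integers(0, 2**31 - 1))
            sessions.append(
                simulate_session(
                    sig, replace(base_noise, seed=child_seed), phase_lengths
                )
            )
    return sessions


# ---------------------------------------------------------------------------
# presets

def default_signatures() -> list:
    """Three overlapping whiskey-like signatures plus one well-separated
    acetone-like signature (the hard 3-class task and the easy 2-class task).

    Whiskey amplitudes occupy the same 25-45 unit band and differ by
    ~5-15 units per feature; the acetone profile is 2-3x stronger, as the
    far more volatile compound saturates the nanotubes faster and harder.
    """
    return [
        SignatureSpec("whiskey_T", (
            42, 38, 45, 30, 33, 40, 36, 28, 31, 44, 39, 35, 29, 37, 41,
        )),
        SignatureSpec("whiskey_C", (
            30, 45, 38, 42, 28, 33, 44, 36, 40, 31, 28, 42, 37, 30, 35,
        )),
        SignatureSpec("whiskey_L", (
            38, 33, 30, 45, 42, 29, 32, 41, 28, 37, 44, 30, 42, 36, 28,
        )),
        SignatureSpec("acetone", (
            120, 95, 140, 110, 130, 100, 125, 135, 90, 115, 105, 140, 120,
            95, 130,
        ), rise_tau=8.0, decay_tau=30.0, recovery_fraction=0.7),
    ]


def default_noise_schedule(n_campaigns: int = 5) -> list:
    """Campaign conditions: fixed baseline/drift/noise, sensitivity easing
    from 1.0 to 0.85 as the sensor saturates over the measurement day."""
    if n_campaigns < 1:
        raise ValueError("n_campaigns must be >= 1")
    sens = np.linspace(1.0, 0.85, n_campaigns)
    return [SessionNoiseSpec(sensitivity=float(s)) for s in sens]
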