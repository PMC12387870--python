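"""Synthetic 100 Hz expired-gas traces with known ground truth.

Generates dual-channel (PO2, PCO2) tidal-breathing waveforms with end-tidal
plateaus, per-breath noise, linear drift, cough artifacts, and an optional
unsteady-then-steady end-tidal CO2 wander, so the breath segmentation and
steady-state logic downstream are fully testable without device exports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "SAMPLE_RATE_HZ",
    "BreathPlan",
    "GasTrace",
    "synthesize_trace",
    "synthesize_unsteady_then_steady",
]

SAMPLE_RATE_HZ = 100.0

# Shape constants (see module tests): expiratory approach to the end-tidal
# value uses a time constant of 20% of the expiratory time; coughs are 0.3 s
# excursions of +/-15 mmHg in both channels that abort the expiration.
_PLATEAU_TAU_FRACTION = 0.2
_COUGH_DURATION_S = 0.3
_COUGH_AMPLITUDE_MMHG = 15.0


@dataclass(frozen=True)
class BreathPlan:
    """Planted ground truth for one synthetic breathing pattern."""

    respiratory_rate: float = 15.0  # breaths/min
    inspiratory_fraction: float = 0.4
    et_po2: float = 105.0  # mmHg, planted end-tidal O2 plateau
    et_pco2: float = 36.0  # mmHg, planted end-tidal CO2 plateau
    inspired_po2: float = 149.7  # mmHg (room air at sea level)
    inspired_pco2: float = 0.0  # mmHg
    plateau_noise_sd: float = 0.0  # mmHg, per-breath end-tidal jitter
    drift_per_min: float = 0.0  # mmHg/min linear drift of end-tidal values
    cough_times: tuple[float, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.respiratory_rate > 0:
            raise ValueError("respiratory_rate must be positive")
        if not 0.0 < self.inspiratory_fraction < 1.0:
            raise ValueError("inspiratory_fraction must be in (0, 1)")
        if not self.et_pco2 > self.inspired_pco2:
            raise ValueError("et_pco2 must exceed inspired_pco2")
        if not self.et_po2 < self.inspired_po2:
            raise ValueError("et_po2 must be below inspired_po2")
        if self.plateau_noise_sd < 0:
            raise ValueError("plateau_noise_sd must be non-negative")
        object.__setattr__(self, "cough_times", tuple(self.cough_times))

    @property
    def period_s(self) -> float:
        return 60.0 / self.respiratory_rate


@dataclass
class GasTrace:
    """Uniformly sampled expired PO2/PCO2 with one concurrent SpO2 reading."""

    po2: np.ndarray
    pco2: np.ndarray
    spo2: float = 96.0  # percent, single oximetry value paired with the trace
    barometric_pressure: float = 760.0  # mmHg
    sample_rate: float = SAMPLE_RATE_HZ
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.po2 = np.asarray(self.po2, dtype=float)
        self.pco2 = np.asarray(self.pco2, dtype=float)
        if self.po2.shape != self.pco2.shape:
            raise ValueError("po2 and pco2 must have the same length")
        if self.sample_rate != SAMPLE_RATE_HZ:
            raise ValueError(f"sample_rate must be {SAMPLE_RATE_HZ} Hz")
        if not (np.isfinite(self.po2).all() and np.isfinite(self.pco2).all()):
            raise ValueError("all pressures must be finite")
        if (self.po2 < 0).any() or (self.pco2 < 0).any():
            raise ValueError("all pressures must be non-negative")
        if not 50.0 <= self.spo2 <= 100.0:
            raise ValueError("spo2 must be in [50, 100]")

    @property
    def n_samples(self) -> int:
        return self.po2.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.n_samples) / self.sample_rate


def _expiration_profile(n: int, dt: float, t_exp: float) -> np.ndarray:
    """Weights in [0, 1] for the approach from inspired to end-tidal value.

    Exponential approach with tau = 20% of the expiratory time, normalized so
    the final expiration sample sits exactly at the end-tidal target (the
    planted plateau value is reproduced at machine precision).
    """
    tau = _PLATEAU_TAU_FRACTION * t_exp
    s = (np.arange(n) + 1) * dt
    w = (1.0 - np.exp(-s / tau)) / (1.0 - np.exp(-t_exp / tau))
    w[-1] = 1.0
    return np.clip(w, 0.0, 1.0)


def _render(
    plan: BreathPlan,
    duration: float,
    et_offset_fn: Callable[[float], tuple[float, float]] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Render the two channels; ``et_offset_fn(t_breath_start)`` may shift the
    per-breath end-tidal targets (used for the unsteady wander)."""
    fs = SAMPLE_RATE_HZ
    dt = 1.0 / fs
    n = int(round(duration * fs))
    po2 = np.full(n, plan.inspired_po2, dtype=float)
    pco2 = np.full(n, plan.inspired_pco2, dtype=float)
    rng = np.random.default_rng(plan.seed)

    period = plan.period_s
    t_insp = plan.inspiratory_fraction * period
    t_exp = period - t_insp

    for time in plan.cough_times:
        if not 0.0 <= time <= duration:
            raise ValueError(f"cough time {time}s outside trace duration {duration}s")

    k = 0
    while k * period < duration - 1e-9:
        b_start = k * period
        exp_start = b_start + t_insp
        b_end = min(b_start + period, duration)
        i_exp = int(round(exp_start * fs))
        i_end = int(round(b_end * fs))
        k += 1
        if i_exp >= n:
            break

        # per-breath end-tidal targets: planted value + drift + jitter + wander
        drift = plan.drift_per_min * exp_start / 60.0
        jitter_o2 = rng.normal(0.0, plan.plateau_noise_sd) if plan.plateau_noise_sd else 0.0
        jitter_co2 = rng.normal(0.0, plan.plateau_noise_sd) if plan.plateau_noise_sd else 0.0
        off_o2 = off_co2 = 0.0
        if et_offset_fn is not None:
            off_o2, off_co2 = et_offset_fn(b_start)
        target_o2 = plan.et_po2 + drift + jitter_o2 + off_o2
        target_co2 = plan.et_pco2 + drift + jitter_co2 + off_co2

        n_exp = i_end - i_exp
        if n_exp <= 1:
            continue
        w = _expiration_profile(n_exp, dt, t_exp)
        po2[i_exp:i_end] = plan.inspired_po2 + (target_o2 - plan.inspired_po2) * w
        pco2[i_exp:i_end] = plan.inspired_pco2 + (target_co2 - plan.inspired_pco2) * w

        # cough: high-frequency excursion that truncates the plateau, after
        # which the breath aborts back to inspired values
        for time in plan.cough_times:
            if b_start <= time < b_end:
                i_c = int(round(time * fs))
                i_c = max(i_c, i_exp)  # coughs only disturb the expired limb
                n_c = min(int(round(_COUGH_DURATION_S * fs)), n - i_c)
                if n_c <= 0:
                    continue
                signs = np.where(np.arange(n_c) % 2 == 0, 1.0, -1.0)
                po2[i_c : i_c + n_c] = np.clip(
                    po2[i_c] + signs * _COUGH_AMPLITUDE_MMHG, 0.0, None
                )
                pco2[i_c : i_c + n_c] = np.clip(
                    pco2[i_c] + signs * _COUGH_AMPLITUDE_MMHG, 0.0, None
                )
                if i_c + n_c < i_end:
                    po2[i_c + n_c : i_end] = plan.inspired_po2
                    pco2[i_c + n_c : i_end] = plan.inspired_pco2

    return np.clip(po2, 0.0, None), np.clip(pco2, 0.0, None)


def synthesize_trace(
    plan: BreathPlan,
    duration: float,
    *,
    spo2: float = 96.0,
    barometric_pressure: float = 760.0,
) -> GasTrace:
    """Build a 100 Hz trace of tidal breaths per ``plan``.

    Deterministic given ``plan.seed``.  Raises if ``duration`` is shorter
    than one breath period.
    """
    if duration < plan.period_s:
        raise ValueError(
            f"duration {duration}s shorter than one breath period {plan.period_s}s"
        )
    po2, pco2 = _render(plan, duration)
    return GasTrace(
        po2=po2,
        pco2=pco2,
        spo2=spo2,
        barometric_pressure=barometric_pressure,
        metadata={
            "inspired_po2": plan.inspired_po2,
            "inspired_pco2": plan.inspired_pco2,
            "planted_et_po2": plan.et_po2,
            "planted_et_pco2": plan.et_pco2,
            "respiratory_rate": plan.respiratory_rate,
            "seed": plan.seed,
        },
    )


def synthesize_unsteady_then_steady(
    plan: BreathPlan,
    settle_time: float,
    duration: float,
    *,
    wander_amplitude: float = 6.0,
    wander_period_s: float = 20.0,
    spo2: float = 96.0,
    barometric_pressure: float = 760.0,
) -> GasTrace:
    """Trace whose end-tidal values wander before ``settle_time`` then hold.

    Before ``settle_time`` the per-breath end-tidal CO2 target follows a
    sinusoid of amplitude ``wander_amplitude`` (O2 moves oppositely); after it
    the planted plateau values hold exactly.  The ground-truth settle time is
    recorded in ``metadata['settle_time_s']``.
    """
    if settle_time >= duration:
        raise ValueError("settle_time must be less than duration")
    if settle_time < 0:
        raise ValueError("settle_time must be non-negative")

    def offsets(t: float) -> tuple[float, float]:
        if t >= settle_time:
            return 0.0, 0.0
        w = wander_amplitude * np.sin(2.0 * np.pi * t / wander_period_s)
        return -w, w

    po2, pco2 = _render(plan, duration, et_offset_fn=offsets)
    return GasTrace(
        po2=po2,
        pco2=pco2,
        spo2=spo2,
        barometric_pressure=barometric_pressure,
        metadata={
            "inspired_po2": plan.inspired_po2,
            "inspired_pco2": plan.inspired_pco2,
            "planted_et_po2": plan.et_po2,
            "planted_et_pco2": plan.et_pco2,
            "respiratory_rate": plan.respiratory_rate,
            "settle_time_s": settle_time,
            "wander_amplitude": wander_amplitude,
            "seed": plan.seed,
        },
    )
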