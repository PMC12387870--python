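"""Breath segmentation, steady-state detection, and gas-exchange summary.

A trace is split into breaths on CO2 threshold crossings; each breath's
end-tidal values are taken at the CO2 maximum in the final portion of the
expiration.  A measurement is usable once the end-tidal CO2 signal shows no
variation (range within a tolerance) over the preceding 45 s, after which the
alveolar tensions PAO2/PACO2 are the means of the end-tidal values of five
consecutive steady-state breaths.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from statistics import median
from typing import Sequence

import numpy as np

from .physiology import (
    OxygenCurveConfig,
    gpao2_from_spo2,
    od_from_odflip,
    odflip as od_to_odflip,
    oxygen_deficit,
)
from .trace_synth import GasTrace

__all__ = [
    "Breath",
    "SteadyStateWindow",
    "GasExchangeSummary",
    "NoSteadyStateError",
    "NoUsableMeasurementError",
    "segment_breaths",
    "detect_steady_state",
    "summarize",
    "analyze_trace",
    "DEFAULT_STEADY_TOLERANCE_MMHG",
    "STEADY_WINDOW_S",
]

logger = logging.getLogger(__name__)

# Segmentation constants.  Onset = CO2 rising through 5 mmHg; expiration ends
# when CO2 falls back below onset minus 1 mmHg hysteresis.  End-tidal value =
# CO2 maximum over the final 30% of the expiration.
_ONSET_MMHG = 5.0
_HYSTERESIS_MMHG = 1.0
_ET_TAIL_FRACTION = 0.3

# Artifact rules: implausible expiratory duration, or end-tidal CO2 deviating
# more than 3 robust-SD from the trailing median.
_EXP_DURATION_BOUNDS_S = (0.5, 10.0)
_ARTIFACT_Z = 3.0
_ARTIFACT_SD_FLOOR_MMHG = 1.0
_ARTIFACT_HISTORY = 10

DEFAULT_STEADY_TOLERANCE_MMHG = 2.0
STEADY_WINDOW_S = 45.0
_MIN_STEADY_BREATHS = 5
_N_AVERAGED_BREATHS = 5


class NoSteadyStateError(RuntimeError):
    """The trace never satisfied the 45 s end-tidal CO2 stability rule."""


class NoUsableMeasurementError(RuntimeError):
    """Too few clean breaths to average; no usable measurement file."""


@dataclass
class Breath:
    """One segmented breath (times in seconds from trace start, [start, end))."""

    start: float
    end: float
    expiratory_duration: float
    et_po2: float
    et_pco2: float
    flagged_artifact: bool = False

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError("breath start must precede end")
        if self.expiratory_duration > (self.end - self.start) + 1e-9:
            raise ValueError("expiratory_duration cannot exceed breath span")
        if not self.flagged_artifact:
            if not (np.isfinite(self.et_po2) and np.isfinite(self.et_pco2)):
                raise ValueError("end-tidal values must be finite when unflagged")


@dataclass
class SteadyStateWindow:
    """Trailing window of unflagged breaths with stable end-tidal CO2."""

    breath_indices: list[int]
    window_start: float
    window_end: float
    etco2_variation: float


@dataclass
class GasExchangeSummary:
    """One steady-state measurement: alveolar tensions and derived scores."""

    pao2: float
    paco2: float
    spo2: float
    gpao2: float
    od: float
    odflip: float
    respiratory_rate: float
    rq: float
    inspired_po2: float
    barometric_pressure: float


def segment_breaths(trace: GasTrace) -> list[Breath]:
    """Split a trace into time-ordered, non-overlapping breaths.

    Returns an empty list (with a warning) when no CO2 onset crossings are
    found, e.g. for a flat trace.
    """
    co2 = trace.pco2
    o2 = trace.po2
    fs = trace.sample_rate
    n = co2.size

    below = co2 < (_ONSET_MMHG - _HYSTERESIS_MMHG)
    rising = (co2[1:] >= _ONSET_MMHG) & (co2[:-1] < _ONSET_MMHG)

    # onset only counts after the signal has dropped below the hysteresis
    # floor since the previous expiration (or from trace start)
    onsets: list[int] = []
    armed = bool(co2[0] < _ONSET_MMHG)
    for i in range(1, n):
        if below[i]:
            armed = True
        if rising[i - 1] and armed:
            onsets.append(i)
            armed = False

    if not onsets:
        logger.warning("no CO2 onset crossings found; returning no breaths")
        return []

    breaths: list[Breath] = []
    for k, i0 in enumerate(onsets):
        i1 = onsets[k + 1] if k + 1 < len(onsets) else n
        # expiration runs until CO2 falls below the hysteresis floor
        seg = co2[i0:i1]
        drop = np.nonzero(seg < (_ONSET_MMHG - _HYSTERESIS_MMHG))[0]
        i_exp_end = i0 + int(drop[0]) if drop.size else i1
        n_exp = i_exp_end - i0
        if n_exp < 1:
            continue
        tail0 = i_exp_end - max(1, int(np.ceil(_ET_TAIL_FRACTION * n_exp)))
        i_et = tail0 + int(np.argmax(co2[tail0:i_exp_end]))
        breaths.append(
            Breath(
                start=i0 / fs,
                end=i1 / fs,
                expiratory_duration=n_exp / fs,
                et_po2=float(o2[i_et]),
                et_pco2=float(co2[i_et]),
            )
        )

    _flag_artifacts(breaths)
    return breaths


def _flag_artifacts(breaths: list[Breath]) -> None:
    lo, hi = _EXP_DURATION_BOUNDS_S
    for b in breaths:
        if not lo <= b.expiratory_duration <= hi:
            b.flagged_artifact = True

    # deviation from trailing median of recent duration-plausible breaths
    history: list[float] = []
    for b in breaths:
        if history:
            med = median(history)
            mad = median(abs(x - med) for x in history)
            sd = max(1.4826 * mad, _ARTIFACT_SD_FLOOR_MMHG)
            if abs(b.et_pco2 - med) > _ARTIFACT_Z * sd:
                b.flagged_artifact = True
        if not b.flagged_artifact:
            history.append(b.et_pco2)
            if len(history) > _ARTIFACT_HISTORY:
                history.pop(0)


def detect_steady_state(
    breaths: Sequence[Breath],
    tolerance: float = DEFAULT_STEADY_TOLERANCE_MMHG,
    window_s: float = STEADY_WINDOW_S,
) -> SteadyStateWindow | None:
    """Earliest trailing window of >=45 s whose etCO2 range is within tolerance.

    The window for a candidate end-breath consists of every breath overlapping
    the preceding ``window_s`` seconds; it qualifies when it contains no
    flagged breaths, holds at least five breaths, spans at least ``window_s``
    seconds, and its end-tidal CO2 max-min is at most ``tolerance``.  Returns
    ``None`` when no window qualifies (a valid outcome, not an error).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    for j, b in enumerate(breaths):
        t_lo = b.end - window_s
        idx = [i for i in range(j + 1) if breaths[i].end > t_lo]
        if len(idx) < _MIN_STEADY_BREATHS:
            continue
        window = [breaths[i] for i in idx]
        if any(w.flagged_artifact for w in window):
            continue
        if b.end - window[0].start < window_s:
            continue
        ets = [w.et_pco2 for w in window]
        variation = max(ets) - min(ets)
        if variation <= tolerance:
            win = SteadyStateWindow(
                breath_indices=idx,
                window_start=window[0].start,
                window_end=b.end,
                etco2_variation=variation,
            )
            assert win.window_end - win.window_start >= window_s
            assert not any(breaths[i].flagged_artifact for i in idx)
            return win
    return None


def summarize(
    breaths: Sequence[Breath],
    window: SteadyStateWindow,
    spo2: float,
    physiology_config: OxygenCurveConfig | None = None,
    *,
    inspired_po2: float = 149.7,
    barometric_pressure: float = 760.0,
) -> GasExchangeSummary:
    """Average the last five steady-state breaths into a measurement summary.

    PAO2/PACO2 are the means of the end-tidal O2/CO2 of the five most recent
    unflagged breaths in the window; gPaO2, OD and ODFlip are delegated to the
    physiology layer; respiratory rate comes from the median breath period;
    RQ = PACO2 / (PiO2 - PAO2).
    """
    config = physiology_config or OxygenCurveConfig()
    usable = [i for i in window.breath_indices if not breaths[i].flagged_artifact]
    if len(usable) < _N_AVERAGED_BREATHS:
        raise NoUsableMeasurementError(
            f"only {len(usable)} unflagged breaths in steady-state window; "
            "no usable measurement file"
        )
    chosen = [breaths[i] for i in usable[-_N_AVERAGED_BREATHS:]]
    pao2 = float(np.mean([b.et_po2 for b in chosen]))
    paco2 = float(np.mean([b.et_pco2 for b in chosen]))

    periods = np.diff([breaths[i].start for i in window.breath_indices])
    rr = 60.0 / float(np.median(periods)) if periods.size else float("nan")

    gpao2 = gpao2_from_spo2(spo2, paco2, config)
    od = oxygen_deficit(pao2, gpao2)
    return GasExchangeSummary(
        pao2=pao2,
        paco2=paco2,
        spo2=spo2,
        gpao2=gpao2,
        od=od,
        odflip=od_to_odflip(od),
        respiratory_rate=rr,
        rq=paco2 / (inspired_po2 - pao2),
        inspired_po2=inspired_po2,
        barometric_pressure=barometric_pressure,
    )


def analyze_trace(
    trace: GasTrace,
    physiology_config: OxygenCurveConfig | None = None,
    tolerance: float = DEFAULT_STEADY_TOLERANCE_MMHG,
) -> GasExchangeSummary:
    """Full pipeline for one trace: segment, find steady state, summarize.

    Raises :class:`NoSteadyStateError` when the stability rule is never met.
    """
    breaths = segment_breaths(trace)
    window = detect_steady_state(breaths, tolerance=tolerance)
    if window is None:
        raise NoSteadyStateError("steady state not achieved")
    inspired = float(trace.metadata.get("inspired_po2", 149.7))
    return summarize(
        breaths,
        window,
        trace.spo2,
        physiology_config,
        inspired_po2=inspired,
        barometric_pressure=trace.barometric_pressure,
    )
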