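"""Oxyhemoglobin dissociation arithmetic: SpO2 + PACO2 -> gPaO2 -> oxygen deficit.

The calculated arterial oxygen tension (gPaO2) is obtained by algebraically
inverting the Hill saturation curve at the observed SpO2, with the half-
saturation tension (P50) shifted for the CO2/Bohr effect.  The oxygen deficit
(OD) is the alveolar-minus-calculated-arterial difference PAO2 - gPaO2, a
noninvasive surrogate for the alveolar-arterial gradient.  ODFlip = 100 - OD
is an orientation dummy so that OD and SpO2 score on a common ROC axis.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

__all__ = [
    "OxygenCurveConfig",
    "hill_saturation",
    "severinghaus_saturation",
    "corrected_p50",
    "gpao2_from_spo2",
    "oxygen_deficit",
    "odflip",
    "od_from_odflip",
]

logger = logging.getLogger(__name__)

# Henderson-Hasselbalch constants for estimating pH from PCO2
_PK_CARBONIC = 6.1
_CO2_SOLUBILITY = 0.03  # mmol/L per mmHg


@dataclass(frozen=True)
class OxygenCurveConfig:
    """Constants of the saturation-curve model.

    Attributes
    ----------
    hill_n:
        Hill coefficient of the O2 saturation curve.
    p50_standard:
        Half-saturation O2 tension (mmHg) under standard conditions.
    reference_paco2:
        PACO2 (mmHg) at which no Bohr shift is applied.
    bohr_slope:
        d(log10 P50) / d(pH); negative, so acidosis raises P50.
    assumed_hco3:
        Bicarbonate (mmol/L) assumed when estimating pH from PACO2.
    spo2_clamp:
        (lower, upper) admissible SpO2 percent; readings above the upper
        bound are clamped with a warning, readings below the lower bound
        are rejected.
    """

    hill_n: float = 2.88
    p50_standard: float = 26.86
    reference_paco2: float = 40.0
    bohr_slope: float = -0.48
    assumed_hco3: float = 24.0
    spo2_clamp: tuple[float, float] = (50.0, 99.5)

    def __post_init__(self) -> None:
        if not self.hill_n > 0:
            raise ValueError("hill_n must be positive")
        if not self.p50_standard > 0:
            raise ValueError("p50_standard must be positive")
        lo, hi = self.spo2_clamp
        if not (lo < hi < 100.0):
            raise ValueError("spo2_clamp must satisfy lower < upper < 100")


def _ph_from_paco2(paco2: float, hco3: float) -> float:
    """Henderson-Hasselbalch pH estimate from CO2 tension."""
    return _PK_CARBONIC + math.log10(hco3 / (_CO2_SOLUBILITY * paco2))


def hill_saturation(po2: float, p50: float, n: float) -> float:
    """Fractional hemoglobin saturation po2**n / (po2**n + p50**n).

    Strictly increasing in ``po2``; returns 0.5 exactly at ``po2 == p50``.
    """
    if po2 < 0:
        raise ValueError(f"po2 must be non-negative, got {po2}")
    if p50 <= 0:
        raise ValueError(f"p50 must be positive, got {p50}")
    if n <= 0:
        raise ValueError(f"n must be positive, got {n}")
    if po2 == 0.0:
        return 0.0
    # (p50/po2)**n form avoids overflow for large po2
    return 1.0 / (1.0 + (p50 / po2) ** n)


def severinghaus_saturation(po2: float) -> float:
    """Empirical standard-curve saturation 1 / (23400/(po2^3 + 150 po2) + 1).

    Used as an independent cross-check of the Hill approximation.
    """
    if po2 <= 0:
        raise ValueError(f"po2 must be positive, got {po2}")
    return 1.0 / (23400.0 / (po2**3 + 150.0 * po2) + 1.0)


def corrected_p50(paco2: float, config: OxygenCurveConfig | None = None) -> float:
    """P50 shifted for the Bohr effect of CO2.

    pH is estimated from ``paco2`` by Henderson-Hasselbalch at the configured
    fixed bicarbonate; the shift is applied relative to the pH at
    ``reference_paco2`` so that ``corrected_p50(reference_paco2)`` returns
    ``p50_standard`` exactly.  P50 increases with PACO2.
    """
    config = config or OxygenCurveConfig()
    if not (10.0 <= paco2 <= 120.0):
        raise ValueError(f"paco2 {paco2} mmHg outside supported range [10, 120]")
    ph = _ph_from_paco2(paco2, config.assumed_hco3)
    ph_ref = _ph_from_paco2(config.reference_paco2, config.assumed_hco3)
    return config.p50_standard * 10.0 ** (config.bohr_slope * (ph - ph_ref))


def gpao2_from_spo2(
    spo2: float, paco2: float, config: OxygenCurveConfig | None = None
) -> float:
    """Calculated arterial O2 tension by inverting the Hill curve at SpO2.

    gPaO2 = P50(PACO2) * (S / (1 - S))**(1/n) with S = spo2/100.  Strictly
    increasing in SpO2 and in PACO2.  SpO2 at or above the clamp ceiling is
    clamped (the inversion is singular at 100%); SpO2 below the clamp floor
    is rejected as physiologically implausible.
    """
    config = config or OxygenCurveConfig()
    lo, hi = config.spo2_clamp
    if spo2 < lo:
        raise ValueError(f"spo2 {spo2}% below clamp floor {lo}%")
    if spo2 > hi:
        logger.warning("spo2 %.2f%% clamped to %.2f%% for Hill inversion", spo2, hi)
        spo2 = hi
    s = spo2 / 100.0
    p50 = corrected_p50(paco2, config)
    return p50 * (s / (1.0 - s)) ** (1.0 / config.hill_n)


def oxygen_deficit(pao2: float, gpao2: float) -> float:
    """Oxygen deficit OD = PAO2 - gPaO2 (mmHg).

    Negative values (possible with noisy inputs) are passed through with a
    warning rather than rejected.
    """
    if not (math.isfinite(pao2) and math.isfinite(gpao2)):
        raise ValueError("pao2 and gpao2 must be finite")
    od = pao2 - gpao2
    if od < 0:
        logger.warning("negative oxygen deficit %.2f mmHg (pao2=%.2f, gpao2=%.2f)",
                       od, pao2, gpao2)
    return od


def odflip(od: float) -> float:
    """Orientation dummy 100 - OD."""
    if not math.isfinite(od):
        raise ValueError("od must be finite")
    return 100.0 - od


def od_from_odflip(value: float) -> float:
    """Inverse of :func:`odflip`; the pair is an exact involution."""
    if not math.isfinite(value):
        raise ValueError("odflip must be finite")
    return 100.0 - value
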