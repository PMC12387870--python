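"""Synthetic patient cohorts with a planted logistic outcome model.

Two generation routes: draw (ODFlip, SpO2) directly from a correlated
bivariate Gaussian with a Bernoulli outcome on a planted logit, or push
synthetic gas traces through the full breath/physiology pipeline so each
row's oxygen deficit is computed, not drawn.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import breath_engine, trace_synth
from .breath_engine import GasExchangeSummary, NoSteadyStateError
from .physiology import OxygenCurveConfig
from .trace_synth import BreathPlan

__all__ = [
    "CohortPlan",
    "TraceParticipant",
    "COHORT_COLUMNS",
    "simulate_cohort",
    "simulate_cohort_from_traces",
]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = [
    "id",
    "od",
    "odflip",
    "spo2",
    "needs_supplemental_o2",
    "covid_status",
    "cohort_label",
]

# eligibility-style truncation of simulated SpO2 (enrollment ceiling 97%,
# protocol stop floor 88%)
_SPO2_BOUNDS = (88.0, 97.0)


@dataclass(frozen=True)
class CohortPlan:
    """Planted generative model for a direct-draw cohort."""

    n: int
    intercept: float = 0.0
    beta_odflip: float = 0.0  # per mmHg of ODFlip
    beta_spo2: float = 0.0  # per percent SpO2
    odflip_mean: float = 65.0  # mmHg (mean OD 35)
    odflip_sd: float = 15.0
    spo2_mean: float = 94.0  # percent
    spo2_sd: float = 2.0
    correlation: float = 0.6  # corr(odflip, spo2)
    covid_label_fraction: float = 0.0
    spo2_bounds: tuple[float, float] = _SPO2_BOUNDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if self.odflip_sd <= 0 or self.spo2_sd <= 0:
            raise ValueError("distribution SDs must be positive")
        if not -1.0 <= self.correlation <= 1.0:
            raise ValueError("correlation must be in [-1, 1]")
        if not 0.0 <= self.covid_label_fraction <= 1.0:
            raise ValueError("covid_label_fraction must be in [0, 1]")


def simulate_cohort(plan: CohortPlan) -> pd.DataFrame:
    """Draw a cohort table from the planted bivariate + logistic model.

    (odflip, spo2) come from a correlated Gaussian, with spo2 truncated to
    the eligibility bounds by rejection; the outcome is Bernoulli with
    logit = intercept + beta_odflip*odflip + beta_spo2*spo2.  Deterministic
    given ``plan.seed``.
    """
    if abs(plan.correlation) >= 1.0:
        raise ValueError("degenerate covariance: |correlation| must be < 1")
    rng = np.random.default_rng(plan.seed)
    cov = np.array(
        [
            [plan.odflip_sd**2, plan.correlation * plan.odflip_sd * plan.spo2_sd],
            [plan.correlation * plan.odflip_sd * plan.spo2_sd, plan.spo2_sd**2],
        ]
    )
    mean = np.array([plan.odflip_mean, plan.spo2_mean])

    lo, hi = plan.spo2_bounds
    odflip = np.empty(0)
    spo2 = np.empty(0)
    while odflip.size < plan.n:
        draw = rng.multivariate_normal(mean, cov, size=2 * plan.n, method="cholesky")
        keep = (draw[:, 1] >= lo) & (draw[:, 1] <= hi)
        odflip = np.concatenate([odflip, draw[keep, 0]])
        spo2 = np.concatenate([spo2, draw[keep, 1]])
    odflip = odflip[: plan.n]
    spo2 = spo2[: plan.n]

    logit = plan.intercept + plan.beta_odflip * odflip + plan.beta_spo2 * spo2
    prob = 1.0 / (1.0 + np.exp(-logit))
    outcome = rng.random(plan.n) < prob

    n_covid = int(round(plan.covid_label_fraction * plan.n))
    covid = np.zeros(plan.n, dtype=bool)
    covid[rng.permutation(plan.n)[:n_covid]] = True

    return pd.DataFrame(
        {
            "id": [f"P{i:05d}" for i in range(plan.n)],
            "od": 100.0 - odflip,
            "odflip": odflip,
            "spo2": spo2,
            "needs_supplemental_o2": outcome,
            "covid_status": covid,
            "cohort_label": np.where(covid, "positive", "negative"),
        }
    )


@dataclass(frozen=True)
class TraceParticipant:
    """One participant whose oxygen deficit is measured through the pipeline."""

    participant_id: str
    breath_plan: BreathPlan
    duration_s: float = 180.0
    spo2: float = 94.0
    settle_time_s: float = 0.0
    never_steady: bool = False  # wander the whole trace; measurement censored
    covid_status: bool = False


def simulate_cohort_from_traces(
    participants: Sequence[TraceParticipant],
    outcome_rule: Callable[[GasExchangeSummary], bool],
    physiology_config: OxygenCurveConfig | None = None,
    tolerance: float = breath_engine.DEFAULT_STEADY_TOLERANCE_MMHG,
) -> pd.DataFrame:
    """End-to-end cohort: trace -> breaths -> steady state -> OD -> row.

    Participants whose trace never reaches steady state are censored from the
    table with a log entry; the returned table holds only surviving rows.
    """
    rows = []
    for part in participants:
        if part.never_steady:
            # wander persists past the end of the trace
            trace = trace_synth.synthesize_unsteady_then_steady(
                part.breath_plan,
                settle_time=part.duration_s - 1e-6,
                duration=part.duration_s,
                spo2=part.spo2,
            )
        elif part.settle_time_s > 0:
            trace = trace_synth.synthesize_unsteady_then_steady(
                part.breath_plan,
                settle_time=part.settle_time_s,
                duration=part.duration_s,
                spo2=part.spo2,
            )
        else:
            trace = trace_synth.synthesize_trace(
                part.breath_plan, part.duration_s, spo2=part.spo2
            )
        try:
            summary = breath_engine.analyze_trace(
                trace, physiology_config, tolerance=tolerance
            )
        except NoSteadyStateError:
            logger.info(
                "participant %s censored: steady state not achieved",
                part.participant_id,
            )
            continue
        rows.append(
            {
                "id": part.participant_id,
                "od": summary.od,
                "odflip": summary.odflip,
                "spo2": summary.spo2,
                "needs_supplemental_o2": bool(outcome_rule(summary)),
                "covid_status": part.covid_status,
                "cohort_label": "positive" if part.covid_status else "negative",
            }
        )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
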