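"""Behavioral scoring of Salience-CPT runs.

Responses are registered between 200 and 1500 ms after stimulus onset only
(closed interval); a response outside that window counts as no response.
Go trials are scored HIT/MISS, NoGo trials FA (false alarm, commission) /
CorrectInhibition.  Summary measures follow the conventional definitions:
commission ratio = FA / (FA + CorrectInhibition), omission ratio =
MISS / (MISS + HIT) pooled over both Go conditions, RT mean/SD over HIT
trials per condition (sample SD, n-1 denominator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import TrialSequence

logger = logging.getLogger(__name__)

HIT, MISS, FA, CORRECT_INHIBITION = "HIT", "MISS", "FA", "CorrectInhibition"


class UndefinedRatioError(ValueError):
    """Ratio requested but its denominator class has no trials."""


@dataclass(frozen=True)
class TrialOutcome:
    index: int
    condition: str
    label: str
    rt: float | None  # ms; present iff label in {HIT, FA}


@dataclass
class BehavioralSummary:
    rt_mean_standard: float
    rt_mean_salient: float
    rt_sd_standard: float | None
    rt_sd_salient: float | None
    omission_ratio: float
    commission_ratio: float
    salience_rt_effect: float

    def to_row(self) -> dict:
        return dict(self.__dict__)


def classify_trials(
    seq: TrialSequence,
    responses: pd.DataFrame,
    window_lo: float = 200.0,
    window_hi: float = 1500.0,
) -> list:
    """Label every trial HIT/MISS/FA/CorrectInhibition.

    ``responses`` must align with ``seq.trials`` (columns ``responded`` and
    ``rt_ms``).  A response with RT outside [window_lo, window_hi] is
    treated as no response.
    """
    if len(responses) != len(seq):
        raise ValueError(
            f"responses ({len(responses)}) do not align with trials ({len(seq)})"
        )
    responded = responses["responded"].to_numpy()
    rts = responses["rt_ms"].to_numpy(dtype=float)

    outcomes = []
    for trial, ans, rt in zip(seq.trials, responded, rts):
        in_window = bool(ans) and np.isfinite(rt) and window_lo <= rt <= window_hi
        if trial.condition == "NoGo":
            label = FA if in_window else CORRECT_INHIBITION
        else:
            label = HIT if in_window else MISS
        outcomes.append(
            TrialOutcome(
                index=trial.index,
                condition=trial.condition,
                label=label,
                rt=float(rt) if label in (HIT, FA) else None,
            )
        )
    return outcomes


def outcome_frame(outcomes) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "trial": [o.index for o in outcomes],
            "condition": [o.condition for o in outcomes],
            "outcome": [o.label for o in outcomes],
            "rt_ms": [o.rt if o.rt is not None else np.nan for o in outcomes],
        }
    )


def commission_ratio(outcomes) -> float:
    """FA / (FA + CorrectInhibition)."""
    labels = [o.label for o in outcomes if o.condition == "NoGo"]
    if not labels:
        raise UndefinedRatioError("no NoGo trials")
    return labels.count(FA) / len(labels)


def omission_ratio(outcomes) -> float:
    """MISS / (MISS + HIT), pooled over StandardGo and SalientGo."""
    labels = [o.label for o in outcomes if o.condition != "NoGo"]
    if not labels:
        raise UndefinedRatioError("no Go trials")
    return labels.count(MISS) / len(labels)


def rt_summary(outcomes, condition: str) -> tuple:
    """(mean, sd) of HIT reaction times in one Go condition.

    SD uses the n-1 denominator and is ``None`` with fewer than two hits.
    """
    rts = np.array(
        [o.rt for o in outcomes if o.condition == condition and o.label == HIT]
    )
    if rts.size == 0:
        return float("nan"), None
    mean = float(rts.mean())
    if rts.size < 2:
        logger.info("only %d HIT(s) in %s: SD undefined", rts.size, condition)
        return mean, None
    return mean, float(rts.std(ddof=1))


def behavioral_summary(outcomes) -> BehavioralSummary:
    m_std, sd_std = rt_summary(outcomes, "StandardGo")
    m_sal, sd_sal = rt_summary(outcomes, "SalientGo")
    return BehavioralSummary(
        rt_mean_standard=m_std,
        rt_mean_salient=m_sal,
        rt_sd_standard=sd_std,
        rt_sd_salient=sd_sal,
        omission_ratio=omission_ratio(outcomes),
        commission_ratio=commission_ratio(outcomes),
        salience_rt_effect=m_sal - m_std,
    )
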