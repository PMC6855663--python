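"""Progression detection and progression-free survival (Kaplan-Meier).

Tumour progression is scored per animal from its relative-tumour-volume
(RTV) trace: the first post-baseline day with RTV > 1 at or after the RTV
nadir ("after initial treatment response"); an animal killed before
progressing counts as an event at its kill day; otherwise the animal is
censored at its last follow-up day. Progression-free survival is estimated
with a hand-implemented product-limit (Kaplan-Meier) estimator.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .growth import FATE_KILLED, MeasurementSeries, relative_volume

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProgressionRecord:
    """Time-to-progression for one animal (event=False means censored)."""

    animal_id: str
    time: float
    event: bool


@dataclass
class SurvivalCurve:
    """Right-continuous product-limit step function, S(0) = 1.

    ``times`` are the distinct event times in increasing order and
    ``survival[i]`` the estimate just after ``times[i]``.
    """

    times: np.ndarray
    survival: np.ndarray

    def at(self, t: float) -> float:
        """S(t) for arbitrary t (right-continuous lookup)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def detect_progression(
    series: MeasurementSeries,
    rtvs: Optional[Sequence[tuple[float, float]]] = None,
) -> ProgressionRecord:
    """Score one animal's progression event from its RTV trace.

    The event day is the first day t > 0 with RTV(t) > 1 occurring at or
    after the day of minimal RTV (strict inequality; baseline equality is
    not progression). For tumours that never respond (RTV minimum at day 0)
    this reduces to the first day with RTV > 1. Killed animals that have not
    progressed by their kill day are events at ``fate_day``; all others are
    censored at the last follow-up day.
    """
    if rtvs is None:
        rtvs = relative_volume(series)
    rtvs = list(rtvs)
    post = [(d, r) for d, r in rtvs if d > 0]
    if not post:
        logger.warning("%s: no post-baseline measurements; censored at day 0",
                       series.animal_id)
        return ProgressionRecord(series.animal_id, 0.0, False)

    days = np.array([d for d, _ in rtvs])
    vals = np.array([r for _, r in rtvs])
    nadir_day = days[int(np.argmin(vals))]
    for d, r in post:
        if d >= nadir_day and r > 1.0:
            return ProgressionRecord(series.animal_id, float(d), True)
    if series.fate == FATE_KILLED:
        return ProgressionRecord(series.animal_id, float(series.fate_day), True)
    last = series.fate_day if series.fate_day is not None else post[-1][0]
    return ProgressionRecord(series.animal_id, float(last), False)


def km_estimator(records: Sequence[ProgressionRecord]) -> SurvivalCurve:
    """Product-limit estimate of progression-free survival.

    At each distinct event time t: S <- S * (1 - d_t / n_t) with n_t the
    number at risk (time >= t, so observations censored exactly at t are
    still at risk: events precede censorings at tied times).
    """
    if not records:
        raise ValueError("km_estimator needs at least one record")
    times = np.array([r.time for r in records])
    events = np.array([r.event for r in records])
    event_times = np.unique(times[events])
    surv = []
    s = 1.0
    for t in event_times:
        n_at_risk = int(np.sum(times >= t))
        d = int(np.sum((times == t) & events))
        s *= 1.0 - d / n_at_risk
        surv.append(s)
    return SurvivalCurve(times=event_times.astype(float), survival=np.array(surv))


def median_ttp(curve: SurvivalCurve) -> Optional[float]:
    """Median time to progression: smallest step time with S <= 0.5.

    Returns None (and logs) when the curve never reaches 0.5, i.e. fewer
    than half the animals progressed during follow-up.
    """
    below = np.nonzero(curve.survival <= 0.5)[0]
    if len(below) == 0:
        logger.info("median TTP undefined: survival never reaches 0.5")
        return None
    return float(curve.times[below[0]])


def records_table(records: Sequence[ProgressionRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"animal_id": r.animal_id, "time": r.time, "event": int(r.event)}
         for r in records]
    )


def curve_table(curve: SurvivalCurve, group: str = "") -> pd.DataFrame:
    """Step-function table including the S(0)=1 anchor row."""
    rows = [{"group": group, "time": 0.0, "survival": 1.0}]
    for t, s in zip(curve.times, curve.survival):
        rows.append({"group": group, "time": t, "survival": s})
    return pd.DataFrame(rows)
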