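"""Tumour growth-curve analysis from calliper measurements.

Turns per-animal calliper triples (length, width, height in mm) into
ellipsoid volumes, relative tumour volumes (RTV, volume normalised to the
day-0 baseline at treatment start) and group-level summary curves with
per-day means, SEMs and ratios to the untreated control arm.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Calliper-ellipsoid constant: V = (pi/6) * l * w * h, i.e. an ellipsoid
#: whose semi-axes are half the measured calliper dimensions.
ELLIPSOID_FACTOR = math.pi / 6.0

FATE_FOLLOWED = "followed-to-end"
FATE_KILLED = "killed"


class ConfigurationError(ValueError):
    """Input data violates a structural requirement (e.g. missing baseline)."""


def ellipsoid_volume(length: float, width: float, height: float) -> float:
    """Tumour volume in mm^3 from three calliper dimensions in mm.

    Uses the standard calliper-ellipsoid convention V = (pi/6)*l*w*h.
    A zero dimension gives volume 0; negative dimensions are invalid.
    """
    if length < 0 or width < 0 or height < 0:
        raise ValueError(
            f"calliper dimensions must be non-negative, got "
            f"({length}, {width}, {height})"
        )
    return ELLIPSOID_FACTOR * length * width * height


@dataclass(frozen=True)
class Measurement:
    """One calliper visit: study day plus the three dimensions in mm.

    All three dimensions are present, or all absent (a missed visit).
    """

    day: float
    length: Optional[float] = None
    width: Optional[float] = None
    height: Optional[float] = None

    def __post_init__(self) -> None:
        dims = (self.length, self.width, self.height)
        present = [d is not None for d in dims]
        if any(present) and not all(present):
            raise ValueError(f"day {self.day}: partial calliper triple {dims}")
        if self.day < 0:
            raise ValueError(f"negative study day {self.day}")
        if all(present) and any(d <= 0 for d in dims):  # type: ignore[operator]
            raise ValueError(f"day {self.day}: non-positive dimension in {dims}")

    @property
    def missed(self) -> bool:
        return self.length is None

    @property
    def volume(self) -> Optional[float]:
        if self.missed:
            return None
        return ellipsoid_volume(self.length, self.width, self.height)


@dataclass
class MeasurementSeries:
    """One animal's time-ordered calliper measurements and fate."""

    animal_id: str
    group: str
    measurements: list[Measurement]
    fate: str = FATE_FOLLOWED
    fate_day: Optional[float] = None

    def __post_init__(self) -> None:
        days = [m.day for m in self.measurements]
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError(f"{self.animal_id}: days not strictly increasing: {days}")
        if self.fate not in (FATE_FOLLOWED, FATE_KILLED):
            raise ValueError(f"{self.animal_id}: unknown fate {self.fate!r}")
        if self.fate == FATE_KILLED:
            if self.fate_day is None:
                raise ValueError(f"{self.animal_id}: killed without fate_day")
            if days and self.fate_day < days[-1]:
                raise ValueError(
                    f"{self.animal_id}: fate_day {self.fate_day} before last "
                    f"measurement day {days[-1]}"
                )

    @property
    def baseline(self) -> Measurement:
        for m in self.measurements:
            if m.day == 0 and not m.missed:
                return m
        raise ConfigurationError(f"{self.animal_id}: no day-0 baseline measurement")

    @property
    def last_day(self) -> float:
        observed = [m.day for m in self.measurements if not m.missed]
        return observed[-1] if observed else 0.0


@dataclass
class Cohort:
    """Animals grouped by treatment arm."""

    series: list[MeasurementSeries]
    control_group: str

    def __post_init__(self) -> None:
        groups = {s.group for s in self.series}
        if self.control_group not in groups:
            raise ConfigurationError(
                f"control group {self.control_group!r} has no animals "
                f"(arms present: {sorted(groups)})"
            )

    @property
    def groups(self) -> list[str]:
        seen: list[str] = []
        for s in self.series:
            if s.group not in seen:
                seen.append(s.group)
        return seen

    def arm(self, group: str) -> list[MeasurementSeries]:
        return [s for s in self.series if s.group == group]


@dataclass
class GroupCurve:
    """Per-day mean RTV summary for one treatment arm."""

    group: str
    days: np.ndarray
    mean_rtv: np.ndarray
    sem_rtv: np.ndarray
    n: np.ndarray
    ratio_to_control: np.ndarray = field(default=None)  # type: ignore[assignment]


def relative_volume(series: MeasurementSeries) -> list[tuple[float, float]]:
    """RTV sequence for one animal: volume at each day over the day-0 volume.

    Missed visits are skipped (never interpolated). Raises
    :class:`ConfigurationError` when the day-0 baseline is absent or zero.
    """
    v0 = series.baseline.volume
    if v0 is None or v0 <= 0:
        raise ConfigurationError(f"{series.animal_id}: non-positive baseline volume")
    out = []
    for m in series.measurements:
        if m.missed:
            continue
        out.append((m.day, m.volume / v0))
    return out


def animal_table(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-animal table: animal_id, group, day, volume_mm3, rtv."""
    rows = []
    for s in cohort.series:
        rtv = dict(relative_volume(s))
        for m in s.measurements:
            if m.missed:
                continue
            rows.append(
                {
                    "animal_id": s.animal_id,
                    "group": s.group,
                    "day": m.day,
                    "volume_mm3": m.volume,
                    "rtv": rtv[m.day],
                }
            )
    return pd.DataFrame(rows)


def _sem(values: np.ndarray) -> float:
    # single-animal convention: SEM = 0 so curves stay plottable
    if len(values) < 2:
        return 0.0
    return float(np.std(values, ddof=1) / math.sqrt(len(values)))


def summarise_groups(cohort: Cohort) -> list[GroupCurve]:
    """Per-arm mean/SEM RTV curves plus the per-day ratio to the control arm.

    Means are taken over the animals still measured on each day (shrinking-n
    follow-up); a day with zero animals in an arm is dropped from that arm's
    curve. The control arm's own ratio_to_control is identically 1.
    """
    per_animal = animal_table(cohort)
    control_mean: dict[float, float] = {}
    ctrl = per_animal[per_animal["group"] == cohort.control_group]
    for day, sub in ctrl.groupby("day"):
        control_mean[day] = float(sub["rtv"].mean())

    curves = []
    for group in cohort.groups:
        sub = per_animal[per_animal["group"] == group]
        days, means, sems, ns, ratios = [], [], [], [], []
        for day, g in sub.groupby("day"):
            vals = g["rtv"].to_numpy()
            if len(vals) == 0:
                logger.warning("arm %s: no animals measured on day %s", group, day)
                continue
            days.append(day)
            means.append(float(vals.mean()))
            sems.append(_sem(vals))
            ns.append(len(vals))
            if group == cohort.control_group:
                ratios.append(1.0)
            elif day in control_mean:
                ratios.append(means[-1] / control_mean[day])
            else:
                ratios.append(np.nan)
        curves.append(
            GroupCurve(
                group=group,
                days=np.asarray(days, dtype=float),
                mean_rtv=np.asarray(means),
                sem_rtv=np.asarray(sems),
                n=np.asarray(ns, dtype=int),
                ratio_to_control=np.asarray(ratios),
            )
        )
    return curves


def group_table(cohort: Cohort) -> pd.DataFrame:
    """Tidy per-group table: group, day, mean_rtv, sem_rtv, n, ratio_to_control."""
    rows = []
    for c in summarise_groups(cohort):
        for i, day in enumerate(c.days):
            rows.append(
                {
                    "group": c.group,
                    "day": day,
                    "mean_rtv": c.mean_rtv[i],
                    "sem_rtv": c.sem_rtv[i],
                    "n": c.n[i],
                    "ratio_to_control": c.ratio_to_control[i],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV interface
# ---------------------------------------------------------------------------

MEASUREMENT_COLUMNS = ["animal_id", "group", "day", "length_mm", "width_mm", "height_mm"]


def cohort_from_frame(df: pd.DataFrame, control_group: str) -> Cohort:
    """Build a :class:`Cohort` from a tidy measurement table.

    Required columns: animal_id, group, day, length_mm, width_mm, height_mm.
    Optional columns: fate ("followed-to-end" / "killed"), fate_day. NaN in
    all three dimension columns marks a missed visit.
    """
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"measurement table missing columns: {missing}")
    series = []
    for (animal, group), sub in df.groupby(["animal_id", "group"], sort=False):
        sub = sub.sort_values("day")
        ms = []
        for _, r in sub.iterrows():
            dims = [r["length_mm"], r["width_mm"], r["height_mm"]]
            if all(pd.isna(d) for d in dims):
                ms.append(Measurement(day=float(r["day"])))
            else:
                ms.append(
                    Measurement(
                        day=float(r["day"]),
                        length=float(r["length_mm"]),
                        width=float(r["width_mm"]),
                        height=float(r["height_mm"]),
                    )
                )
        fate = FATE_FOLLOWED
        fate_day = None
        if "fate" in sub.columns and not pd.isna(sub["fate"].iloc[0]):
            fate = str(sub["fate"].iloc[0])
        if "fate_day" in sub.columns and not pd.isna(sub["fate_day"].iloc[0]):
            fate_day = float(sub["fate_day"].iloc[0])
        if fate == FATE_FOLLOWED and fate_day is None:
            fate_day = ms[-1].day if ms else 0.0
        series.append(
            MeasurementSeries(
                animal_id=str(animal), group=str(group), measurements=ms,
                fate=fate, fate_day=fate_day,
            )
        )
    return Cohort(series=series, control_group=control_group)


def read_measurements_csv(path, control_group: str) -> Cohort:
    """Read a measurement CSV (UTF-8, header required) into a Cohort."""
    return cohort_from_frame(pd.read_csv(path), control_group)


def cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    """Inverse of :func:`cohort_from_frame` (round-trips the cohort)."""
    rows = []
    for s in cohort.series:
        for m in s.measurements:
            rows.append(
                {
                    "animal_id": s.animal_id,
                    "group": s.group,
                    "day": m.day,
                    "length_mm": m.length,
                    "width_mm": m.width,
                    "height_mm": m.height,
                    "fate": s.fate,
                    "fate_day": s.fate_day,
                }
            )
    return pd.DataFrame(rows)
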