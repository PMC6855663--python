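"""Bliss-independence interaction analysis of combination therapy.

From per-day group-mean relative tumour volumes (RTVs): the fractional
response of an arm is F = 1 - RTV_arm / RTV_control; under Bliss
independence two monotherapies combine to the predicted additive fraction
F_add = F_rad + F_gem - F_rad*F_gem, equivalently 1 - (1-F_rad)(1-F_gem).
The observed combination fraction above / equal to / below F_add is
classified synergistic / additive / antagonistic, with an optional
tolerance band for noisy data.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

SYNERGISTIC = "synergistic"
ADDITIVE = "additive"
ANTAGONISTIC = "antagonistic"


@dataclass(frozen=True)
class InteractionResult:
    day: float
    f_rad: float
    f_gem: float
    f_add: float
    f_obs: float
    rtv_predicted_additive: float
    classification: str


def fractional_response(rtv_arm: float, rtv_control: float) -> float:
    """F = 1 - RTV_arm / RTV_control.

    May be negative (arm grew faster than control) or exceed 1; such values
    are passed through unclamped with a warning since the probabilistic
    reading of Bliss independence breaks outside [0, 1].
    """
    if rtv_control <= 0:
        raise ValueError("control RTV must be positive")
    f = 1.0 - rtv_arm / rtv_control
    if not (0.0 <= f <= 1.0):
        warnings.warn(
            f"fractional response {f:.3f} outside [0, 1]; Bliss independence "
            "is only interpretable on [0, 1]",
            stacklevel=2,
        )
    return f


def bliss_additive(f_rad: float, f_gem: float) -> float:
    """Predicted additive fraction F_add = F_rad + F_gem - F_rad*F_gem."""
    for name, f in (("f_rad", f_rad), ("f_gem", f_gem)):
        if not (0.0 <= f <= 1.0):
            warnings.warn(f"{name}={f:.3f} outside [0, 1]", stacklevel=2)
    return f_rad + f_gem - f_rad * f_gem


def predicted_additive_rtv(f_add: float, rtv_control: float) -> float:
    """RTV a Bliss-additive combination would show: (1 - F_add)*RTV_control."""
    if rtv_control <= 0:
        raise ValueError("control RTV must be positive")
    return (1.0 - f_add) * rtv_control


def classify_interaction(f_obs: float, f_add: float, tolerance: float = 0.0) -> str:
    """Synergistic / additive / antagonistic by comparing F_obs with F_add.

    ``tolerance`` widens the "additive" band (exact equality is measure-zero
    on real data; the default 0 reproduces the strict comparison).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    if f_obs > f_add + tolerance:
        return SYNERGISTIC
    if f_obs < f_add - tolerance:
        return ANTAGONISTIC
    return ADDITIVE


def evaluate_interaction(
    group_table: pd.DataFrame,
    rad_arm: str,
    gem_arm: str,
    combo_arm: str,
    control_arm: str,
    tolerance: float = 0.0,
) -> pd.DataFrame:
    """Per-day Bliss analysis on group-mean RTVs.

    ``group_table`` is the tidy per-group summary (columns group, day,
    mean_rtv). Only days on which all four arms were measured are evaluated.
    Returns one row per day: f_rad, f_gem, f_add, f_obs,
    rtv_predicted_additive, classification.
    """
    means = group_table.pivot_table(index="day", columns="group", values="mean_rtv")
    needed = [control_arm, rad_arm, gem_arm, combo_arm]
    missing = [a for a in needed if a not in means.columns]
    if missing:
        raise ValueError(f"arms absent from group table: {missing}")
    means = means.dropna(subset=needed)
    rows = []
    for day, r in means.iterrows():
        if day == 0:
            continue
        rtv_c = r[control_arm]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f_rad = fractional_response(r[rad_arm], rtv_c)
            f_gem = fractional_response(r[gem_arm], rtv_c)
            f_add = bliss_additive(f_rad, f_gem)
            f_obs = fractional_response(r[combo_arm], rtv_c)
        rows.append(
            InteractionResult(
                day=float(day),
                f_rad=f_rad,
                f_gem=f_gem,
                f_add=f_add,
                f_obs=f_obs,
                rtv_predicted_additive=predicted_additive_rtv(f_add, rtv_c),
                classification=classify_interaction(f_obs, f_add, tolerance),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])
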