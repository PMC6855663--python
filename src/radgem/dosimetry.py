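"""MIRD internal dosimetry from time-activity concentration data.

Mean absorbed dose D = A_tilde * sum_i(E_i * Y_i) * phi_i / M, with the
time-integrated activity A_tilde obtained by fitting a mono-exponential
C(t) = C0 * exp(-lambda_eff * t) to tracer concentration data and
integrating analytically from injection (t = 0) to infinity. When the
input is an activity *concentration* (per gram) the mass term is implicit
and the dose comes out per unit tissue mass directly.

Defaults model the beta-only contribution of 177Lu: energy per decay
147.9 keV, absorbed fraction 1. Also provides the body-surface-area
conversion of animal drug doses (mg/kg) to human-equivalent doses (mg/m^2).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize

#: decays per MBq*h
DECAYS_PER_MBQ_H = 3.6e9
#: joules per keV
JOULES_PER_KEV = 1.602e-16
#: grams per kilogram (concentration per g -> dose per kg)
G_PER_KG = 1.0e3

#: beta-only energy emitted per decay of 177Lu, keV
LU177_BETA_KEV = 147.9
#: body-surface-area Km factor for mouse
MOUSE_KM_FACTOR = 3.0

UNIT_MBQ_PER_G = "MBq_per_g"
UNIT_PERCENT_IA_PER_G = "percent_IA_per_g"


class DivergentIntegralError(ValueError):
    """The fitted curve does not decay; its 0-to-infinity integral diverges."""


@dataclass
class TimeActivitySeries:
    """Tracer activity concentration vs time for one tissue."""

    times_h: np.ndarray
    concentrations: np.ndarray
    unit: str = UNIT_MBQ_PER_G
    injected_mbq: Optional[float] = None

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times_h.shape != self.concentrations.shape:
            raise ValueError("times and concentrations differ in length")
        if np.any(np.diff(self.times_h) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.times_h < 0):
            raise ValueError("negative time")
        if self.unit not in (UNIT_MBQ_PER_G, UNIT_PERCENT_IA_PER_G):
            raise ValueError(f"unknown unit {self.unit!r}")

    def in_mbq_per_g(self) -> "TimeActivitySeries":
        """Convert %IA/g input to MBq/g using the injected activity."""
        if self.unit == UNIT_MBQ_PER_G:
            return self
        if self.injected_mbq is None:
            raise ValueError("percent_IA_per_g input requires injected_mbq")
        return TimeActivitySeries(
            times_h=self.times_h,
            concentrations=self.concentrations / 100.0 * self.injected_mbq,
            unit=UNIT_MBQ_PER_G,
        )


@dataclass
class DoseParameters:
    """Energy per decay (keV), absorbed fraction, optional tissue mass (g)."""

    energy_per_decay_kev: float = LU177_BETA_KEV
    absorbed_fraction: float = 1.0
    mass_g: Optional[float] = None

    def __post_init__(self) -> None:
        if self.energy_per_decay_kev <= 0:
            raise ValueError("energy per decay must be positive")
        if not (0 < self.absorbed_fraction <= 1):
            raise ValueError("absorbed fraction must be in (0, 1]")


@dataclass
class DoseResult:
    c0: float
    lambda_eff_per_h: float
    half_life_h: float
    a_tilde_mbq_h_per_g: float
    dose_gy: float


def fit_monoexponential(
    series: TimeActivitySeries, method: str = "loglinear"
) -> tuple[float, float]:
    """Fit C(t) = C0*exp(-lambda*t); returns (C0, lambda_eff in 1/h).

    Default is ordinary least squares on log concentrations; ``method="nls"``
    runs nonlinear least squares (initialised from the log-linear fit) for
    sensitivity checks. A non-decaying fit (lambda <= 0) is an error because
    the 0-to-infinity integral would diverge.
    """
    s = series.in_mbq_per_g()
    if len(s.times_h) < 2:
        raise ValueError("need at least 2 points to fit")
    if np.any(s.concentrations <= 0):
        raise ValueError("concentrations must be strictly positive")
    slope, intercept = np.polyfit(s.times_h, np.log(s.concentrations), 1)
    c0, lam = float(np.exp(intercept)), float(-slope)
    if method == "nls":
        popt, _ = optimize.curve_fit(
            lambda t, c, l: c * np.exp(-l * t),
            s.times_h, s.concentrations, p0=[c0, max(lam, 1e-6)],
        )
        c0, lam = float(popt[0]), float(popt[1])
    elif method != "loglinear":
        raise ValueError(f"unknown fit method {method!r}")
    if lam <= 0:
        raise DivergentIntegralError(
            f"fitted effective decay constant {lam:.4g}/h is not positive"
        )
    return c0, lam


def time_integrated_activity(c0: float, lambda_eff: float) -> float:
    """A_tilde = C0/lambda: integral of C0*exp(-lambda*t) from 0 to infinity."""
    if lambda_eff <= 0:
        raise DivergentIntegralError("lambda_eff must be positive")
    return c0 / lambda_eff


def mean_absorbed_dose(
    a_tilde_mbq_h_per_g: float, params: DoseParameters = DoseParameters()
) -> float:
    """Mean absorbed dose in Gy from a time-integrated activity concentration.

    dose = A_tilde[MBq*h/g] * 3.6e9[decays/MBq*h] * E[keV] * 1.602e-16[J/keV]
           * phi * 1e3[g/kg]
    """
    if a_tilde_mbq_h_per_g < 0:
        raise ValueError("a_tilde must be non-negative")
    return (
        a_tilde_mbq_h_per_g
        * DECAYS_PER_MBQ_H
        * params.energy_per_decay_kev
        * JOULES_PER_KEV
        * params.absorbed_fraction
        * G_PER_KG
    )


def absorbed_dose_from_series(
    series: TimeActivitySeries,
    params: DoseParameters = DoseParameters(),
    method: str = "loglinear",
) -> DoseResult:
    """Full chain: fit -> integrate -> dose, with the effective half-life."""
    c0, lam = fit_monoexponential(series, method=method)
    a_tilde = time_integrated_activity(c0, lam)
    return DoseResult(
        c0=c0,
        lambda_eff_per_h=lam,
        half_life_h=float(np.log(2) / lam),
        a_tilde_mbq_h_per_g=a_tilde,
        dose_gy=mean_absorbed_dose(a_tilde, params),
    )


def human_equivalent_dose(
    animal_dose_mg_per_kg: float, km_factor: float = MOUSE_KM_FACTOR
) -> float:
    """Body-surface-area scaling of an animal drug dose to mg/m^2.

    For mouse (Km = 3) a 60 mg/kg dose corresponds to 180 mg/m^2 in humans.
    """
    if animal_dose_mg_per_kg < 0:
        raise ValueError("dose must be non-negative")
    if km_factor <= 0:
        raise ValueError("Km factor must be positive")
    return animal_dose_mg_per_kg * km_factor
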