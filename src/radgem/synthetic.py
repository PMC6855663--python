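"""Synthetic study data with known ground truth.

Generates the three kinds of input the analysis modules consume:

* tumour-growth cohorts — per-animal two-compartment kinetics
  V(t) = V0 * v_gem(t) * [f_s_eff*exp(g*t) + (1 - f_s_eff)*exp(-d*t)] * eps(t),
  where f_s_eff is the radiation surviving fraction (times an interaction
  multiplier iota on combination arms), v_gem(t) is a whole-tumour
  gemcitabine growth-modification factor accumulated during the
  twice-weekly dosing window, and eps is lognormal multiplicative calliper
  noise. Because the drug factor multiplies both compartments, monotherapy
  effects combine independently on the RTV scale and iota = 1 yields an
  exactly Bliss-additive combination arm in the noiseless model; iota < 1
  injects extra killing (synergy). Volumes are re-expressed as calliper
  triples whose product round-trips the volume exactly.
* mono-exponential tracer washout with lognormal noise.
* paired MT / Ki67 stained-section images with exactly known positive-pixel
  fractions, a necrotic disc, crack/fold artefacts and a known similarity
  transform between the sections plus matching control points.

All generators are pure functions of (config, seed).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from skimage import draw as _skdraw
from skimage import transform as _sktransform

from .dosimetry import TimeActivitySeries
from .growth import (
    ELLIPSOID_FACTOR,
    FATE_FOLLOWED,
    FATE_KILLED,
    Cohort,
    Measurement,
    MeasurementSeries,
)
from .histology import ControlPointSet, StainedSection, STAIN_KI67, STAIN_MT

# ---------------------------------------------------------------------------
# Growth cohorts
# ---------------------------------------------------------------------------

#: twice-weekly visit schedule out to day 58 (longest follow-up arm)
DEFAULT_SCHEDULE = (0, 3, 7, 10, 13, 16, 20, 23, 27, 30, 34, 37, 41, 44, 48, 51, 55, 58)


@dataclass(frozen=True)
class ArmConfig:
    """One treatment arm of the growth simulator.

    ``surviving_fraction`` < 1 models an acute radiation effect (the
    complement regresses at ``regression_rate`` from the model config);
    ``gem_multiplier`` scales the growth rate during the gemcitabine dosing
    window (1 = no drug; negative values mean net regression while dosing);
    ``interaction`` (iota) multiplies the surviving fraction on combination
    arms — 1 keeps the two effects independent, < 1 injects extra killing
    (synergy). ``weight_loss_hazard`` is a per-day hazard of toxicity kill.
    """

    name: str
    n: int
    follow_up: float
    surviving_fraction: float = 1.0
    gem_multiplier: float = 1.0
    interaction: float = 1.0
    weight_loss_hazard: float = 0.0

    def __post_init__(self) -> None:
        if not (0 < self.surviving_fraction * self.interaction <= 1):
            raise ValueError(
                f"arm {self.name}: effective surviving fraction must be in (0, 1]"
            )
        if self.n < 1 or self.follow_up <= 0 or self.weight_loss_hazard < 0:
            raise ValueError(f"arm {self.name}: invalid n/follow_up/hazard")


@dataclass(frozen=True)
class GrowthModelConfig:
    """Study-level growth-model parameters (rates in 1/day, volumes in mm^3).

    Defaults emulate a subcutaneous xenograft study: baseline volumes
    lognormal with mean 570 and SD 406 mm^3, control doubling time ~16 d,
    gemcitabine dosed twice weekly on days 0-13, and a kill rule at an
    absolute volume cap standing in for the "tumour exceeds 10% of body
    weight" criterion (~2500 mm^3 for a 25 g mouse at unit density).
    """

    arms: tuple[ArmConfig, ...]
    baseline_mean_mm3: float = 570.0
    baseline_sd_mm3: float = 406.0
    growth_rate: float = 0.042
    regression_rate: float = 0.12
    gem_window: tuple[float, float] = (0.0, 13.0)
    noise_cv: float = 0.15
    schedule: tuple[float, ...] = DEFAULT_SCHEDULE
    kill_volume_cap_mm3: float = 2500.0
    anisotropy_jitter: float = 0.2

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise CV must be non-negative")
        names = [a.name for a in self.arms]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate arm names: {names}")


def _lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(mu, sigma) of a lognormal with the given natural-scale mean and SD."""
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    return math.log(mean) - sigma2 / 2.0, math.sqrt(sigma2)


def _growth_exponent(t: float, g: float, gem_multiplier: float,
                     window: tuple[float, float]) -> float:
    """Integral of the growth rate to time t with the gem window applied."""
    lo, hi = window
    in_window = max(0.0, min(t, hi) - lo)
    outside = t - in_window
    return g * gem_multiplier * in_window + g * outside


def noiseless_rtv(arm: ArmConfig, config: GrowthModelConfig, t: float) -> float:
    """Deterministic model RTV at time t (independent of V0).

    The gemcitabine factor v_gem = exp(G(t) - g*t) multiplies both the
    surviving and the regressing compartment (the drug acts on all tumour
    cells), so an arm combining radiation and drug with interaction 1 has
    RTV_combo/RTV_control = (RTV_rad/RTV_control)*(RTV_gem/RTV_control)
    exactly — the Bliss-independence null.
    """
    g = config.growth_rate
    fs = arm.surviving_fraction * arm.interaction
    gexp = _growth_exponent(t, g, arm.gem_multiplier, config.gem_window)
    v_gem = math.exp(gexp - g * t)
    return v_gem * (
        fs * math.exp(g * t)
        + (1.0 - fs) * math.exp(-config.regression_rate * t)
    )


def _calliper_triple(volume: float, rng: np.random.Generator,
                     jitter: float) -> tuple[float, float, float]:
    """Invert V = (pi/6) l w h with anisotropy jitter; product is exact."""
    base = (volume / ELLIPSOID_FACTOR) ** (1.0 / 3.0)
    a = math.exp(rng.uniform(-jitter, jitter))
    b = math.exp(rng.uniform(-jitter, jitter))
    return base * a, base * b, base / (a * b)


def simulate_growth_cohort(config: GrowthModelConfig, seed: int,
                           control_arm: Optional[str] = None) -> Cohort:
    """Simulate a full cohort; reproducible for a fixed (config, seed).

    The control arm defaults to the first arm whose parameters are all
    neutral (surviving_fraction = gem_multiplier = interaction = 1).
    """
    rng = np.random.default_rng(seed)
    if control_arm is None:
        neutral = [a.name for a in config.arms
                   if a.surviving_fraction == 1.0 and a.gem_multiplier == 1.0
                   and a.interaction == 1.0]
        if not neutral:
            raise ValueError("no neutral arm found; pass control_arm explicitly")
        control_arm = neutral[0]
    if control_arm not in {a.name for a in config.arms}:
        raise ValueError(f"control arm {control_arm!r} not among configured arms")

    mu, sigma = _lognormal_params(config.baseline_mean_mm3, config.baseline_sd_mm3)
    sigma_eps = math.sqrt(math.log(1.0 + config.noise_cv**2))
    series = []
    for arm in config.arms:
        for i in range(arm.n):
            animal_id = f"{arm.name}-{i + 1:02d}"
            v0 = float(np.exp(rng.normal(mu, sigma)))
            days = [d for d in config.schedule if d <= arm.follow_up]
            measurements = []
            fate, fate_day = FATE_FOLLOWED, float(arm.follow_up)
            prev_day = 0.0
            for day in days:
                if arm.weight_loss_hazard > 0 and day > 0:
                    p_kill = 1.0 - math.exp(-arm.weight_loss_hazard * (day - prev_day))
                    if rng.random() < p_kill:
                        fate, fate_day = FATE_KILLED, float(day)
                        break
                prev_day = day
                v = v0 * noiseless_rtv(arm, config, day)
                if config.noise_cv > 0:
                    v *= float(np.exp(rng.normal(-sigma_eps**2 / 2.0, sigma_eps)))
                l, w, h = _calliper_triple(v, rng, config.anisotropy_jitter)
                measurements.append(Measurement(day=float(day), length=l,
                                                width=w, height=h))
                if day > 0 and v > config.kill_volume_cap_mm3:
                    fate, fate_day = FATE_KILLED, float(day)
                    break
            series.append(
                MeasurementSeries(animal_id=animal_id, group=arm.name,
                                  measurements=measurements, fate=fate,
                                  fate_day=fate_day)
            )
    return Cohort(series=series, control_group=control_arm)


def study_like_arms() -> tuple[ArmConfig, ...]:
    """The seven-arm layout of the emulated study design.

    Monotherapy effect sizes are calibrated so that, in the noiseless
    model, the gemcitabine arm's RTV ratio to control plateaus near 0.5
    after the dosing window and the radiotherapy arm's RTV dips to a nadir
    of ~0.6 around day 13 before regrowing at the control rate.
    """
    return (
        ArmConfig("control", n=12, follow_up=30),
        ArmConfig("Lu", n=5, follow_up=16, surviving_fraction=0.98),
        ArmConfig("Gem high", n=5, follow_up=16, gem_multiplier=-0.55),
        ArmConfig("Lu + Gem high", n=5, follow_up=16, surviving_fraction=0.98,
                  gem_multiplier=-0.55, weight_loss_hazard=0.01),
        ArmConfig("EBRT", n=5, follow_up=44, surviving_fraction=0.25),
        ArmConfig("Gem low", n=10, follow_up=44, gem_multiplier=-0.36),
        ArmConfig("EBRT + Gem low", n=6, follow_up=58, surviving_fraction=0.25,
                  gem_multiplier=-0.36),
    )


# ---------------------------------------------------------------------------
# Tracer kinetics
# ---------------------------------------------------------------------------

def simulate_time_activity(
    c0: float,
    lambda_eff: float,
    times_h: Sequence[float],
    noise_cv: float,
    seed: int,
) -> TimeActivitySeries:
    """Mono-exponential washout with lognormal multiplicative noise."""
    if lambda_eff <= 0:
        raise ValueError("lambda_eff must be positive")
    if noise_cv < 0:
        raise ValueError("noise CV must be non-negative")
    t = np.asarray(times_h, dtype=float)
    conc = c0 * np.exp(-lambda_eff * t)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv**2))
        conc = conc * np.exp(rng.normal(-sigma**2 / 2.0, sigma, size=t.shape))
    return TimeActivitySeries(times_h=t, concentrations=conc)


# ---------------------------------------------------------------------------
# Stained-section pairs
# ---------------------------------------------------------------------------

#: renderer palette (RGB), matched to the default ColourThresholds
PALETTE = {
    "glass": (250, 250, 250),
    "crack": (246, 246, 244),
    "fold": (45, 40, 50),
    "mt_viable": (190, 85, 125),
    "mt_necrosis": (230, 195, 205),
    "mt_collagen": (70, 100, 205),
    "ki67_counterstain": (110, 95, 185),
    "ki67_positive": (145, 82, 38),
    "ki67_necrosis": (230, 195, 205),
}

# label codes in the section layout map
_L_OUTSIDE, _L_VIABLE, _L_NECROTIC, _L_CRACK, _L_FOLD = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class SectionLayoutConfig:
    """Layout of a rendered MT/Ki67 section pair (fractions in [0, 1])."""

    seed: int
    size: tuple[int, int] = (384, 384)
    necrotic_fraction: float = 0.2
    ki67_positive_fraction: float = 0.64
    mt_collagen_fraction: float = 0.03
    n_cracks: int = 3
    n_folds: int = 2
    rotation_deg: float = 3.0
    scale: float = 1.0
    translation: tuple[float, float] = (6.0, -4.0)
    #: rendered canvases are a downsampled overview of a section, not a
    #: native 0.25 um/px scan: 4 um/px keeps physical-area parameters
    #: (e.g. the necrosis minimum region area) meaningful on a small raster
    pixel_size_um: float = 4.0
    colour_jitter: int = 4

    def __post_init__(self) -> None:
        for name in ("necrotic_fraction", "ki67_positive_fraction",
                     "mt_collagen_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass(frozen=True)
class SectionGroundTruth:
    """What the renderer actually placed, for round-trip validation."""

    necrotic_fraction: float
    ki67_positive_fraction: float
    mt_collagen_fraction: float
    transform_params: np.ndarray


def _ellipse_polygon(cx: float, cy: float, rx: float, ry: float,
                     n: int = 72) -> np.ndarray:
    th = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return np.column_stack([cx + rx * np.cos(th), cy + ry * np.sin(th)])


def _paint(canvas: np.ndarray, mask: np.ndarray, colour: tuple[int, int, int],
           rng: np.random.Generator, jitter: int) -> None:
    n = int(mask.sum())
    block = np.tile(np.array(colour, dtype=float), (n, 1))
    if jitter > 0:
        block += rng.integers(-jitter, jitter + 1, size=block.shape)
    canvas[mask] = np.clip(block, 0, 255).astype(np.uint8)


def _choose_exact(rng: np.random.Generator, within: np.ndarray,
                  fraction: float) -> np.ndarray:
    """Boolean mask selecting exactly round(fraction * |within|) pixels."""
    idx = np.flatnonzero(within.ravel())
    k = int(round(fraction * len(idx)))
    chosen = rng.choice(idx, size=k, replace=False)
    out = np.zeros(within.size, dtype=bool)
    out[chosen] = True
    return out.reshape(within.shape)


def render_section_pair(
    layout: SectionLayoutConfig,
) -> tuple[StainedSection, StainedSection, ControlPointSet, SectionGroundTruth]:
    """Render a matched MT / Ki67 section pair with exact ground truth.

    The tissue layout (elliptical tumour ROI, one necrotic disc, crack and
    fold artefacts) is built on the MT raster; the Ki67 raster is the same
    layout pushed through a known similarity transform. Positive pixels are
    drawn to hit the configured fractions exactly on the rendered rasters:
    MT collagen as a fraction of all artefact-free tissue, Ki67 positivity
    as a fraction of viable (non-necrotic) tissue. Control points are four
    landmarks mapped through the embedded transform.
    """
    rng = np.random.default_rng(layout.seed)
    h, w = layout.size
    cy, cx = h / 2.0, w / 2.0
    ry, rx = 0.40 * h, 0.42 * w

    labels = np.full((h, w), _L_OUTSIDE, dtype=np.uint8)
    rr, cc = _skdraw.ellipse(cy, cx, ry, rx, shape=(h, w))
    labels[rr, cc] = _L_VIABLE
    roi_area = len(rr)

    if layout.necrotic_fraction > 0:
        r_nec = math.sqrt(layout.necrotic_fraction * roi_area / math.pi)
        if r_nec > min(rx, ry) * 0.9:
            raise ValueError("necrotic fraction too large for the ROI layout")
        ncy = cy + rng.uniform(-0.2, 0.2) * ry
        ncx = cx + rng.uniform(-0.2, 0.2) * rx
        rr, cc = _skdraw.disk((ncy, ncx), r_nec, shape=(h, w))
        inside = labels[rr, cc] == _L_VIABLE
        labels[rr[inside], cc[inside]] = _L_NECROTIC

    for _ in range(layout.n_cracks):
        r0, c0 = rng.integers(0, h), rng.integers(0, w)
        r1, c1 = rng.integers(0, h), rng.integers(0, w)
        rr, cc = _skdraw.line(int(r0), int(c0), int(r1), int(c1))
        for dr in (-1, 0, 1):
            rs = np.clip(rr + dr, 0, h - 1)
            labels[rs, cc] = np.where(labels[rs, cc] != _L_OUTSIDE, _L_CRACK,
                                      labels[rs, cc])
    for _ in range(layout.n_folds):
        fr = rng.integers(int(cy - ry * 0.7), int(cy + ry * 0.7))
        fc = rng.integers(int(cx - rx * 0.7), int(cx + rx * 0.7))
        rr, cc = _skdraw.ellipse(fr, fc, 4, 18, shape=(h, w),
                                 rotation=float(rng.uniform(0, np.pi)))
        inside = labels[rr, cc] != _L_OUTSIDE
        labels[rr[inside], cc[inside]] = _L_FOLD

    # known similarity transform, MT (moving) -> Ki67 (fixed)
    tform = _sktransform.SimilarityTransform(
        scale=layout.scale,
        rotation=math.radians(layout.rotation_deg),
        translation=layout.translation,
    )
    ki_labels = _sktransform.warp(
        labels, inverse_map=tform.inverse, output_shape=(h, w), order=0,
        cval=_L_OUTSIDE, preserve_range=True,
    ).astype(np.uint8)

    # ---- MT render ----
    mt_img = np.empty((h, w, 3), dtype=np.uint8)
    _paint(mt_img, labels == _L_OUTSIDE, PALETTE["glass"], rng, layout.colour_jitter)
    _paint(mt_img, labels == _L_VIABLE, PALETTE["mt_viable"], rng, layout.colour_jitter)
    _paint(mt_img, labels == _L_NECROTIC, PALETTE["mt_necrosis"], rng,
           layout.colour_jitter)
    _paint(mt_img, labels == _L_CRACK, PALETTE["crack"], rng, layout.colour_jitter)
    _paint(mt_img, labels == _L_FOLD, PALETTE["fold"], rng, layout.colour_jitter)
    mt_tissue = (labels == _L_VIABLE) | (labels == _L_NECROTIC)
    collagen = _choose_exact(rng, mt_tissue, layout.mt_collagen_fraction)
    _paint(mt_img, collagen, PALETTE["mt_collagen"], rng, layout.colour_jitter)

    # ---- Ki67 render ----
    ki_img = np.empty((h, w, 3), dtype=np.uint8)
    _paint(ki_img, ki_labels == _L_OUTSIDE, PALETTE["glass"], rng,
           layout.colour_jitter)
    _paint(ki_img, ki_labels == _L_VIABLE, PALETTE["ki67_counterstain"], rng,
           layout.colour_jitter)
    _paint(ki_img, ki_labels == _L_NECROTIC, PALETTE["ki67_necrosis"], rng,
           layout.colour_jitter)
    _paint(ki_img, ki_labels == _L_CRACK, PALETTE["crack"], rng,
           layout.colour_jitter)
    _paint(ki_img, ki_labels == _L_FOLD, PALETTE["fold"], rng, layout.colour_jitter)
    ki_viable = ki_labels == _L_VIABLE
    positive = _choose_exact(rng, ki_viable, layout.ki67_positive_fraction)
    _paint(ki_img, positive, PALETTE["ki67_positive"], rng, layout.colour_jitter)

    # ROI polygons: slightly inside the tissue ellipse so the polygon never
    # clips tissue at the raster boundary after transformation
    mt_roi = _ellipse_polygon(cx, cy, rx + 2, ry + 2)
    mt_roi[:, 0] = np.clip(mt_roi[:, 0], 0, w - 1)
    mt_roi[:, 1] = np.clip(mt_roi[:, 1], 0, h - 1)
    ki_roi = tform(mt_roi)
    ki_roi[:, 0] = np.clip(ki_roi[:, 0], 0, w - 1)
    ki_roi[:, 1] = np.clip(ki_roi[:, 1], 0, h - 1)

    moving = np.array(
        [[cx - rx, cy], [cx + rx, cy], [cx, cy - ry], [cx, cy + ry]], dtype=float
    )
    points = ControlPointSet(moving=moving, fixed=tform(moving))

    mt = StainedSection(image=mt_img, stain=STAIN_MT, roi=mt_roi,
                        pixel_size_um=layout.pixel_size_um)
    ki = StainedSection(image=ki_img, stain=STAIN_KI67, roi=ki_roi,
                        pixel_size_um=layout.pixel_size_um)
    truth = SectionGroundTruth(
        necrotic_fraction=float((labels == _L_NECROTIC).sum() / mt_tissue.sum()
                                if mt_tissue.sum() else 0.0),
        ki67_positive_fraction=float(positive.sum() / ki_viable.sum()
                                     if ki_viable.sum() else 0.0),
        mt_collagen_fraction=float(collagen.sum() / mt_tissue.sum()
                                   if mt_tissue.sum() else 0.0),
        transform_params=tform.params.copy(),
    )
    return mt, ki, points, truth
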