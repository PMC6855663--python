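"""Quantitative IHC analysis of stained tumour sections.

Reimplements a digital-pathology workflow for paired tumour sections:
colour-threshold segmentation of a Masson's-trichrome (MT) and a Ki67
(DAB) section inside a hand-drawn tumour ROI, removal of crack (near-white)
and fold (over-dark) artefacts, automatic necrotic/viable partition of the
MT section, landmark (control-point) registration of the MT section onto
the Ki67 section so the viable mask can be transferred, and area-fraction
quantification: Ki67 positivity within viable tumour only, MT collagen
positivity over the whole tumour section (artefacts excluded).

Colour classification runs on an HSV representation with fully
user-overridable thresholds; the shipped defaults are calibrated against
the synthetic section renderer in :mod:`radgem.synthetic` and are a
starting point, not a validated clinical calibration — on real slides the
thresholds are a manual, pathologist-approved step.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from skimage import color as _skcolor
from skimage import draw as _skdraw
from skimage import measure as _skmeasure
from skimage import morphology as _skmorph
from skimage import transform as _sktransform

logger = logging.getLogger(__name__)

STAIN_MT = "MT"
STAIN_KI67 = "Ki67"

#: default scanner resolution, micrometres per pixel (40x slide scan)
DEFAULT_PIXEL_SIZE_UM = 0.25


@dataclass
class ColourThresholds:
    """HSV ranges defining the colour classes.

    Hue, saturation and value are on [0, 1]. Background (cracks / bare
    glass) is near-white: low saturation at high value. Folds are over-dark.
    Positive stain is brown (DAB) for Ki67 and blue (collagen) for MT;
    necrosis on MT is the pale, eosin-dominant class.
    """

    background_s_max: float = 0.10
    background_v_min: float = 0.85
    fold_v_max: float = 0.28
    dab_hue: tuple[float, float] = (0.0, 0.14)
    dab_s_min: float = 0.35
    collagen_hue: tuple[float, float] = (0.50, 0.78)
    collagen_s_min: float = 0.30
    necrosis_s_range: tuple[float, float] = (0.10, 0.38)
    necrosis_v_min: float = 0.70


@dataclass
class StainedSection:
    """One digitised stained section with its tumour ROI polygon.

    ``roi`` is an (N, 2) array of (x, y) pixel-centre coordinates (origin
    top-left, x right, y down, 0-based) delineating the tumour and
    excluding the capsule.
    """

    image: np.ndarray
    stain: str
    roi: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError("image must be RGB (H, W, 3)")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        self.roi = np.asarray(self.roi, dtype=float)
        if self.roi.ndim != 2 or self.roi.shape[1] != 2 or len(self.roi) < 3:
            raise ValueError("roi must be an (N>=3, 2) polygon")
        h, w = self.image.shape[:2]
        if (self.roi < -0.5).any() or (self.roi[:, 0] > w - 0.5).any() or (
            self.roi[:, 1] > h - 0.5
        ).any():
            raise ValueError("roi extends beyond the image bounds")

    def roi_mask(self) -> np.ndarray:
        # polygon2mask takes (row, col) vertices
        return _skdraw.polygon2mask(self.image.shape[:2], self.roi[:, ::-1])


@dataclass
class TissueMasks:
    """Binary masks from one section; all of identical shape.

    Invariants: positive is a subset of tissue; once the necrotic/viable
    partition exists, necrotic and viable are disjoint and their union is
    the tissue mask.
    """

    background_artefact: np.ndarray
    tissue: np.ndarray
    positive: np.ndarray
    necrotic: Optional[np.ndarray] = None
    viable: Optional[np.ndarray] = None
    necrosis_candidate: Optional[np.ndarray] = field(default=None, repr=False)

    def validate(self) -> None:
        if np.any(self.positive & ~self.tissue):
            raise AssertionError("positive pixels outside tissue")
        if np.any(self.background_artefact & self.tissue):
            raise AssertionError("tissue overlaps artefacts")
        if self.necrotic is not None and self.viable is not None:
            if np.any(self.necrotic & self.viable):
                raise AssertionError("necrotic and viable overlap")
            if np.any((self.necrotic | self.viable) != self.tissue):
                raise AssertionError("necrotic + viable does not tile tissue")


@dataclass
class ControlPointSet:
    """Paired landmark coordinates: moving (MT) -> fixed (Ki67), (x, y)."""

    moving: np.ndarray
    fixed: np.ndarray

    def __post_init__(self) -> None:
        self.moving = np.asarray(self.moving, dtype=float)
        self.fixed = np.asarray(self.fixed, dtype=float)
        if self.moving.shape != self.fixed.shape or self.moving.ndim != 2:
            raise ValueError("moving and fixed must be matching (N, 2) arrays")
        if len(self.moving) < 2:
            raise ValueError("need at least 2 control-point pairs")
        if len(np.unique(self.fixed, axis=0)) != len(self.fixed):
            raise ValueError("duplicate fixed control points")


@dataclass
class QuantResult:
    """Area-fraction quantification for one MT/Ki67 section pair."""

    ki67_percent_viable: float
    mt_percent_whole: float
    viable_area_mm2: float
    tumour_area_mm2: float


class EmptyTissueError(ValueError):
    """Thresholds labelled no tissue pixels inside the ROI."""


def classify_pixels(
    section: StainedSection, thresholds: ColourThresholds = ColourThresholds()
) -> TissueMasks:
    """Assign every ROI pixel to exactly one colour class.

    Precedence inside the ROI: background (near-white cracks/glass), then
    fold artefacts (over-dark), then positive stain (DAB brown for Ki67,
    collagen blue for MT); the remainder is counterstained tissue. For MT
    sections a pale necrosis-candidate mask is additionally extracted for
    :func:`segment_necrosis`. Pixels outside the ROI are ignored.
    """
    roi = section.roi_mask()
    hsv = _skcolor.rgb2hsv(section.image)
    hue, sat, val = hsv[..., 0], hsv[..., 1], hsv[..., 2]

    background = (sat < thresholds.background_s_max) & (val > thresholds.background_v_min)
    fold = val < thresholds.fold_v_max
    artefact = (background | fold) & roi
    tissue = roi & ~artefact
    if not tissue.any():
        raise EmptyTissueError("thresholds labelled zero tissue pixels inside ROI")

    if section.stain == STAIN_KI67:
        lo, hi = thresholds.dab_hue
        positive = (hue >= lo) & (hue <= hi) & (sat >= thresholds.dab_s_min)
        candidate = None
    elif section.stain == STAIN_MT:
        lo, hi = thresholds.collagen_hue
        positive = (hue >= lo) & (hue <= hi) & (sat >= thresholds.collagen_s_min)
        s_lo, s_hi = thresholds.necrosis_s_range
        candidate = (
            tissue
            & (sat >= s_lo)
            & (sat <= s_hi)
            & (val >= thresholds.necrosis_v_min)
        )
    else:
        raise ValueError(f"unknown stain {section.stain!r}")
    positive &= tissue

    masks = TissueMasks(
        background_artefact=artefact,
        tissue=tissue,
        positive=positive,
        necrosis_candidate=candidate,
    )
    masks.validate()
    return masks


def segment_necrosis(
    mt_masks: TissueMasks,
    min_region_area_um2: float = 2000.0,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    closing_radius_px: int = 2,
) -> TissueMasks:
    """Partition MT tissue into necrotic and viable tumour.

    Necrosis = the pale colour class, morphologically closed (bridging
    small holes such as scattered collagen fibres) and filtered by a
    minimum connected-region area; everything else is viable. Speckles
    below ``min_region_area_um2`` are absorbed into viable tissue. Returns
    the same masks object with ``necrotic`` and ``viable`` filled in.
    """
    if mt_masks.necrosis_candidate is None:
        raise ValueError("masks carry no necrosis candidate (not an MT section?)")
    cand = mt_masks.necrosis_candidate & mt_masks.tissue
    if closing_radius_px > 0:
        cand = _skmorph.closing(cand, _skmorph.disk(closing_radius_px))
        cand &= mt_masks.tissue
    min_px = max(1, int(round(min_region_area_um2 / pixel_size_um**2)))
    lab = _skmeasure.label(cand, connectivity=2)
    counts = np.bincount(lab.ravel())
    keep = counts >= min_px
    keep[0] = False
    cand = keep[lab]
    mt_masks.necrotic = cand
    mt_masks.viable = mt_masks.tissue & ~cand
    mt_masks.validate()
    return mt_masks


def fit_registration(
    points: ControlPointSet, model: str = "similarity"
) -> tuple[_sktransform.ProjectiveTransform, float]:
    """Least-squares landmark transform mapping moving onto fixed coordinates.

    ``model`` is "similarity" (rigid + isotropic scale; the default for
    adjacent 4-um sections) or "affine". Returns (transform, RMS residual
    in pixels). Degenerate point sets raise.
    """
    if model == "similarity":
        cls = _sktransform.SimilarityTransform
    elif model == "affine":
        if len(points.moving) < 3:
            raise ValueError("affine registration needs >= 3 point pairs")
        design = np.column_stack([points.moving, np.ones(len(points.moving))])
        if np.linalg.matrix_rank(design) < 3:
            raise np.linalg.LinAlgError(
                "collinear control points: affine transform underdetermined"
            )
        cls = _sktransform.AffineTransform
    else:
        raise ValueError(f"unknown registration model {model!r}")
    tform = cls.from_estimate(points.moving, points.fixed)
    if not tform or not np.all(np.isfinite(tform.params)):
        raise np.linalg.LinAlgError("degenerate control points: cannot estimate")
    resid = tform(points.moving) - points.fixed
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return tform, rms


def transfer_mask(
    mask: np.ndarray,
    transform: _sktransform.ProjectiveTransform,
    target_shape: tuple[int, int],
) -> np.ndarray:
    """Resample a binary mask through a moving->fixed transform.

    Nearest-neighbour resampling keeps the mask binary; pixels mapping from
    outside the source frame stay unlabelled (False).
    """
    warped = _sktransform.warp(
        mask.astype(float),
        inverse_map=transform.inverse,
        output_shape=target_shape,
        order=0,
        cval=0.0,
        preserve_range=True,
    )
    return warped > 0.5


def quantify(
    ki67_masks: TissueMasks,
    mt_masks: TissueMasks,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> QuantResult:
    """Area fractions: Ki67 in viable tumour only, MT over the whole tumour.

    ``ki67_masks.viable`` must already hold the viable mask transferred
    from the MT section. Areas are reported in mm^2. An empty viable region
    gives an undefined (NaN) Ki67 percentage, flagged via warning.
    """
    if ki67_masks.viable is None:
        raise ValueError("Ki67 masks lack a viable mask (transfer it first)")
    viable = ki67_masks.viable & ki67_masks.tissue
    n_viable = int(viable.sum())
    if n_viable == 0:
        warnings.warn("empty viable region: Ki67 percentage undefined",
                      stacklevel=2)
        ki67_pct = float("nan")
    else:
        ki67_pct = 100.0 * float((ki67_masks.positive & viable).sum()) / n_viable
    n_tissue_mt = int(mt_masks.tissue.sum())
    if n_tissue_mt == 0:
        raise EmptyTissueError("MT section has no tissue pixels")
    mt_pct = 100.0 * float(mt_masks.positive.sum()) / n_tissue_mt
    px_mm2 = (pixel_size_um * 1e-3) ** 2
    return QuantResult(
        ki67_percent_viable=ki67_pct,
        mt_percent_whole=mt_pct,
        viable_area_mm2=n_viable * px_mm2,
        tumour_area_mm2=n_tissue_mt * px_mm2,
    )


def analyse_section_pair(
    mt: StainedSection,
    ki67: StainedSection,
    points: ControlPointSet,
    thresholds: ColourThresholds = ColourThresholds(),
    min_region_area_um2: float = 2000.0,
    closing_radius_px: int = 2,
    registration_model: str = "similarity",
) -> tuple[QuantResult, float]:
    """Full per-pair chain: classify, partition, register, transfer, quantify.

    Returns the quantification plus the registration RMS residual (px).
    """
    mt_masks = classify_pixels(mt, thresholds)
    segment_necrosis(
        mt_masks,
        min_region_area_um2=min_region_area_um2,
        pixel_size_um=mt.pixel_size_um,
        closing_radius_px=closing_radius_px,
    )
    ki_masks = classify_pixels(ki67, thresholds)
    tform, rms = fit_registration(points, model=registration_model)
    ki_masks.viable = transfer_mask(mt_masks.viable, tform, ki67.image.shape[:2])
    ki_masks.necrotic = ki_masks.tissue & ~ki_masks.viable
    ki_masks.viable &= ki_masks.tissue
    return quantify(ki_masks, mt_masks, pixel_size_um=ki67.pixel_size_um), rms


def results_table(rows: list[dict]) -> pd.DataFrame:
    """Per-section results CSV layout (section id, group, fractions, areas)."""
    return pd.DataFrame(
        rows,
        columns=[
            "section_id",
            "group",
            "ki67_percent_viable",
            "mt_percent_whole",
            "viable_area_mm2",
            "tumour_area_mm2",
            "registration_rms_px",
        ],
    )
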