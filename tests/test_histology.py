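import numpy as np
import pytest
from skimage.transform import SimilarityTransform

from radgem.histology import (
    ControlPointSet,
    EmptyTissueError,
    StainedSection,
    TissueMasks,
    analyse_section_pair,
    classify_pixels,
    fit_registration,
    quantify,
    segment_necrosis,
    transfer_mask,
)
from radgem.synthetic import (
    PALETTE,
    SectionLayoutConfig,
    render_section_pair,
)


def flat_image(colour, shape=(64, 64)):
    img = np.empty(shape + (3,), dtype=np.uint8)
    img[:] = colour
    return img


def square_roi(shape, margin=2):
    h, w = shape
    return np.array(
        [[margin, margin], [w - 1 - margin, margin],
         [w - 1 - margin, h - 1 - margin], [margin, h - 1 - margin]], float
    )


class TestClassifyPixels:
    def test_uniform_near_white_image_has_no_tissue(self):
        img = flat_image(PALETTE["glass"])
        section = StainedSection(img, "Ki67", square_roi(img.shape[:2]))
        with pytest.raises(EmptyTissueError):
            classify_pixels(section)

    def test_dab_patch_on_counterstain(self):
        img = flat_image(PALETTE["ki67_counterstain"])
        img[20:30, 20:30] = PALETTE["ki67_positive"]
        section = StainedSection(img, "Ki67", square_roi(img.shape[:2]))
        masks = classify_pixels(section)
        patch = np.zeros(img.shape[:2], bool)
        patch[20:30, 20:30] = True
        assert masks.positive[patch].all()
        assert not masks.positive[masks.tissue & ~patch].any()

    def test_known_positive_fraction_recovered(self):
        rng = np.random.default_rng(5)
        img = flat_image(PALETTE["ki67_counterstain"], shape=(128, 128))
        roi = square_roi(img.shape[:2])
        flat = rng.random((128, 128)) < 0.4
        img[flat] = PALETTE["ki67_positive"]
        masks = classify_pixels(StainedSection(img, "Ki67", roi))
        measured = masks.positive.sum() / masks.tissue.sum()
        assert measured == pytest.approx(0.4, abs=0.02)

    def test_every_roi_pixel_labelled_once_and_outside_ignored(self):
        mt, _, _, _ = render_section_pair(SectionLayoutConfig(seed=3, size=(128, 128)))
        masks = classify_pixels(mt)
        roi = mt.roi_mask()
        covered = masks.background_artefact | masks.tissue
        assert (covered == roi).all()
        assert not masks.positive[~roi].any()


class TestSegmentNecrosis:
    def test_no_necrosis_gives_viable_everywhere(self):
        mt, _, _, _ = render_section_pair(
            SectionLayoutConfig(seed=3, size=(128, 128), necrotic_fraction=0.0)
        )
        masks = segment_necrosis(classify_pixels(mt), pixel_size_um=mt.pixel_size_um)
        assert masks.necrotic.sum() == 0
        assert (masks.viable == masks.tissue).all()

    def test_thirty_percent_disc_recovered(self):
        mt, _, _, truth = render_section_pair(
            SectionLayoutConfig(seed=4, size=(192, 192), necrotic_fraction=0.3)
        )
        masks = segment_necrosis(classify_pixels(mt), pixel_size_um=mt.pixel_size_um)
        frac = masks.necrotic.sum() / masks.tissue.sum()
        assert frac == pytest.approx(truth.necrotic_fraction, abs=0.02)

    def test_speckles_below_min_area_absorbed_into_viable(self):
        img = flat_image(PALETTE["mt_viable"], shape=(96, 96))
        img[10:12, 10:12] = PALETTE["mt_necrosis"]  # 4-px speckle
        masks = classify_pixels(StainedSection(img, "MT", square_roi((96, 96))))
        out = segment_necrosis(masks, min_region_area_um2=2000.0,
                               pixel_size_um=4.0, closing_radius_px=0)
        assert out.necrotic.sum() == 0

    def test_partition_invariants_hold(self):
        mt, _, _, _ = render_section_pair(SectionLayoutConfig(seed=6, size=(128, 128)))
        masks = segment_necrosis(classify_pixels(mt), pixel_size_um=mt.pixel_size_um)
        masks.validate()
        assert ((masks.necrotic | masks.viable) == masks.tissue).all()
        assert not (masks.necrotic & masks.viable).any()


class TestRegistration:
    def test_identity_point_pairs(self):
        pts = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], float)
        tform, rms = fit_registration(ControlPointSet(pts, pts))
        np.testing.assert_allclose(tform.params, np.eye(3), atol=1e-12)
        assert rms == pytest.approx(0.0, abs=1e-12)

    def test_pure_translation_recovered(self):
        pts = np.array([[0, 0], [10, 0], [0, 10]], float)
        tform, rms = fit_registration(ControlPointSet(pts, pts + [10, -5]))
        np.testing.assert_allclose(tform.translation, [10, -5], atol=1e-10)
        assert rms < 1e-10

    def test_rotation_about_centroid_recovered(self):
        pts = np.array([[0, 0], [20, 0], [20, 20], [0, 20]], float)
        angle = np.deg2rad(30)
        true = SimilarityTransform(rotation=angle, translation=(3, 4))
        tform, rms = fit_registration(ControlPointSet(pts, true(pts)))
        assert tform.rotation == pytest.approx(angle, abs=1e-6)
        assert rms < 1e-9

    def test_affine_needs_three_noncollinear_points(self):
        pts2 = np.array([[0, 0], [10, 10]], float)
        with pytest.raises(ValueError):
            fit_registration(ControlPointSet(pts2, pts2), model="affine")
        collinear = np.array([[0, 0], [5, 5], [10, 10]], float)
        with pytest.raises(np.linalg.LinAlgError):
            fit_registration(ControlPointSet(collinear, collinear * 2),
                             model="affine")

    def test_duplicate_fixed_points_rejected(self):
        with pytest.raises(ValueError):
            ControlPointSet(np.array([[0, 0], [1, 1]], float),
                            np.array([[2, 2], [2, 2]], float))


class TestTransferMask:
    @staticmethod
    def blob(shape=(40, 40)):
        m = np.zeros(shape, bool)
        m[10:20, 12:25] = True
        return m

    def test_identity_transform_is_noop(self):
        m = self.blob()
        out = transfer_mask(m, SimilarityTransform(), m.shape)
        np.testing.assert_array_equal(out, m)

    def test_known_translation_shifts_exactly(self):
        m = self.blob()
        out = transfer_mask(m, SimilarityTransform(translation=(3, 5)), m.shape)
        np.testing.assert_array_equal(out[15:25, 15:28], m[10:20, 12:25])
        assert out.sum() == m.sum()

    def test_out_of_frame_pixels_dropped(self):
        m = self.blob()
        out = transfer_mask(m, SimilarityTransform(translation=(20, 0)), m.shape)
        # columns 12..24 shifted by +20 -> 32..44; only 32..39 remain (8 cols)
        assert out.sum() == 10 * 8

    def test_mask_stays_binary_under_rotation(self):
        m = self.blob()
        out = transfer_mask(m, SimilarityTransform(rotation=0.3), m.shape)
        assert out.dtype == bool


class TestQuantify:
    def test_positive_equal_viable_gives_hundred_percent(self):
        shape = (32, 32)
        tissue = np.ones(shape, bool)
        masks_ki = TissueMasks(
            background_artefact=np.zeros(shape, bool), tissue=tissue,
            positive=tissue.copy(), viable=tissue.copy(),
            necrotic=np.zeros(shape, bool),
        )
        masks_mt = TissueMasks(
            background_artefact=np.zeros(shape, bool), tissue=tissue,
            positive=np.zeros(shape, bool),
        )
        q = quantify(masks_ki, masks_mt, pixel_size_um=4.0)
        assert q.ki67_percent_viable == 100.0
        assert q.mt_percent_whole == 0.0
        assert q.tumour_area_mm2 == pytest.approx(32 * 32 * (4e-3) ** 2)

    def test_empty_viable_region_flagged_undefined(self):
        shape = (8, 8)
        tissue = np.ones(shape, bool)
        masks_ki = TissueMasks(
            background_artefact=np.zeros(shape, bool), tissue=tissue,
            positive=np.zeros(shape, bool), viable=np.zeros(shape, bool),
        )
        masks_mt = TissueMasks(
            background_artefact=np.zeros(shape, bool), tissue=tissue,
            positive=np.zeros(shape, bool),
        )
        with pytest.warns(UserWarning):
            q = quantify(masks_ki, masks_mt)
        assert np.isnan(q.ki67_percent_viable)


class TestEndToEnd:
    def test_ground_truth_fractions_recovered(self):
        layout = SectionLayoutConfig(seed=21, size=(192, 192),
                                     ki67_positive_fraction=0.64,
                                     mt_collagen_fraction=0.03)
        mt, ki, pts, truth = render_section_pair(layout)
        q, rms = analyse_section_pair(mt, ki, pts)
        assert q.ki67_percent_viable == pytest.approx(
            100 * truth.ki67_positive_fraction, abs=2.0)
        assert q.mt_percent_whole == pytest.approx(
            100 * truth.mt_collagen_fraction, abs=1.0)
        assert rms < 1e-3

    def test_quantification_invariant_to_embedded_transform(self):
        base = dict(seed=22, size=(192, 192), ki67_positive_fraction=0.5,
                    mt_collagen_fraction=0.05, necrotic_fraction=0.25)
        q1, _ = analyse_section_pair(
            *render_section_pair(SectionLayoutConfig(**base, rotation_deg=0.0,
                                                     translation=(0.0, 0.0)))[:3])
        q2, _ = analyse_section_pair(
            *render_section_pair(SectionLayoutConfig(**base, rotation_deg=8.0,
                                                     translation=(9.0, -7.0)))[:3])
        assert q1.ki67_percent_viable == pytest.approx(q2.ki67_percent_viable,
                                                       abs=1.0)
        assert q1.mt_percent_whole == pytest.approx(q2.mt_percent_whole, abs=0.5)
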