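import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import bnctcam as bc
from bnctcam.errors import (DegenerateImageError, GeometryError,
                            UndefinedScoreError)
from bnctcam.segmentation import (MorphParams, binarize, confusion_counts,
                                  morph_filter, overlay_categories, score,
                                  truth_mask_3d, truth_mask_slice)

mask9 = arrays(bool, (9, 9), elements=st.booleans())


def brute_force_otsu(values, n_bins=128):
    """Exhaustive inter-class-variance search (independent Otsu oracle)."""
    hist, edges = np.histogram(values.ravel(), bins=n_bins)
    mids = (edges[:-1] + edges[1:]) / 2
    best_t, best_v = mids[0], -1.0
    for i in range(1, n_bins):
        w0, w1 = hist[:i].sum(), hist[i:].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[:i] * mids[:i]).sum() / w0
        m1 = (hist[i:] * mids[i:]).sum() / w1
        v = w0 * w1 * (m0 - m1) ** 2
        if v > best_v:
            best_v, best_t = v, edges[i]
    return best_t


class TestBinarize:
    def test_constant_image_all_selected(self):
        m = binarize(np.full((5, 5), 0.7))
        assert m.all()

    def test_two_level_separation(self):
        arr = np.where(np.eye(6) > 0, 1.0, 0.2)
        m = binarize(arr, MorphParams(binarize_threshold=0.5))
        assert np.array_equal(m, np.eye(6) > 0)

    def test_otsu_threshold_between_bimodal_modes(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0.2, 0.03, 600),
                               rng.normal(0.8, 0.03, 400)]).reshape(50, 20)
        m = binarize(vals, MorphParams(binarize_threshold="otsu"))
        oracle = brute_force_otsu(vals)
        # any split inside the empty gap is Otsu-equivalent: the masks must
        # agree and the oracle threshold must separate the two modes
        assert 0.25 < oracle < 0.75
        assert np.mean(m == (vals >= oracle)) > 0.995

    def test_all_zero_rejected(self):
        with pytest.raises(DegenerateImageError):
            binarize(np.zeros((4, 4)))


class TestMorphFilter:
    def test_single_erosion_removes_isolated_pixel(self):
        m = np.zeros((7, 7), bool)
        m[3, 3] = True
        p = MorphParams(n_cycles=1, operation_order=("erode",),
                        structuring_element="cross")
        assert not morph_filter(m, p).any()

    def test_opening_is_idempotent(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(size=(30, 30)) < 0.45
        p = MorphParams(n_cycles=1, operation_order=("erode", "dilate"))
        once = morph_filter(m, p)
        assert np.array_equal(morph_filter(once, p), once)

    def test_closing_fills_one_pixel_hole(self):
        m = np.ones((9, 9), bool)
        m[4, 4] = False
        p = MorphParams(n_cycles=1, operation_order=("dilate", "erode"))
        assert morph_filter(m, p).all()

    @given(mask9)
    @settings(max_examples=40, deadline=None)
    def test_extensivity_and_antiextensivity(self, m):
        dil = morph_filter(m, MorphParams(n_cycles=1, operation_order=("dilate",)))
        ero = morph_filter(m, MorphParams(n_cycles=1, operation_order=("erode",)))
        assert np.all(dil | ~m)   # dilation is a superset
        assert np.all(m | ~ero)   # erosion is a subset

    def test_footprint_larger_than_image_rejected(self):
        with pytest.raises(GeometryError):
            morph_filter(np.ones((3, 3), bool), MorphParams(selem_radius=4))

    def test_footprint_shapes(self):
        assert MorphParams(structuring_element="cross").footprint().sum() == 5
        assert MorphParams(structuring_element="square").footprint().sum() == 9


class TestConfusionAndScore:
    def test_hand_counted_3x3(self):
        pred = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 0]], bool)
        truth = np.array([[1, 0, 0], [1, 0, 0], [1, 0, 0]], bool)
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn) == (2, 2, 1)
        s = score(c)
        assert s.accuracy == pytest.approx(50.0)
        assert s.sensitivity == pytest.approx(100.0 * 2 / 3)

    def test_hand_counted_5x5(self):
        pred = np.zeros((5, 5), bool)
        truth = np.zeros((5, 5), bool)
        pred[1:4, 1:4] = True      # 9 pixels
        truth[2:5, 2:5] = True     # 9 pixels, overlap 2x2
        c = confusion_counts(pred, truth)
        assert (c.tp, c.fp, c.fn) == (4, 5, 5)
        s = score(c)
        assert s.accuracy == pytest.approx(100.0 * 4 / 9)
        assert s.sensitivity == pytest.approx(100.0 * 4 / 9)

    def test_perfect_and_over_segmentation(self):
        truth = np.zeros((4, 4), bool)
        truth[0, :2] = True
        perfect = confusion_counts(truth, truth)
        assert (perfect.fp, perfect.fn) == (0, 0)
        over = confusion_counts(np.ones((4, 4), bool), truth)
        assert (over.tp, over.fn, over.fp) == (2, 0, 14)

    def test_table_style_percentages(self):
        assert score(bc.ConfusionCounts(97, 3, 21)).accuracy == pytest.approx(97.0)
        s4 = score(bc.ConfusionCounts(8, 92, 0))
        assert s4.accuracy == pytest.approx(8.0)
        assert s4.sensitivity == pytest.approx(100.0)
        s_eq = score(bc.ConfusionCounts(5, 5, 5))
        assert s_eq.accuracy == s_eq.sensitivity == pytest.approx(50.0)

    def test_undefined_scores_rejected(self):
        with pytest.raises(UndefinedScoreError):
            score(bc.ConfusionCounts(0, 0, 3))
        with pytest.raises(UndefinedScoreError):
            score(bc.ConfusionCounts(0, 3, 0))

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_counts(np.ones((2, 2), bool), np.ones((3, 3), bool))

    @given(mask9, mask9)
    @settings(max_examples=40, deadline=None)
    def test_counts_partition_the_masks(self, pred, truth):
        c = confusion_counts(pred, truth)
        assert c.tp + c.fn == truth.sum()
        assert c.tp + c.fp == pred.sum()

    @given(mask9, mask9)
    @settings(max_examples=40, deadline=None)
    def test_overlay_counts_match_confusion(self, pred, truth):
        c = confusion_counts(pred, truth)
        cat = overlay_categories(pred, truth)
        assert (cat == 1).sum() == c.tp
        assert (cat == 2).sum() == c.fp
        assert (cat == 3).sum() == c.fn

    def test_scores_invariant_under_joint_permutation(self):
        rng = np.random.default_rng(6)
        pred = rng.uniform(size=(8, 8)) < 0.4
        truth = rng.uniform(size=(8, 8)) < 0.4
        perm = rng.permutation(64)
        c1 = confusion_counts(pred, truth)
        c2 = confusion_counts(pred.ravel()[perm].reshape(8, 8),
                              truth.ravel()[perm].reshape(8, 8))
        assert c1 == c2


class TestTruthMasks:
    def test_sphere_mask_matches_ball_volume(self):
        grid = bc.VoxelGrid()
        mask = truth_mask_3d(grid, bc.SourceModel())
        vol = mask.sum() * grid.voxel_side**3
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 1000.0, rel=0.05)

    def test_five_point_slice_has_five_pixels(self):
        grid = bc.VoxelGrid()
        sl = truth_mask_slice(grid, bc.SourceModel(shape="five_points"))
        assert sl.sum() == 5

    def test_sphere_slice_is_centered_disk(self):
        grid = bc.VoxelGrid()
        sl = truth_mask_slice(grid, bc.SourceModel())
        ii, jj = np.nonzero(sl)
        assert abs(ii.mean() - 49.5) < 1 and abs(jj.mean() - 49.5) < 1
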