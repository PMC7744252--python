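import numpy as np
import pytest

from lesionft.metrics import (compare_paired, detection_metrics,
                              modified_hausdorff, segmentation_metrics,
                              summarize_cohort)
from lesionft.postprocess import label_objects


def objset(volume):
    return label_objects(np.asarray(volume, np.uint8), (1, 1, 1))


def three_truth_objects():
    truth = np.zeros((3, 12, 12), np.uint8)
    truth[0, 1:3, 1:3] = 1    # A
    truth[1, 6:8, 6:8] = 1    # B
    truth[2, 9:11, 2:4] = 1   # C
    return truth


class TestDetection:
    def test_partial_detection_hand_computed(self):
        truth = three_truth_objects()
        pred = np.zeros_like(truth)
        pred[0, 2, 2] = 1          # P1 overlaps A
        pred[1, 0:2, 9:11] = 1     # P2 overlaps nothing
        m = detection_metrics(objset(pred), objset(truth))
        assert m.tpr == pytest.approx(1 / 3)
        assert m.fpc == 1
        assert m.f1 == pytest.approx(0.4)  # 2*(1/3)(1/2)/((1/3)+(1/2))

    def test_perfect_prediction(self):
        truth = three_truth_objects()
        m = detection_metrics(objset(truth), objset(truth))
        assert (m.tpr, m.fpc, m.f1) == (1.0, 0, 1.0)

    def test_empty_prediction(self):
        truth = three_truth_objects()
        m = detection_metrics(objset(np.zeros_like(truth)), objset(truth))
        assert (m.tpr, m.fpc, m.f1) == (0.0, 0, 0.0)

    def test_no_true_lesions_is_flagged_not_raised(self):
        pred = np.zeros((2, 4, 4), np.uint8)
        pred[0, 0, 0] = 1
        m = detection_metrics(objset(pred), objset(np.zeros_like(pred)))
        assert not m.defined
        assert np.isnan(m.tpr)
        assert m.fpc == 1

    def test_matches_brute_force_matcher_on_random_masks(self):
        """Oracle equivalence on 200 random 16^3 mask pairs."""
        rng = np.random.default_rng(11)
        checked = 0
        for _ in range(200):
            pred = (rng.random((16, 16, 16)) < 0.04).astype(np.uint8)
            truth = (rng.random((16, 16, 16)) < 0.04).astype(np.uint8)
            po, to = objset(pred), objset(truth)
            m = detection_metrics(po, to)
            # brute force: all-pairs voxel-set intersection
            t_sets = [set(map(tuple, np.argwhere(to.labels == t)))
                      for t in range(1, to.n_objects + 1)]
            p_sets = [set(map(tuple, np.argwhere(po.labels == p)))
                      for p in range(1, po.n_objects + 1)]
            detected = sum(1 for ts in t_sets
                           if any(ts & ps for ps in p_sets))
            fpc = sum(1 for ps in p_sets
                      if not any(ps & ts for ts in t_sets))
            assert m.fpc == fpc
            if to.n_objects:
                assert m.tpr == pytest.approx(detected / to.n_objects)
                recall = detected / to.n_objects
                precision = ((po.n_objects - fpc) / po.n_objects
                             if po.n_objects else 0.0)
                f1 = (2 * recall * precision / (recall + precision)
                      if recall + precision else 0.0)
                assert m.f1 == pytest.approx(f1)
                checked += 1
        assert checked > 150


class TestSegmentation:
    def test_dice_hand_computed(self):
        pred = np.zeros((1, 4, 4), np.uint8)
        truth = np.zeros((1, 4, 4), np.uint8)
        pred[0, 0, 0:4] = 1                  # |X| = 4
        truth[0, 0, 1:4] = truth[0, 1, 0:3] = 1  # |Y| = 6, overlap 3
        m = segmentation_metrics(pred, truth, (1, 1, 1))
        assert m.dice == pytest.approx(0.6)

    def test_avd_hand_computed(self):
        pred = np.zeros((1, 20, 20), np.uint8)
        truth = np.zeros((1, 20, 20), np.uint8)
        pred[0, :12, :10] = 1   # V(X) = 120
        truth[0, :10, :10] = 1  # V(Y) = 100
        m = segmentation_metrics(pred, truth, (1, 1, 1))
        assert m.avd_percent == pytest.approx(20.0)

    def test_identity_masks(self):
        truth = three_truth_objects()
        m = segmentation_metrics(truth, truth, (1.5, 1.0, 1.0))
        assert m.dice == 1.0
        assert m.avd_percent == 0.0
        assert m.h_mod_mm == 0.0

    def test_empty_annotation_flagged(self):
        pred = np.ones((2, 3, 3), np.uint8)
        m = segmentation_metrics(pred, np.zeros_like(pred), (1, 1, 1))
        assert not m.defined and np.isnan(m.avd_percent)


class TestModifiedHausdorff:
    def test_single_voxel_pair_one_z_step(self):
        a = np.zeros((3, 3, 3), np.uint8)
        b = np.zeros((3, 3, 3), np.uint8)
        a[0, 1, 1] = 1
        b[1, 1, 1] = 1
        d = modified_hausdorff(a, b, (3.0, 0.958, 0.958))
        assert d == pytest.approx(3.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        a = (rng.random((8, 8, 8)) < 0.1).astype(np.uint8)
        b = (rng.random((8, 8, 8)) < 0.1).astype(np.uint8)
        a[0, 0, 0] = b[7, 7, 7] = 1  # keep both nonempty
        d1 = modified_hausdorff(a, b, (2, 1, 1))
        d2 = modified_hausdorff(b, a, (2, 1, 1))
        assert d1 == pytest.approx(d2)

    def test_empty_mask_raises(self):
        a = np.zeros((2, 2, 2), np.uint8)
        b = np.ones((2, 2, 2), np.uint8)
        with pytest.raises(ValueError, match="nonempty"):
            modified_hausdorff(a, b, (1, 1, 1))


class TestComparePaired:
    def test_paired_t_closed_form(self):
        a = np.array([2.0, 4.0, 6.0])
        b = np.array([1.0, 2.0, 3.0])  # diffs [1, 2, 3]
        r = compare_paired(a, b, "paired_t")
        assert r.statistic == pytest.approx(2 / (1 / np.sqrt(3)), rel=1e-4)
        assert r.p_value == pytest.approx(0.0742, abs=2e-4)

    def test_wilcoxon_exact_five_positive_differences(self):
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a - np.array([0.5, 0.4, 0.3, 0.2, 0.1])
        r = compare_paired(a, b, "wilcoxon_signed_rank")
        assert r.p_value == pytest.approx(2 / 32)  # enumeration of 2^5 signs

    def test_identical_vectors_degenerate(self):
        a = np.array([1.0, 2.0, 3.0])
        r = compare_paired(a, a, "paired_t")
        assert r.degenerate and r.p_value == 1.0

    def test_short_input_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            compare_paired([1, 2], [2, 1], "paired_t")


def test_dice_symmetry_and_f1_role_swap():
    """Dice is symmetric in its arguments.  Object-level F1 swaps the roles
    of recall and precision when arguments are exchanged (recall(X,Y) ==
    precision(Y,X)), and its degenerate handling is one-sided: empty truth is
    flagged undefined while empty prediction scores 0."""
    rng = np.random.default_rng(7)
    a = (rng.random((10, 10, 10)) < 0.08).astype(np.uint8)
    b = (rng.random((10, 10, 10)) < 0.08).astype(np.uint8)
    d_ab = segmentation_metrics(a, b, (1, 1, 1)).dice
    d_ba = segmentation_metrics(b, a, (1, 1, 1)).dice
    assert d_ab == pytest.approx(d_ba)

    m_ab = detection_metrics(objset(a), objset(b))
    m_ba = detection_metrics(objset(b), objset(a))
    precision_ab = (m_ab.n_pred - m_ab.fpc) / m_ab.n_pred
    assert m_ba.tpr == pytest.approx(precision_ab)

    truth = np.zeros((1, 4, 4), np.uint8)
    truth[0, 1, 1] = 1
    empty = np.zeros_like(truth)
    assert detection_metrics(objset(empty), objset(truth)).f1 == 0.0
    assert not detection_metrics(objset(truth), objset(empty)).defined


def test_size_stratified_tpr_splits_on_object_volume():
    from lesionft.metrics import size_stratified_tpr
    truth = np.zeros((4, 12, 12), np.uint8)
    truth[0:3, 1:7, 1:7] = 1      # 108 voxels -> large at 50 mm^3 threshold
    truth[3, 10, 10] = 1          # 1 voxel   -> small, undetected
    pred = np.zeros_like(truth)
    pred[1, 2, 2] = 1             # hits the large lesion only
    strat = size_stratified_tpr(objset(pred), objset(truth),
                                threshold_mm3=50.0)
    assert strat == {"tpr_small": 0.0, "tpr_large": 1.0, "n_small": 1,
                     "n_large": 1, "threshold_mm3": 50.0}
    # no small lesions -> flagged NaN rather than a misleading 0
    strat2 = size_stratified_tpr(objset(pred), objset(truth),
                                 threshold_mm3=0.5)
    assert np.isnan(strat2["tpr_small"]) and strat2["n_small"] == 0


def test_cohort_summary_uses_median_iqr_and_mean_sd():
    import pandas as pd
    rows = pd.DataFrame([
        {"patient_id": "a", "model": "base", "tpr": 0.2, "fpc": 3, "f1": 0.3,
         "dice": 0.7, "avd_percent": 10.0, "h_mod_mm": 2.0, "defined": True},
        {"patient_id": "b", "model": "base", "tpr": 0.8, "fpc": 1, "f1": 0.5,
         "dice": 0.9, "avd_percent": 30.0, "h_mod_mm": 4.0, "defined": True},
        {"patient_id": "c", "model": "base", "tpr": 0.4, "fpc": 2, "f1": 0.4,
         "dice": 0.8, "avd_percent": 20.0, "h_mod_mm": 3.0, "defined": True},
    ])
    s = summarize_cohort(rows).iloc[0]
    assert s.tpr_median == pytest.approx(0.4)
    assert s.fpc_median == pytest.approx(2.0)
    assert s.dice_mean == pytest.approx(0.8)
    assert s.avd_percent_sd == pytest.approx(10.0)
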