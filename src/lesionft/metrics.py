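"""Object-level detection metrics, volumetric segmentation metrics, and
paired statistical model comparison.

Detection is object-based: an annotated lesion counts as detected when any
predicted voxel overlaps it (>0 overlap); the false-positive count (FPC) is
the number of predicted objects overlapping no true lesion.  Detection
results over a cohort are reported as median [IQR] and compared with the
Wilcoxon signed-rank test; segmentation results (Dice, absolute volume
difference, 95th-percentile Hausdorff) as mean +/- SD with the paired
Student's t-test.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

from .postprocess import LesionObjectSet


@dataclasses.dataclass
class DetectionMetrics:
    tpr: float            # detected true objects / all true objects
    fpc: int              # predicted objects overlapping no true lesion
    f1: float
    n_true: int
    n_pred: int
    n_detected: int
    defined: bool = True  # False when there are no true objects


@dataclasses.dataclass
class SegmentationMetrics:
    dice: float
    avd_percent: float
    h_mod_mm: float
    defined: bool = True  # False when the annotation is empty


@dataclasses.dataclass
class PairedComparison:
    test: str
    statistic: float
    p_value: float
    degenerate: bool = False  # all paired differences were zero


def detection_metrics(pred_objects: LesionObjectSet,
                      true_objects: LesionObjectSet) -> DetectionMetrics:
    """Object-level TPR, FPC and F1 (overlap predicate: >= 1 shared voxel)."""
    if pred_objects.labels.shape != true_objects.labels.shape:
        raise ValueError("prediction and annotation volumes differ in shape")
    pred_any = pred_objects.any_mask
    true_any = true_objects.any_mask

    n_true = true_objects.n_objects
    n_pred = pred_objects.n_objects
    detected = sum(
        1 for t in range(1, n_true + 1)
        if pred_any[true_objects.labels == t].any())
    fpc = sum(
        1 for p in range(1, n_pred + 1)
        if not true_any[pred_objects.labels == p].any())

    if n_true == 0:
        return DetectionMetrics(tpr=float("nan"), fpc=fpc, f1=float("nan"),
                                n_true=0, n_pred=n_pred, n_detected=0,
                                defined=False)
    recall = detected / n_true
    precision = (n_pred - fpc) / n_pred if n_pred > 0 else 0.0
    f1 = (2 * recall * precision / (recall + precision)
          if (recall + precision) > 0 else 0.0)
    return DetectionMetrics(tpr=recall, fpc=int(fpc), f1=f1, n_true=n_true,
                            n_pred=n_pred, n_detected=int(detected))


def _boundary_coords_mm(mask: np.ndarray, spacing_mm) -> np.ndarray:
    """Physical coordinates of boundary voxels (mask minus its erosion)."""
    face = ndimage.generate_binary_structure(mask.ndim, 1)
    interior = ndimage.binary_erosion(mask, structure=face, border_value=0)
    boundary = mask & ~interior
    coords = np.argwhere(boundary).astype(np.float64)
    return coords * np.asarray(spacing_mm, dtype=np.float64)


def modified_hausdorff(pred_mask: np.ndarray, true_mask: np.ndarray,
                       spacing_mm) -> float:
    """95th-percentile symmetric boundary distance in millimetres."""
    pred_mask = np.asarray(pred_mask).astype(bool)
    true_mask = np.asarray(true_mask).astype(bool)
    if not pred_mask.any() or not true_mask.any():
        raise ValueError("modified Hausdorff requires two nonempty masks")
    pb = _boundary_coords_mm(pred_mask, spacing_mm)
    tb = _boundary_coords_mm(true_mask, spacing_mm)
    d_pt = cKDTree(tb).query(pb)[0]
    d_tp = cKDTree(pb).query(tb)[0]
    return float(np.percentile(np.concatenate([d_pt, d_tp]), 95))


def segmentation_metrics(pred_mask: np.ndarray, true_mask: np.ndarray,
                         spacing_mm) -> SegmentationMetrics:
    """Dice, absolute volume difference (% of annotation volume) and H95."""
    pred_mask = np.asarray(pred_mask).astype(bool)
    true_mask = np.asarray(true_mask).astype(bool)
    if pred_mask.shape != true_mask.shape:
        raise ValueError("mask shapes differ")
    np_, nt = int(pred_mask.sum()), int(true_mask.sum())
    inter = int((pred_mask & true_mask).sum())
    if nt == 0:
        return SegmentationMetrics(float("nan"), float("nan"), float("nan"),
                                   defined=False)
    dice = 2.0 * inter / (np_ + nt)
    voxel = float(np.prod(spacing_mm))
    avd = abs(np_ * voxel - nt * voxel) / (nt * voxel) * 100.0
    h95 = modified_hausdorff(pred_mask, true_mask, spacing_mm) \
        if np_ > 0 else float("nan")
    return SegmentationMetrics(dice=dice, avd_percent=avd, h_mod_mm=h95)


def compare_paired(values_a, values_b, test: str) -> PairedComparison:
    """Two-sided paired comparison of per-patient metric values.

    test='wilcoxon_signed_rank': zero differences dropped, exact null
    distribution for n <= 25, normal approximation with continuity
    correction above.  test='paired_t': Student's paired t.
    All differences zero -> degenerate record with p = 1.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be equal-length 1D")
    if a.size < 3:
        raise ValueError("need at least 3 pairs")
    diffs = a - b
    if np.all(diffs == 0):
        return PairedComparison(test=test, statistic=0.0, p_value=1.0,
                                degenerate=True)
    if test == "paired_t":
        res = stats.ttest_rel(a, b)
        return PairedComparison(test=test, statistic=float(res.statistic),
                                p_value=float(res.pvalue))
    if test == "wilcoxon_signed_rank":
        nz = diffs[diffs != 0]
        method = "exact" if nz.size <= 25 else "approx"
        res = stats.wilcoxon(nz, zero_method="wilcox", correction=True,
                             method=method)
        return PairedComparison(test=test, statistic=float(res.statistic),
                                p_value=float(res.pvalue))
    raise ValueError(f"unknown test {test!r}")


def size_stratified_tpr(pred_objects: LesionObjectSet,
                        true_objects: LesionObjectSet,
                        threshold_mm3: float = 1000.0) -> dict:
    """Object TPR split into lesions smaller vs at least threshold_mm3.

    Small lesions are missed far more often than large ones, so the split
    (default 1 cm^3) localises where detection gains come from.  False
    positives carry no true size and are not stratified.
    """
    pred_any = pred_objects.any_mask
    small_hit = small_n = large_hit = large_n = 0
    for t in range(1, true_objects.n_objects + 1):
        small = true_objects.volumes_mm3[t - 1] < threshold_mm3
        hit = bool(pred_any[true_objects.labels == t].any())
        if small:
            small_n += 1
            small_hit += hit
        else:
            large_n += 1
            large_hit += hit
    return {"tpr_small": small_hit / small_n if small_n else float("nan"),
            "tpr_large": large_hit / large_n if large_n else float("nan"),
            "n_small": small_n, "n_large": large_n,
            "threshold_mm3": float(threshold_mm3)}


# -- cohort reporting ---------------------------------------------------------

DETECTION_COLUMNS = ("tpr", "fpc", "f1")
SEGMENTATION_COLUMNS = ("dice", "avd_percent", "h_mod_mm")


def case_metrics_row(patient_id: str, model: str,
                     pred_objects: LesionObjectSet,
                     true_objects: LesionObjectSet,
                     spacing_mm) -> dict:
    """Detection + segmentation metrics of one prediction as a report row."""
    det = detection_metrics(pred_objects, true_objects)
    seg = segmentation_metrics(pred_objects.any_mask, true_objects.any_mask,
                               spacing_mm)
    return {"patient_id": patient_id, "model": model,
            "tpr": det.tpr, "fpc": det.fpc, "f1": det.f1,
            "n_true": det.n_true, "n_pred": det.n_pred,
            "dice": seg.dice, "avd_percent": seg.avd_percent,
            "h_mod_mm": seg.h_mod_mm,
            "defined": det.defined and seg.defined}


def summarize_cohort(rows: pd.DataFrame) -> pd.DataFrame:
    """Median [IQR] for detection metrics, mean +/- SD for segmentation.

    Rows flagged undefined (no true lesions) are excluded, matching the
    convention of reporting only evaluable cases.
    """
    df = rows[rows["defined"]] if "defined" in rows else rows
    out = []
    for model, grp in df.groupby("model"):
        rec = {"model": model, "n_cases": len(grp)}
        for col in DETECTION_COLUMNS:
            vals = grp[col].to_numpy(dtype=float)
            rec[f"{col}_median"] = float(np.median(vals))
            rec[f"{col}_iqr_lo"] = float(np.percentile(vals, 25))
            rec[f"{col}_iqr_hi"] = float(np.percentile(vals, 75))
        for col in SEGMENTATION_COLUMNS:
            vals = grp[col].to_numpy(dtype=float)
            vals = vals[~np.isnan(vals)]
            rec[f"{col}_mean"] = float(np.mean(vals)) if vals.size else float("nan")
            rec[f"{col}_sd"] = float(np.std(vals, ddof=1)) if vals.size > 1 \
                else float("nan")
        out.append(rec)
    return pd.DataFrame(out)


def compare_models(rows: pd.DataFrame, model_a: str, model_b: str,
                   alpha: float = 0.01) -> pd.DataFrame:
    """Paired tests between two models over the cohort (aligned by patient).

    Detection metrics use the Wilcoxon signed-rank test, segmentation metrics
    the paired t-test; significance is assessed at the given alpha.
    """
    df = rows[rows["defined"]] if "defined" in rows else rows
    a = df[df["model"] == model_a].set_index("patient_id").sort_index()
    b = df[df["model"] == model_b].set_index("patient_id").sort_index()
    common = a.index.intersection(b.index)
    out = []
    for col in DETECTION_COLUMNS + SEGMENTATION_COLUMNS:
        test = ("wilcoxon_signed_rank" if col in DETECTION_COLUMNS
                else "paired_t")
        va = a.loc[common, col].to_numpy(dtype=float)
        vb = b.loc[common, col].to_numpy(dtype=float)
        keep = ~(np.isnan(va) | np.isnan(vb))
        if keep.sum() < 3:
            # too few evaluable pairs for any paired test
            cmp = PairedComparison(test=test, statistic=float("nan"),
                                   p_value=float("nan"), degenerate=True)
        else:
            cmp = compare_paired(va[keep], vb[keep], test)
        out.append({"metric": col, "test": test,
                    "statistic": cmp.statistic, "p_value": cmp.p_value,
                    "significant": bool(cmp.p_value < alpha
                                        and not cmp.degenerate),
                    "degenerate": cmp.degenerate, "n_pairs": int(keep.sum())})
    return pd.DataFrame(out)
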