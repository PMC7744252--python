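"""Patient-specific fine-tuning.

Starting from the base network, only the two final 1x1 convolutions (the
head) continue training on the patient's annotated baseline scan; every
pathway parameter and every batch-norm parameter and running statistic stays
bit-identical (batch norm runs in inference mode throughout).

Slices offered to fine-tuning are chosen by ``slice_mode``:

* ``all_lesion`` -- every slice with annotated lesions (the default and the
  best-performing option for lesion detection),
* ``all_organ``  -- every slice intersecting the organ mask,
* ``k_selected_organ`` / ``k_selected_lesion`` -- the k candidate slices whose
  mean lesion probability (base model, organ pixels) lies closest to 0.5.

Optionally, per-pixel loss weights derived from the base model's confusion on
the baseline scan replace the class weighting (values in {0, 1, 2, 5}):

* detection scheme: missed lesions 5, detected-lesion true positives 2,
  their false negatives 0, false-positive pixels connected to detected
  lesions 0, stand-alone false-positive objects and background 1;
* segmentation scheme: false positives and false negatives 5, true
  positives 2, true negatives 1.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import AnnotatedCase
from .nn.model import DualPathwayNet, new_optimizer
from .postprocess import BRAIN_PROFILE, PostprocessProfile, postprocess
from .predict import predict_volume
from .sampling import (augment_rotate, batch_arrays, lesion_slices,
                       normalize_case, organ_slices, sample_ft_patches)
from .training import softmax_ce_loss_grad

SLICE_MODES = ("all_lesion", "all_organ", "k_selected_organ",
               "k_selected_lesion")
WEIGHTINGS = ("none", "detection", "segmentation")


@dataclasses.dataclass
class FTConfig:
    """Fine-tuning hyperparameters (loss, optimizer and learning rate match
    base training; 100 iterations is the operating point used throughout)."""

    iterations: int = 100
    minibatch: int = 4
    learning_rate: float = 1e-4
    slice_mode: str = "all_lesion"
    k: int = 1
    weighting: str = "none"
    class_weights: tuple = (1.0, 5.0)
    patch_size: int = 128
    seed: int = 0

    def validate(self) -> None:
        if self.iterations < 0:
            raise ValueError("iterations must be >= 0")
        if self.slice_mode not in SLICE_MODES:
            raise ValueError(f"slice_mode must be one of {SLICE_MODES}")
        if self.weighting not in WEIGHTINGS:
            raise ValueError(f"weighting must be one of {WEIGHTINGS}")
        if self.slice_mode.startswith("k_selected") and self.k < 1:
            raise ValueError("k must be >= 1 for k_selected modes")


def select_slices(baseline_prob_map: np.ndarray | None, case: AnnotatedCase,
                  mode: str, k: int = 1) -> list:
    """Slice indices offered to fine-tuning (ascending).

    For the k-selected modes, candidates are ranked by |mean organ-pixel
    probability - 0.5| (ties broken toward the lower slice index).
    """
    if mode == "all_lesion":
        return lesion_slices(case)
    if mode == "all_organ":
        return organ_slices(case)
    if mode not in ("k_selected_organ", "k_selected_lesion"):
        raise ValueError(f"unknown slice mode {mode!r}")
    if baseline_prob_map is None:
        raise ValueError("k_selected modes require the baseline probability "
                         "map of the base model")
    candidates = organ_slices(case) if mode == "k_selected_organ" \
        else lesion_slices(case)
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidate "
                         f"slices of mode {mode}")
    scores = []
    for z in candidates:
        organ = case.organ_mask[z] > 0
        mean_p = float(baseline_prob_map[z][organ].mean()) if organ.any() \
            else np.inf
        scores.append((abs(mean_p - 0.5), z))
    scores.sort()
    return sorted(z for _, z in scores[:k])


def build_weight_map(annotation: np.ndarray, prediction: np.ndarray,
                     scheme: str) -> np.ndarray:
    """Per-pixel fine-tuning loss weights in {0, 1, 2, 5}.

    Works on 2D slices or 3D volumes; objects use full connectivity
    (8-connected in 2D, 26-connected in 3D).
    """
    annotation = np.asarray(annotation)
    prediction = np.asarray(prediction)
    if annotation.shape != prediction.shape:
        raise ValueError("annotation and prediction shapes differ")
    for name, arr in (("annotation", annotation), ("prediction", prediction)):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} must be binary")
    ann = annotation.astype(bool)
    pred = prediction.astype(bool)
    weights = np.ones(ann.shape, np.float32)

    if scheme == "segmentation":
        weights[pred & ~ann] = 5.0   # false positives
        weights[~pred & ann] = 5.0   # false negatives
        weights[pred & ann] = 2.0    # true positives
        return weights
    if scheme != "detection":
        raise ValueError(f"unknown weighting scheme {scheme!r}")

    structure = np.ones((3,) * ann.ndim, bool)
    ann_lbl, n_ann = ndimage.label(ann, structure=structure)
    pred_lbl, _ = ndimage.label(pred, structure=structure)
    touched_pred_ids: set = set()
    for a in range(1, n_ann + 1):
        obj = ann_lbl == a
        overlap = obj & pred
        if not overlap.any():
            weights[obj] = 5.0                    # missed lesion
            continue
        weights[overlap] = 2.0                    # detected: TP pixels
        weights[obj & ~pred] = 0.0                # detected: FN pixels
        touched_pred_ids.update(np.unique(pred_lbl[overlap]).tolist())
    for p in touched_pred_ids:
        # FP pixels of prediction objects connected to a detected lesion
        weights[(pred_lbl == p) & ~ann] = 0.0
    # prediction objects touching no annotation keep weight 1 (background)
    return weights


def finetune(base_net: DualPathwayNet, baseline_case: AnnotatedCase,
             ft_config: FTConfig,
             profile: PostprocessProfile = BRAIN_PROFILE,
             baseline_prob_map: np.ndarray | None = None) -> tuple:
    """Head-only refinement on one patient's baseline scan.

    Returns (fine-tuned network, log).  The returned network's body
    parameters and batch-norm statistics are bit-identical to
    ``base_net``'s; with ``iterations=0`` the whole state is identical.
    When ``weighting`` is not 'none', the confusion-based pixel-weight map
    replaces class weighting (class weights become 1).
    """
    ft_config.validate()
    if baseline_case.lesion_mask is None:
        raise ValueError("fine-tuning requires the annotated baseline scan")
    net = base_net.copy()
    log = {"seed": ft_config.seed, "slice_mode": ft_config.slice_mode,
           "weighting": ft_config.weighting,
           "iterations": ft_config.iterations}
    if ft_config.iterations == 0:
        log["slices"] = []
        return net, log

    needs_prob = (ft_config.slice_mode.startswith("k_selected")
                  or ft_config.weighting != "none")
    if needs_prob and baseline_prob_map is None:
        baseline_prob_map = predict_volume(base_net, baseline_case)

    slices = select_slices(baseline_prob_map, baseline_case,
                           ft_config.slice_mode, ft_config.k)
    if not slices:
        raise ValueError("no slices selected for fine-tuning")
    log["slices"] = [int(z) for z in slices]

    weight_volume = None
    if ft_config.weighting != "none":
        binary = postprocess(baseline_prob_map, baseline_case.organ_mask,
                             profile)
        weight_volume = build_weight_map(baseline_case.lesion_mask, binary,
                                         ft_config.weighting)
        class_weights = (1.0, 1.0)
    else:
        class_weights = ft_config.class_weights

    norm = normalize_case(baseline_case)
    pool = []
    for z in slices:
        pool.extend(sample_ft_patches(norm, z, ft_config.patch_size,
                                      weight_volume=weight_volume))

    root = np.random.SeedSequence(ft_config.seed)
    s_batch, s_rot, s_drop = root.spawn(3)
    batch_rng = np.random.default_rng(s_batch)
    rot_rng = np.random.default_rng(s_rot)
    drop_rng = np.random.default_rng(s_drop)
    opt, grads_fn = new_optimizer(net, ft_config.learning_rate,
                                  head_only=True)

    losses = []
    for _ in range(ft_config.iterations):
        idx = batch_rng.integers(0, len(pool), ft_config.minibatch)
        patches = [augment_rotate(pool[i], rot_rng) for i in idx]
        xa, xb, y, w = batch_arrays(patches)
        logits = net.forward(xa, xb, mode="ft", rng=drop_rng)
        loss, dlogits = softmax_ce_loss_grad(logits, y, class_weights, w)
        net.backward(dlogits, head_only=True)
        opt.step(grads_fn())
        losses.append(float(loss))
    log["ft_loss"] = losses
    return net, log
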