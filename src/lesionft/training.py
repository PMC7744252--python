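"""Base-model training: class-weighted categorical cross-entropy on lesion
slices, Adam, fixed patch pool with online rotation augmentation, and
lowest-validation-loss checkpoint selection.

Only slices that contain lesions enter the training set (class balance);
85% of slices train, 15% validate.  Each slice contributes a fixed pool of
randomly placed organ-intersecting patches (drawn once per run, seeded);
every minibatch draw applies a fresh random rotation.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .io import AnnotatedCase
from .nn.model import DualPathwayNet, ModelConfig, build_model, new_optimizer
from .nn.ops import F32, softmax
from .sampling import (augment_rotate, batch_arrays, lesion_slices,
                       normalize_case, sample_training_patches)


@dataclasses.dataclass
class TrainConfig:
    """Optimization hyperparameters (defaults follow the published schedule)."""

    learning_rate: float = 1e-4
    iterations: int = 10000
    minibatch: int = 4
    class_weights: tuple = (1.0, 5.0)
    patches_per_slice: int = 25
    patch_size: int = 128
    val_fraction: float = 0.15
    checkpoint_every: int = 250
    split_level: str = "slice"   # "slice" (default) or "patient"
    seed: int = 0

    def validate(self) -> None:
        if min(self.learning_rate, self.iterations, self.minibatch,
               self.patches_per_slice, self.checkpoint_every) <= 0:
            raise ValueError("all training parameters must be positive")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")
        if any(w < 0 for w in self.class_weights):
            raise ValueError("class weights must be non-negative")
        if self.split_level not in ("slice", "patient"):
            raise ValueError("split_level must be 'slice' or 'patient'")


def weighted_cross_entropy(prob_plane: np.ndarray, label_plane: np.ndarray,
                           class_weights=(1.0, 5.0),
                           pixel_weights: np.ndarray | None = None,
                           eps: float = 1e-7) -> float:
    """Mean over pixels of w_pixel * w_class(label) * (-log p_label).

    ``prob_plane`` holds per-class probabilities on the last axis; labels are
    integer class indices.  Pixels with weight zero contribute nothing.
    """
    class_weights = np.asarray(class_weights, dtype=np.float64)
    if (class_weights < 0).any():
        raise ValueError("class weights must be non-negative")
    labels = np.asarray(label_plane)
    if prob_plane.shape[:-1] != labels.shape:
        raise ValueError(f"probability shape {prob_plane.shape[:-1]} does "
                         f"not match labels {labels.shape}")
    p_label = np.take_along_axis(
        np.asarray(prob_plane, dtype=np.float64),
        labels[..., None].astype(np.int64), axis=-1)[..., 0]
    nll = -np.log(np.clip(p_label, eps, 1.0))
    w = class_weights[labels]
    if pixel_weights is not None:
        pw = np.asarray(pixel_weights, dtype=np.float64)
        if (pw < 0).any():
            raise ValueError("pixel weights must be non-negative")
        if pw.shape != labels.shape:
            raise ValueError("pixel_weights shape mismatch")
        w = w * pw
    return float((w * nll).mean())


def softmax_ce_loss_grad(logits: np.ndarray, labels: np.ndarray,
                         class_weights=(1.0, 5.0),
                         pixel_weights: np.ndarray | None = None) -> tuple:
    """(loss, dL/dlogits) of the weighted softmax cross-entropy."""
    p = softmax(logits)
    loss = weighted_cross_entropy(p, labels, class_weights, pixel_weights)
    n_classes = logits.shape[-1]
    onehot = np.eye(n_classes, dtype=F32)[labels]
    w = np.asarray(class_weights, dtype=F32)[labels]
    if pixel_weights is not None:
        w = w * pixel_weights.astype(F32)
    dlogits = (p - onehot) * w[..., None] / F32(labels.size)
    return loss, dlogits.astype(F32, copy=False)


def select_best_checkpoint(val_losses: list) -> int:
    """Index of the checkpoint with minimal validation loss (ties: earliest)."""
    if not val_losses:
        raise ValueError("no checkpoints evaluated")
    return int(np.argmin(val_losses))


def _gather_lesion_slices(cases: list) -> list:
    out = []
    for i, case in enumerate(cases):
        out.extend((i, z) for z in lesion_slices(case))
    return out


def build_patch_pool(cases: list, slices: list, cfg: TrainConfig,
                     rng: np.random.Generator) -> list:
    pool = []
    for case_idx, z in slices:
        pool.extend(sample_training_patches(
            cases[case_idx], z, n_patches=cfg.patches_per_slice,
            patch_size=cfg.patch_size, rng=rng))
    return pool


def evaluate_pool_loss(net: DualPathwayNet, pool: list, class_weights,
                       batch: int = 4) -> float:
    """Mean per-pixel weighted cross-entropy over a patch pool (eval mode).

    The batch size deliberately matches training so the network's
    convolution workspaces are reused instead of reallocated.
    """
    total, count = 0.0, 0
    for start in range(0, len(pool), batch):
        chunk = pool[start:start + batch]
        xa, xb, y, w = batch_arrays(chunk)
        logits = net.forward(xa, xb, mode="eval")
        loss = weighted_cross_entropy(softmax(logits), y, class_weights, w)
        total += loss * y.size
        count += y.size
    return total / max(count, 1)


def train_base(train_cases: list, model_config: ModelConfig,
               train_config: TrainConfig) -> tuple:
    """Train the base network; returns (net at best validation loss, log).

    The training set consists solely of lesion-containing slices of the
    supplied cases; a val_fraction share of slices (or patients, per
    ``split_level``) is held out, and the checkpoint with the lowest
    validation loss is returned.
    """
    train_config.validate()
    if not train_cases:
        raise ValueError("empty training set")
    cases = [normalize_case(c) for c in train_cases]
    all_slices = _gather_lesion_slices(cases)
    if not all_slices:
        raise ValueError("no lesion-containing slices in the training set")

    root = np.random.SeedSequence(train_config.seed)
    s_split, s_pool, s_init, s_batch, s_rot, s_drop = root.spawn(6)
    split_rng = np.random.default_rng(s_split)

    if train_config.split_level == "patient":
        pids = np.arange(len(cases))
        split_rng.shuffle(pids)
        n_val = max(1, round(train_config.val_fraction * len(pids)))
        val_p = set(pids[:n_val].tolist())
        tr = [s for s in all_slices if s[0] not in val_p]
        va = [s for s in all_slices if s[0] in val_p]
    else:
        order = np.arange(len(all_slices))
        split_rng.shuffle(order)
        n_val = max(1, round(train_config.val_fraction * len(all_slices)))
        va = [all_slices[i] for i in order[:n_val]]
        tr = [all_slices[i] for i in order[n_val:]]
    if not tr:
        raise ValueError("training split is empty after validation holdout")

    pool_rng = np.random.default_rng(s_pool)
    train_pool = build_patch_pool(cases, tr, train_config, pool_rng)
    val_pool = build_patch_pool(cases, va, train_config, pool_rng)

    net = build_model(model_config, np.random.default_rng(s_init))
    opt, grads_fn = new_optimizer(net, train_config.learning_rate)
    batch_rng = np.random.default_rng(s_batch)
    rot_rng = np.random.default_rng(s_rot)
    drop_rng = np.random.default_rng(s_drop)

    log = {"train_loss": [], "val_loss": [], "checkpoint_iters": [],
           "n_train_slices": len(tr), "n_val_slices": len(va),
           "n_train_patches": len(train_pool), "seed": train_config.seed}
    best = None

    for it in range(1, train_config.iterations + 1):
        idx = batch_rng.integers(0, len(train_pool), train_config.minibatch)
        patches = [augment_rotate(train_pool[i], rot_rng) for i in idx]
        xa, xb, y, w = batch_arrays(patches)
        logits = net.forward(xa, xb, mode="train", rng=drop_rng)
        loss, dlogits = softmax_ce_loss_grad(
            logits, y, train_config.class_weights)
        net.backward(dlogits)
        opt.step(grads_fn())
        if (it % train_config.checkpoint_every == 0
                or it == train_config.iterations):
            val_loss = evaluate_pool_loss(net, val_pool,
                                          train_config.class_weights)
            log["train_loss"].append(float(loss))
            log["val_loss"].append(float(val_loss))
            log["checkpoint_iters"].append(it)
            if best is None or val_loss < best[0]:
                best = (val_loss,
                        {k: v.copy() for k, v in net.state_arrays().items()})

    net.set_state(best[1])
    sel = select_best_checkpoint(log["val_loss"])
    log["selected_iteration"] = log["checkpoint_iters"][sel]
    log["selected_val_loss"] = log["val_loss"][sel]
    return net, log
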