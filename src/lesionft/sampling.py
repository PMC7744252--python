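"""Slice and patch extraction with rotation augmentation.

Patches are 2D windows (default 128x128) cut identically from both sequences,
the lesion annotation and an optional per-pixel weight map.  Base training
samples patch offsets uniformly among all positions whose footprint touches
the organ mask ("patches originate from the organ of interest" and may
overlap); fine-tuning uses a deterministic five-patch layout per slice: the
four corners of the organ bounding box plus its center.

Intensities are normalized per volume (1st-99th percentile to [0, 1], per
channel) before patching.  Slices smaller than the patch size are zero-padded
symmetrically.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

from .io import AnnotatedCase

DEFAULT_PATCH_SIZE = 128
ROTATION_MAX_DEG = 45.0


class SamplingError(RuntimeError):
    pass


@dataclasses.dataclass
class PatchSample:
    """One training/fine-tuning sample (all planes patch_size x patch_size)."""

    input_a: np.ndarray      # (ps, ps, c1)
    input_b: np.ndarray      # (ps, ps, c2)
    label: np.ndarray        # (ps, ps) in {0, 1}
    pixel_weights: np.ndarray  # (ps, ps) >= 0
    patch_size: int
    provenance: tuple        # (patient_id, slice index, (row, col) offset)

    def validate(self) -> None:
        ps = self.patch_size
        for name in ("input_a", "input_b", "label", "pixel_weights"):
            arr = getattr(self, name)
            if arr.shape[:2] != (ps, ps):
                raise ValueError(f"{name} plane is {arr.shape[:2]}, "
                                 f"expected {(ps, ps)}")
        if not np.isin(self.label, (0, 1)).all():
            raise ValueError("label patch must be binary")
        if (self.pixel_weights < 0).any():
            raise ValueError("pixel weights must be non-negative")


def normalize_volume(vol: np.ndarray) -> np.ndarray:
    """Percentile (1-99) rescale of a (Z, Y, X, C) volume to [0, 1] per channel."""
    vol = np.asarray(vol, dtype=np.float32)
    out = np.empty_like(vol)
    for c in range(vol.shape[-1]):
        lo, hi = np.percentile(vol[..., c], (1.0, 99.0))
        if hi <= lo:
            out[..., c] = 0.0
        else:
            out[..., c] = np.clip((vol[..., c] - lo) / (hi - lo), 0.0, 1.0)
    return out


def normalize_case(case: AnnotatedCase) -> AnnotatedCase:
    """Copy of the case with percentile-normalized sequence intensities."""
    return AnnotatedCase(
        patient_id=case.patient_id, timepoint=case.timepoint,
        sequences=[normalize_volume(s) for s in case.sequences],
        organ_mask=case.organ_mask, lesion_mask=case.lesion_mask,
        spacing_mm=case.spacing_mm)


def lesion_slices(case: AnnotatedCase) -> list:
    """Ascending Z indices of slices with at least one annotated lesion pixel."""
    if case.lesion_mask is None:
        raise ValueError(f"case {case.patient_id}/{case.timepoint} has no "
                         f"lesion annotation")
    return np.flatnonzero(case.lesion_mask.any(axis=(1, 2))).tolist()


def organ_slices(case: AnnotatedCase) -> list:
    return np.flatnonzero(case.organ_mask.any(axis=(1, 2))).tolist()


def _pad_to(arr: np.ndarray, patch_size: int) -> np.ndarray:
    """Zero-pad the leading two axes symmetrically up to patch_size."""
    h, w = arr.shape[:2]
    ph, pw = max(patch_size - h, 0), max(patch_size - w, 0)
    if ph == 0 and pw == 0:
        return arr
    pad = ((ph // 2, ph - ph // 2), (pw // 2, pw - pw // 2)) \
        + ((0, 0),) * (arr.ndim - 2)
    return np.pad(arr, pad)


def _slice_planes(case: AnnotatedCase, slice_idx: int, patch_size: int,
                  weight_volume: np.ndarray | None):
    if not 0 <= slice_idx < case.n_slices:
        raise SamplingError(f"slice {slice_idx} outside volume "
                            f"(0..{case.n_slices - 1})")
    planes = {
        "a": _pad_to(case.sequences[0][slice_idx], patch_size),
        "b": _pad_to(case.sequences[1][slice_idx], patch_size),
        "organ": _pad_to(case.organ_mask[slice_idx], patch_size),
    }
    label = case.lesion_mask[slice_idx] if case.lesion_mask is not None \
        else np.zeros(case.shape[1:], np.uint8)
    planes["label"] = _pad_to(label, patch_size)
    w = weight_volume[slice_idx] if weight_volume is not None \
        else np.ones(case.shape[1:], np.float32)
    planes["weights"] = _pad_to(w.astype(np.float32), patch_size)
    return planes


def _cut(planes: dict, r: int, c: int, ps: int, case, slice_idx) -> PatchSample:
    win = (slice(r, r + ps), slice(c, c + ps))
    return PatchSample(
        input_a=planes["a"][win], input_b=planes["b"][win],
        label=planes["label"][win].astype(np.uint8),
        pixel_weights=planes["weights"][win], patch_size=ps,
        provenance=(case.patient_id, slice_idx, (r, c)))


def valid_patch_offsets(organ_plane: np.ndarray, patch_size: int) -> np.ndarray:
    """All (row, col) top-left offsets whose window intersects the organ.

    Computed with a 2D summed-area table over the organ plane.
    """
    h, w = organ_plane.shape
    ps = patch_size
    if h < ps or w < ps:
        raise ValueError("plane smaller than patch; pad first")
    ii = np.zeros((h + 1, w + 1), np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(organ_plane, axis=0), axis=1)
    sums = (ii[ps:, ps:] - ii[:-ps, ps:] - ii[ps:, :-ps] + ii[:-ps, :-ps])
    return np.argwhere(sums > 0)


def sample_training_patches(case: AnnotatedCase, slice_idx: int,
                            n_patches: int = 25,
                            patch_size: int = DEFAULT_PATCH_SIZE,
                            rng: np.random.Generator | None = None,
                            weight_volume: np.ndarray | None = None) -> list:
    """n_patches random organ-intersecting patches from one slice.

    Offsets are drawn uniformly (with replacement) from all valid top-left
    positions, so patches may overlap.
    """
    if n_patches == 0:
        return []
    if rng is None:
        raise ValueError("rng is required for random patch sampling")
    planes = _slice_planes(case, slice_idx, patch_size, weight_volume)
    offsets = valid_patch_offsets(planes["organ"], patch_size)
    if len(offsets) == 0:
        raise SamplingError(
            f"slice {slice_idx} of {case.patient_id}/{case.timepoint}: no "
            f"patch position intersects the organ mask")
    picks = offsets[rng.integers(0, len(offsets), size=n_patches)]
    return [_cut(planes, int(r), int(c), patch_size, case, slice_idx)
            for r, c in picks]


def sample_ft_patches(case: AnnotatedCase, slice_idx: int,
                      patch_size: int = DEFAULT_PATCH_SIZE,
                      weight_volume: np.ndarray | None = None) -> list:
    """The deterministic five fine-tuning patches of one slice.

    Four patches anchor at the corners of the organ bounding box (clipped to
    stay inside the image) and one is centered on the box centroid.
    """
    planes = _slice_planes(case, slice_idx, patch_size, weight_volume)
    organ = planes["organ"]
    if organ.sum() == 0:
        raise SamplingError(
            f"slice {slice_idx} of {case.patient_id}/{case.timepoint}: "
            f"organ mask empty")
    rows = np.flatnonzero(organ.any(axis=1))
    cols = np.flatnonzero(organ.any(axis=0))
    r0, r1 = int(rows[0]), int(rows[-1])
    c0, c1 = int(cols[0]), int(cols[-1])
    h, w = organ.shape
    ps = patch_size

    def clip(r, c):
        return (int(np.clip(r, 0, h - ps)), int(np.clip(c, 0, w - ps)))

    anchors = [
        clip(r0, c0),                          # top-left
        clip(r0, c1 - ps + 1),                 # top-right
        clip(r1 - ps + 1, c0),                 # bottom-left
        clip(r1 - ps + 1, c1 - ps + 1),        # bottom-right
        clip((r0 + r1 + 1) // 2 - ps // 2,     # center
             (c0 + c1 + 1) // 2 - ps // 2),
    ]
    return [_cut(planes, r, c, ps, case, slice_idx) for r, c in anchors]


def augment_rotate(patch: PatchSample, rng: np.random.Generator | None = None,
                   angle: float | None = None) -> PatchSample:
    """Rotate all planes of a patch by one shared angle ~ U(-45, +45) degrees.

    Images are interpolated bilinearly; label and weight planes use
    nearest-neighbor so they keep their discrete values.  Out-of-frame areas
    fill with zeros.
    """
    if angle is None:
        if rng is None:
            raise ValueError("either rng or an explicit angle is required")
        angle = float(rng.uniform(-ROTATION_MAX_DEG, ROTATION_MAX_DEG))
    if angle == 0.0:
        return patch

    def rot(arr, order):
        return ndimage.rotate(arr, angle, axes=(0, 1), reshape=False,
                              order=order, mode="constant", cval=0.0)

    return PatchSample(
        input_a=rot(patch.input_a, 1).astype(np.float32),
        input_b=rot(patch.input_b, 1).astype(np.float32),
        label=rot(patch.label, 0).astype(np.uint8),
        pixel_weights=rot(patch.pixel_weights, 0).astype(np.float32),
        patch_size=patch.patch_size,
        provenance=patch.provenance)


def batch_arrays(patches: list) -> tuple:
    """Stack PatchSamples into (xa, xb, labels, weights) float32 batches."""
    xa = np.stack([p.input_a for p in patches]).astype(np.float32)
    xb = np.stack([p.input_b for p in patches]).astype(np.float32)
    y = np.stack([p.label for p in patches]).astype(np.int64)
    w = np.stack([p.pixel_weights for p in patches]).astype(np.float32)
    return xa, xb, y, w
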