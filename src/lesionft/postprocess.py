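"""Probability-map postprocessing and lesion-object extraction.

Pipeline: mask the probability volume by the organ mask, threshold at 0.5,
3D morphological closing (3x3x3 cube) to fill holes, optionally a per-slice
2D opening with a plus-shaped 3x3 element to remove single noise pixels
(used for the liver profile; disabled for brain, where one-pixel lesions are
real), re-mask, then split into 26-connected objects.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import ndimage

PLUS_2D = np.array([[0, 1, 0],
                    [1, 1, 1],
                    [0, 1, 0]], bool)
CUBE_3D = np.ones((3, 3, 3), bool)


@dataclasses.dataclass(frozen=True)
class PostprocessProfile:
    name: str
    threshold: float = 0.5
    opening_enabled: bool = False

    def validate(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


LIVER_PROFILE = PostprocessProfile(name="liver", opening_enabled=True)
BRAIN_PROFILE = PostprocessProfile(name="brain", opening_enabled=False)
PROFILES = {"liver": LIVER_PROFILE, "brain": BRAIN_PROFILE}


def postprocess(prob_volume: np.ndarray, organ_mask: np.ndarray,
                profile: PostprocessProfile = BRAIN_PROFILE) -> np.ndarray:
    """Binary lesion volume from a probability volume (see module docstring).

    Thresholding uses >= (ties count as lesion).  Closing never reintroduces
    voxels outside the organ: the result is re-masked after morphology.
    """
    profile.validate()
    prob_volume = np.asarray(prob_volume)
    if prob_volume.shape != organ_mask.shape:
        raise ValueError(f"probability volume {prob_volume.shape} and organ "
                         f"mask {organ_mask.shape} shapes differ")
    if prob_volume.min() < 0 or prob_volume.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    organ = organ_mask.astype(bool)
    binary = (prob_volume >= profile.threshold) & organ
    # closing = dilation then erosion; border_value=1 for the erosion so the
    # volume border does not erode objects
    dilated = ndimage.binary_dilation(binary, structure=CUBE_3D)
    closed = ndimage.binary_erosion(dilated, structure=CUBE_3D,
                                    border_value=1)
    if profile.opening_enabled:
        opened = np.empty_like(closed)
        for z in range(closed.shape[0]):
            opened[z] = ndimage.binary_opening(closed[z], structure=PLUS_2D)
        closed = opened
    return (closed & organ).astype(np.uint8)


@dataclasses.dataclass
class LesionObjectSet:
    """Connected lesion objects of one binary volume (full connectivity)."""

    labels: np.ndarray       # int32, 0 = background, 1..n_objects
    n_objects: int
    voxel_counts: np.ndarray  # (n_objects,)
    volumes_mm3: np.ndarray   # (n_objects,)
    spacing_mm: tuple

    def object_mask(self, object_id: int) -> np.ndarray:
        return self.labels == object_id

    @property
    def any_mask(self) -> np.ndarray:
        return self.labels > 0


def label_objects(binary_volume: np.ndarray, spacing_mm) -> LesionObjectSet:
    """26-connected component labeling with per-object volumes in mm^3."""
    binary_volume = np.asarray(binary_volume)
    if not np.isin(binary_volume, (0, 1)).all():
        raise ValueError("label_objects expects a binary volume")
    structure = np.ones((3,) * binary_volume.ndim, bool)
    labels, n = ndimage.label(binary_volume, structure=structure)
    counts = np.bincount(labels.ravel(), minlength=n + 1)[1:].astype(np.int64)
    voxel = float(np.prod(spacing_mm))
    return LesionObjectSet(labels=labels.astype(np.int32), n_objects=int(n),
                           voxel_counts=counts,
                           volumes_mm3=counts * voxel,
                           spacing_mm=tuple(float(s) for s in spacing_mm))
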