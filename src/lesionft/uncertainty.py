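"""Monte-Carlo-dropout uncertainty estimation.

The test phase is repeated (default 25 times) with dropout active; the
per-voxel standard deviation of the lesion probability over repetitions is
the uncertainty map.  Two scalar summaries: for detection tasks, the mean SD
over all voxels of the detected objects (voxel-pooled across objects); for
segmentation tasks, the maximum SD inside the organ.
"""

from __future__ import annotations

import numpy as np

from .io import AnnotatedCase
from .nn.model import DualPathwayNet
from .postprocess import LesionObjectSet
from .predict import predict_volume
from .sampling import normalize_case

DEFAULT_REPETITIONS = 25


def probability_sd(prob_stack: np.ndarray) -> np.ndarray:
    """Per-voxel sample SD (n-1 denominator) over the repetition axis (0)."""
    prob_stack = np.asarray(prob_stack, dtype=np.float64)
    if prob_stack.shape[0] < 2:
        raise ValueError("need at least 2 repetitions")
    return prob_stack.std(axis=0, ddof=1).astype(np.float32)


def mc_dropout_predict(net: DualPathwayNet, case: AnnotatedCase,
                       repetitions: int = DEFAULT_REPETITIONS,
                       rng: np.random.Generator | None = None) -> tuple:
    """(sd_map, mean probability map) over stochastic forward passes.

    Dropout stays active at test time; batch norm uses its frozen running
    statistics.  With dropout rate 0 the network is deterministic and the SD
    map is identically zero.
    """
    if repetitions < 2:
        raise ValueError("repetitions must be >= 2")
    if rng is None:
        rng = np.random.default_rng(0)
    norm = normalize_case(case)
    stack = np.empty((repetitions,) + case.shape, np.float32)
    for r in range(repetitions):
        stack[r] = predict_volume(net, norm, mode="mc", rng=rng,
                                  normalized=True)
    return probability_sd(stack), stack.mean(axis=0)


def summarize_uncertainty(sd_map: np.ndarray,
                          detected_objects: LesionObjectSet | None = None,
                          mode: str = "detection",
                          organ_mask: np.ndarray | None = None) -> float:
    """Scalar uncertainty summary.

    mode='detection': mean SD over all voxels belonging to detected objects
    (voxel-pooled, i.e. larger objects weigh more); NaN when no objects were
    detected.  mode='segmentation': maximum SD over the (organ-masked) volume.
    """
    sd_map = np.asarray(sd_map)
    if mode == "detection":
        if detected_objects is None:
            raise ValueError("detection mode requires detected_objects")
        voxels = detected_objects.any_mask
        if not voxels.any():
            return float("nan")
        return float(sd_map[voxels].mean())
    if mode == "segmentation":
        region = sd_map if organ_mask is None else sd_map[organ_mask > 0]
        return float(region.max())
    raise ValueError(f"unknown mode {mode!r}")
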