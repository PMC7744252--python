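"""Whole-volume inference.

The network is fully convolutional, so each slice is processed in full (no
tiling); slices are batched and restacked into a 3D lesion-probability
volume.  Intensities are percentile-normalized exactly as during training.
"""

from __future__ import annotations

import numpy as np

from .io import AnnotatedCase
from .nn.model import DualPathwayNet
from .nn.ops import softmax
from .sampling import normalize_case


def predict_volume(net: DualPathwayNet, case: AnnotatedCase,
                   mode: str = "eval", rng: np.random.Generator | None = None,
                   batch_slices: int = 8,
                   normalized: bool = False) -> np.ndarray:
    """Per-voxel lesion probability (Z, Y, X) for one case.

    mode='eval' gives the deterministic prediction; mode='mc' keeps dropout
    active for Monte Carlo sampling.  Set ``normalized`` if the case's
    intensities were already percentile-normalized.
    """
    if mode not in ("eval", "mc"):
        raise ValueError("mode must be 'eval' or 'mc'")
    if not normalized:
        case = normalize_case(case)
    va = case.sequences[0].astype(np.float32)
    vb = case.sequences[1].astype(np.float32)
    nz = case.n_slices
    prob = np.empty(case.shape, np.float32)
    for start in range(0, nz, batch_slices):
        sl = slice(start, min(start + batch_slices, nz))
        logits = net.forward(va[sl], vb[sl], mode=mode, rng=rng)
        prob[sl] = softmax(logits)[..., 1]
    return prob
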