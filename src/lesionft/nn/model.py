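"""Dual-pathway dilated fully-convolutional network.

Two independent pathways (one per MRI sequence) of thirteen 3x3 convolutions
each (64 kernels, BN + ReLU, dilation rates per schedule), split into five
blocks.  The feature maps at the end of every block of both pathways are
concatenated on the channel axis (5 blocks x 2 pathways x 64 = 640 channels
for the default width) and passed to a head of two 1x1 convolutions
(128 kernels with BN + ReLU, then n_classes kernels with a per-pixel softmax).
Dropout (rate 0.2) is applied before and after the 128-kernel layer.

The head -- exactly the two 1x1 convolutions -- is the trainable subset during
patient-specific fine-tuning; everything else (pathway convolutions and all
batch-norm parameters and statistics) is the frozen body.

Because every convolution is stride-1 with zero same-padding, the network is
fully convolutional: any spatial input size maps to an equally sized output.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict

import numpy as np

from .ops import F32, Adam, BNReLU, Conv1x1, ConvBNReLU, Dropout, softmax

DEFAULT_DILATIONS = (1, 1, 2, 2, 4, 4, 4, 8, 8, 8, 8, 8, 3)
DEFAULT_BLOCKS = (2, 2, 3, 3, 3)

CHECKPOINT_FORMAT_VERSION = 1


@dataclass
class ModelConfig:
    """Architecture hyperparameters.

    Defaults reproduce the published network: 13 conv layers per pathway
    (two plain + eleven dilated), 64 kernels each, five blocks, a
    (128, n_classes) head and dropout rate 0.2.  The dilation schedule sums
    to 61, giving the stated 123x123 receptive field.
    """

    channels_per_pathway: tuple = (16, 3)
    kernels_per_conv: int = 64
    dilation_schedule: tuple = DEFAULT_DILATIONS
    block_sizes: tuple = DEFAULT_BLOCKS
    head_channels: tuple = (128, 2)
    dropout_rate: float = 0.2
    n_classes: int = 2

    def validate(self) -> None:
        if len(self.dilation_schedule) != 13:
            raise ValueError(
                f"dilation_schedule must list 13 rates, got "
                f"{len(self.dilation_schedule)}")
        if sum(self.block_sizes) != 13 or len(self.block_sizes) != 5:
            raise ValueError("block_sizes must be 5 ints summing to 13")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.head_channels[1] != self.n_classes:
            raise ValueError("last head layer must have n_classes kernels")
        if any(d < 1 for d in self.dilation_schedule):
            raise ValueError("dilation rates must be positive")

    @property
    def concat_channels(self) -> int:
        return len(self.block_sizes) * 2 * self.kernels_per_conv

    @classmethod
    def scaled(cls, kernels: int, channels_per_pathway=(2, 1),
               n_classes: int = 2) -> "ModelConfig":
        """A width-scaled configuration (head shrinks proportionally)."""
        return cls(channels_per_pathway=tuple(channels_per_pathway),
                   kernels_per_conv=kernels,
                   head_channels=(max(2 * kernels, n_classes), n_classes),
                   n_classes=n_classes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        for key in ("channels_per_pathway", "dilation_schedule",
                    "block_sizes", "head_channels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def receptive_field(config: ModelConfig) -> int:
    """Analytic receptive-field side length of one pathway in pixels.

    For a stack of stride-1 3x3 convolutions with dilation rates d_i the
    receptive field is 1 + 2 * sum_i d_i; the 1x1 head layers add nothing.
    """
    return 1 + 2 * int(sum(config.dilation_schedule))


class _Pathway:
    """Thirteen fused conv+BN+ReLU layers; exposes block-endpoint features."""

    def __init__(self, c_in: int, config: ModelConfig, rng: np.random.Generator):
        k = config.kernels_per_conv
        self.layers: list[ConvBNReLU] = []
        c = c_in
        for d in config.dilation_schedule:
            self.layers.append(ConvBNReLU(c, k, d, rng))
            c = k
        # zero-based indices of layers whose output ends a block
        ends, pos = [], -1
        for size in config.block_sizes:
            pos += size
            ends.append(pos)
        self.block_ends = ends

    def forward(self, x: np.ndarray, training: bool) -> list:
        feats = []
        for i, layer in enumerate(self.layers):
            x = layer.forward_train(x) if training else layer.forward_eval(x)
            if i in self.block_ends:
                feats.append(x)
        return feats

    def backward(self, dfeats: list) -> None:
        dy = None
        block_grad = dict(zip(self.block_ends, dfeats))
        for i in range(12, -1, -1):
            if i in block_grad:
                dy = block_grad[i] if dy is None else dy + block_grad[i]
            dy = self.layers[i].backward(dy, need_dx=(i > 0))


class DualPathwayNet:
    """The trainable network with named body and head parameter subsets."""

    def __init__(self, config: ModelConfig, rng: np.random.Generator):
        config.validate()
        self.config = config
        c1, c2 = config.channels_per_pathway
        self.pathway_a = _Pathway(c1, config, rng)
        self.pathway_b = _Pathway(c2, config, rng)
        h1, _ = config.head_channels
        self.drop1 = Dropout(config.dropout_rate)
        self.head_conv1 = Conv1x1(config.concat_channels, h1, rng, bias=False)
        self.head_bn = BNReLU(h1)
        self.drop2 = Dropout(config.dropout_rate)
        self.head_conv2 = Conv1x1(h1, config.n_classes, rng, bias=True)
        self._cached_feats = None

    # -- forward -----------------------------------------------------------

    def forward(self, xa: np.ndarray, xb: np.ndarray, mode: str = "eval",
                rng: np.random.Generator | None = None) -> np.ndarray:
        """Return logits of shape (B, H, W, n_classes).

        mode: 'train' (batch-stats BN, dropout, full caching),
              'ft'    (frozen BN, dropout, head-only caching),
              'eval'  (frozen BN, no dropout),
              'mc'    (frozen BN, dropout active: Monte Carlo dropout).
        """
        if mode not in ("train", "ft", "eval", "mc"):
            raise ValueError(f"unknown mode {mode!r}")
        self._check_inputs(xa, xb)
        training = mode == "train"
        cache_head = mode in ("train", "ft")
        dropout_on = mode in ("train", "ft", "mc")
        if dropout_on and self.config.dropout_rate > 0 and rng is None:
            raise ValueError("dropout is active but no rng was provided")

        fa = self.pathway_a.forward(xa, training)
        fb = self.pathway_b.forward(xb, training)
        feat = np.concatenate(fa + fb, axis=-1)

        x = self.drop1.forward(feat, rng, dropout_on, cache_head)
        if cache_head:
            self._split_sizes = [f.shape[-1] for f in fa + fb]
        x = self.head_conv1.forward(x, cache_head)
        x = self.head_bn.forward(x, training)
        x = self.drop2.forward(x, rng, dropout_on, cache_head)
        return self.head_conv2.forward(x, cache_head)

    def _check_inputs(self, xa, xb):
        c1, c2 = self.config.channels_per_pathway
        if xa.ndim != 4 or xb.ndim != 4:
            raise ValueError("inputs must be (B, H, W, C) tensors")
        if xa.shape[-1] != c1 or xb.shape[-1] != c2:
            raise ValueError(
                f"channel mismatch: got ({xa.shape[-1]}, {xb.shape[-1]}), "
                f"config expects {self.config.channels_per_pathway}")
        if xa.shape[:3] != xb.shape[:3]:
            raise ValueError("pathway inputs must share spatial shape")

    # -- backward ----------------------------------------------------------

    def backward(self, dlogits: np.ndarray, head_only: bool = False) -> None:
        dy = self.head_conv2.backward(dlogits)
        dy = self.drop2.backward(dy)
        dy = self.head_bn.backward(dy)
        dy = self.head_conv1.backward(dy, need_dx=not head_only)
        if head_only:
            return
        dy = self.drop1.backward(dy)
        parts = np.split(dy, np.cumsum(self._split_sizes)[:-1], axis=-1)
        n = len(parts) // 2
        self.pathway_a.backward(list(parts[:n]))
        self.pathway_b.backward(list(parts[n:]))

    # -- inference ---------------------------------------------------------

    def predict_slice(self, input_a: np.ndarray, input_b: np.ndarray,
                      mode: str = "eval",
                      rng: np.random.Generator | None = None) -> np.ndarray:
        """Lesion-class probability plane for one 2D slice.

        Accepts (H, W) single-channel or (H, W, C) inputs; returns (H, W)
        probabilities of the lesion class (softmax class index 1).
        """
        xa = _as_batch(input_a)
        xb = _as_batch(input_b)
        logits = self.forward(xa, xb, mode=mode, rng=rng)
        return softmax(logits)[0, :, :, 1]

    # -- parameter bookkeeping ----------------------------------------------

    def _pathway_items(self):
        for name, pw in (("a", self.pathway_a), ("b", self.pathway_b)):
            for i in range(13):
                yield f"pathway_{name}.conv{i}", pw.layers[i]

    def named_parameters(self) -> dict:
        out = {}
        for prefix, layer in self._pathway_items():
            out[f"{prefix}.W"] = layer.W
            out[f"{prefix}.bn.gamma"] = layer.gamma
            out[f"{prefix}.bn.beta"] = layer.beta
        out["head.conv1.W"] = self.head_conv1.W
        out["head.bn.gamma"] = self.head_bn.gamma
        out["head.bn.beta"] = self.head_bn.beta
        out["head.conv2.W"] = self.head_conv2.W
        out["head.conv2.b"] = self.head_conv2.b
        return out

    def named_bn_stats(self) -> dict:
        out = {}
        for prefix, layer in self._pathway_items():
            out[f"{prefix}.bn.running_mean"] = layer.running_mean
            out[f"{prefix}.bn.running_var"] = layer.running_var
        out["head.bn.running_mean"] = self.head_bn.running_mean
        out["head.bn.running_var"] = self.head_bn.running_var
        return out

    def head_parameter_names(self) -> list:
        """The fine-tunable subset: weights of the two final 1x1 convolutions."""
        return ["head.conv1.W", "head.conv2.W", "head.conv2.b"]

    def body_parameter_names(self) -> list:
        head = set(self.head_parameter_names())
        return [k for k in self.named_parameters() if k not in head]

    def trainable(self, head_only: bool = False):
        """(params, grads_fn) for the optimizer."""
        if head_only:
            layers = [self.head_conv1, self.head_conv2]
        else:
            layers = ([pw.layers[i] for pw in (self.pathway_a, self.pathway_b)
                       for i in range(13)]
                      + [self.head_conv1, self.head_bn, self.head_conv2])
        params = [p for l in layers for p in l.params()]

        def grads():
            return [g for l in layers for g in l.grads()]

        return params, grads

    def parameter_count(self) -> int:
        return sum(p.size for p in self.named_parameters().values())

    def state_arrays(self) -> dict:
        out = dict(self.named_parameters())
        out.update(self.named_bn_stats())
        return out

    def set_state(self, arrays: dict) -> None:
        own = self.state_arrays()
        missing = set(own) - set(arrays)
        if missing:
            raise ValueError(f"checkpoint missing arrays: {sorted(missing)}")
        for k, dst in own.items():
            src = np.asarray(arrays[k], dtype=dst.dtype)
            if src.shape != dst.shape:
                raise ValueError(f"shape mismatch for {k}: "
                                 f"{src.shape} vs {dst.shape}")
            dst[...] = src

    def copy(self) -> "DualPathwayNet":
        clone = DualPathwayNet(self.config, np.random.default_rng(0))
        clone.set_state({k: v.copy() for k, v in self.state_arrays().items()})
        return clone


def _as_batch(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=F32)
    if x.ndim == 2:
        x = x[:, :, None]
    if x.ndim != 3:
        raise ValueError("slice input must be (H, W) or (H, W, C)")
    return x[None]


def build_model(config: ModelConfig, rng: np.random.Generator | int
                ) -> DualPathwayNet:
    """Build and He-uniform-initialize the dual-pathway network."""
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    return DualPathwayNet(config, rng)


# -- checkpoints -------------------------------------------------------------

def save_checkpoint(net: DualPathwayNet, path, meta: dict | None = None) -> None:
    """Versioned checkpoint: parameters + BN statistics + config + metadata."""
    payload = {f"array.{k}": v for k, v in net.state_arrays().items()}
    header = {"format_version": CHECKPOINT_FORMAT_VERSION,
              "config": net.config.to_dict(),
              "meta": meta or {}}
    payload["header"] = np.frombuffer(
        json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **payload)


def load_checkpoint(path) -> tuple:
    """Return (net, meta) reconstructed from a checkpoint file."""
    with np.load(path) as z:
        header = json.loads(bytes(z["header"]).decode())
        if header.get("format_version") != CHECKPOINT_FORMAT_VERSION:
            raise ValueError("unsupported checkpoint format version")
        config = ModelConfig.from_dict(header["config"])
        net = build_model(config, np.random.default_rng(0))
        arrays = {k[len("array."):]: z[k] for k in z.files
                  if k.startswith("array.")}
        net.set_state(arrays)
    return net, header.get("meta", {})


def new_optimizer(net: DualPathwayNet, lr: float, head_only: bool = False):
    params, grads_fn = net.trainable(head_only=head_only)
    return Adam(params, lr=lr), grads_fn
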