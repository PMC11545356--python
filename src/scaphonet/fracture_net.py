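"""Stage-2 multi-view fracture network.

Each view (AP, LA) runs through its own backbone, per-level dilated-
convolution context extractors and an FPN (the two views have distinct
appearance statistics, so parameters are not shared).  Globally pooled FPN
features from corresponding levels feed the multi-view fusion module, whose
per-level weight transform gates both views' channels with a shared
importance vector before concatenation; the per-level fused vectors are
summed and classified as fracture / non-fracture.  Per-view prediction heads
emit dense per-anchor fracture scores and oriented-box regressions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nnkit
from .backbone import Backbone, BackboneConfig, FPN
from .nnkit import (
    Conv2d, ConvBNReLU, Linear, Module, Tensor, concat, global_avg_pool,
    leaky_relu, relu, reshape, sigmoid, softmax, transpose,
)

__all__ = [
    "ContextExtractorConfig", "HeadConfig", "ContextExtractor",
    "WeightTransform", "FusionModule", "ClassificationHead", "DetectionHead",
    "MultiViewFractureNet", "flatten_head_map",
]


@dataclass
class ContextExtractorConfig:
    """Four-branch context extractor: per-branch kernel sizes and dilation
    rates, each branch working on a quarter of the channels."""

    branch_kernel_sizes: tuple[int, ...] = (1, 3, 5, 7)
    branch_dilation_rates: tuple[int, ...] = (1, 2, 4, 8)
    # "accumulate": branch i's accumulated output is added into branch i+1's
    # output.  "pre_dilation": the previous branch output feeds the next
    # branch's dilated convolution input instead (cascade variant).
    mode: str = "accumulate"

    def __post_init__(self):
        if len(self.branch_kernel_sizes) != 4 or len(self.branch_dilation_rates) != 4:
            raise ValueError("context extractor requires exactly 4 branches")
        if self.mode not in ("accumulate", "pre_dilation"):
            raise ValueError(f"unknown context mode {self.mode!r}")

    def to_json(self) -> dict:
        return {"branch_kernel_sizes": list(self.branch_kernel_sizes),
                "branch_dilation_rates": list(self.branch_dilation_rates),
                "mode": self.mode}

    @classmethod
    def from_json(cls, obj: dict) -> "ContextExtractorConfig":
        return cls(tuple(obj["branch_kernel_sizes"]),
                   tuple(obj["branch_dilation_rates"]), obj["mode"])


@dataclass
class HeadConfig:
    """Prediction-head widths: A anchors per location, C detection classes.

    The detection branch emits A*5 channels (tx, ty, tw, th, raw theta) and
    the score branch A*C channels.
    """

    anchors_per_location: int
    num_classes: int = 1

    @property
    def score_channels(self) -> int:
        return self.anchors_per_location * self.num_classes

    @property
    def delta_channels(self) -> int:
        return self.anchors_per_location * 5


class _ContextBranch(Module):
    def __init__(self, cin: int, k: int, rate: int, rng: np.random.Generator):
        super().__init__()
        c4 = cin // 4
        self.compress = ConvBNReLU(cin, c4, rng, kernel_size=1)
        self.spatial = ConvBNReLU(c4, c4, rng, kernel_size=k)
        self.dilated = ConvBNReLU(c4, c4, rng, kernel_size=3, dilation=rate)


class ContextExtractor(Module):
    """Widens the receptive field without pooling via four dilated branches.

    Each branch: 1x1 channel compression to C/4, a k_i x k_i convolution and
    a 3x3 dilated convolution (rate r_i), every convolution followed by batch
    normalization and ReLU.  Branch outputs are combined cumulatively, then
    concatenated and integrated by a final 1x1 convolution back to C
    channels.  Spatial size is preserved.
    """

    def __init__(self, channels: int, config: ContextExtractorConfig,
                 rng: np.random.Generator):
        super().__init__()
        if channels % 4 != 0:
            raise ValueError("context extractor input channels must divide by 4")
        self.config = config
        self.branches = [
            _ContextBranch(channels, k, r, rng)
            for k, r in zip(config.branch_kernel_sizes, config.branch_dilation_rates)
        ]
        self.integrate = Conv2d(channels, channels, 1, rng, padding=0)

    def forward(self, x: Tensor) -> Tensor:
        outs: list[Tensor] = []
        prev: Tensor | None = None
        for branch in self.branches:
            t = branch.spatial.forward(branch.compress.forward(x))
            if self.config.mode == "pre_dilation" and prev is not None:
                t = t + prev
            y = branch.dilated.forward(t)
            if self.config.mode == "accumulate" and prev is not None:
                y = y + prev
            outs.append(y)
            prev = y
        return self.integrate.forward(concat(outs, axis=1))


class WeightTransform(Module):
    """Shared cross-view channel gate.

    Concatenates the two views' globally pooled vectors (2C), passes an
    affine layer down to C, a LeakyReLU, a second affine C -> C and a
    sigmoid, producing a per-channel weight in (0, 1) that multiplies both
    views' features.
    """

    def __init__(self, channels: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fc1 = Linear(2 * channels, channels, rng, dtype=dtype)
        self.fc2 = Linear(channels, channels, rng, dtype=dtype)

    def forward(self, ap_vec: Tensor, la_vec: Tensor) -> Tensor:
        if ap_vec.data.shape != la_vec.data.shape:
            raise ValueError("AP/LA pooled vector shape mismatch")
        z = concat([ap_vec, la_vec], axis=1)
        return sigmoid(self.fc2.forward(leaky_relu(self.fc1.forward(z))))


class FusionModule(Module):
    """Multi-view fusion over pyramid levels.

    Per level i: W_i = weight_transform_i(AP_i, LA_i); the level vector is
    concat(AP_i * W_i, LA_i * W_i); the fused vector is the elementwise sum
    of level vectors (all levels share the FPN channel count, so the sum is
    well defined).  ``force_weights`` overrides W_i with a constant for
    ablations (1.0 reduces fusion to plain concatenation + sum).
    """

    def __init__(self, channels: int, num_levels: int, rng: np.random.Generator,
                 dtype=np.float32):
        super().__init__()
        self.transforms = [WeightTransform(channels, rng, dtype=dtype)
                           for _ in range(num_levels)]

    def forward(self, ap_vecs: list[Tensor], la_vecs: list[Tensor],
                force_weights: float | None = None) -> Tensor:
        if len(ap_vecs) != len(la_vecs) or len(ap_vecs) != len(self.transforms):
            raise ValueError("pyramid level count mismatch in fusion")
        fused: Tensor | None = None
        for wt, ap, la in zip(self.transforms, ap_vecs, la_vecs):
            if force_weights is None:
                w = wt.forward(ap, la)
            else:
                w = Tensor(np.full_like(ap.data, force_weights))
            level = concat([ap * w, la * w], axis=1)
            fused = level if fused is None else fused + level
        return fused


class ClassificationHead(Module):
    """Fusion classifier: affine halving the width, ReLU, affine to 2 logits,
    softmax over (fracture, non-fracture)."""

    def __init__(self, in_features: int, rng: np.random.Generator, dtype=np.float32):
        super().__init__()
        self.fc1 = Linear(in_features, in_features // 2, rng, dtype=dtype)
        self.fc2 = Linear(in_features // 2, 2, rng, dtype=dtype)

    def forward_logits(self, fused: Tensor) -> Tensor:
        return self.fc2.forward(relu(self.fc1.forward(fused)))

    def forward(self, fused: Tensor) -> Tensor:
        return softmax(self.forward_logits(fused), axis=1)


class DetectionHead(Module):
    """Per-level prediction head: parallel score and box branches, each a 3x3
    convolution + batch norm + ReLU followed by a 3x3 output convolution."""

    def __init__(self, channels: int, head: HeadConfig, rng: np.random.Generator):
        super().__init__()
        self.head = head
        self.score_stem = ConvBNReLU(channels, channels, rng)
        self.score_out = Conv2d(channels, head.score_channels, 3, rng)
        self.delta_stem = ConvBNReLU(channels, channels, rng)
        self.delta_out = Conv2d(channels, head.delta_channels, 3, rng)

    def forward(self, x: Tensor) -> tuple[Tensor, Tensor]:
        return (self.score_out.forward(self.score_stem.forward(x)),
                self.delta_out.forward(self.delta_stem.forward(x)))


def flatten_head_map(t: Tensor, anchors_per_loc: int, depth: int) -> Tensor:
    """(N, A*D, H, W) -> (N, H*W*A, D) in (y, x, anchor) order.

    The order matches the anchor-grid construction, so concatenating levels
    aligns head outputs with the flattened anchor list bijectively.
    """
    n, c, h, w = t.data.shape
    if c != anchors_per_loc * depth:
        raise ValueError("head channel count does not factor as A*D")
    t = reshape(t, (n, anchors_per_loc, depth, h, w))
    t = transpose(t, (0, 3, 4, 1, 2))  # (N, H, W, A, D)
    return reshape(t, (n, h * w * anchors_per_loc, depth))


class MultiViewFractureNet(Module):
    """The full stage-2 model: two view pathways + fusion classifier."""

    def __init__(self, backbone_config: BackboneConfig,
                 context_config: ContextExtractorConfig,
                 head_config: HeadConfig,
                 fpn_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.backbone_config = backbone_config
        self.context_config = context_config
        self.head_config = head_config
        self.fpn_channels = fpn_channels
        stage_ch = list(backbone_config.stage_channels[-3:])
        for view in ("ap", "la"):
            setattr(self, f"{view}_backbone", Backbone(backbone_config, rng))
            setattr(self, f"{view}_context",
                    [ContextExtractor(c, context_config, rng) for c in stage_ch])
            setattr(self, f"{view}_fpn", FPN(stage_ch, fpn_channels, rng))
            setattr(self, f"{view}_heads",
                    [DetectionHead(fpn_channels, head_config, rng)
                     for _ in range(3)])
        self.fusion = FusionModule(fpn_channels, 3, rng)
        self.classifier = ClassificationHead(2 * fpn_channels, rng)

    # -- single-view pathway ---------------------------------------------
    def _view_forward(self, view: str, x: Tensor
                      ) -> tuple[list[Tensor], Tensor, Tensor]:
        backbone: Backbone = getattr(self, f"{view}_backbone")
        contexts = getattr(self, f"{view}_context")
        fpn: FPN = getattr(self, f"{view}_fpn")
        heads = getattr(self, f"{view}_heads")
        stages = backbone.forward(x)
        enriched = [ctx.forward(s) for ctx, s in zip(contexts, stages)]
        pyramid = fpn.forward(enriched)
        scores, deltas = [], []
        a = self.head_config.anchors_per_location
        for head, level in zip(heads, pyramid):
            s, d = head.forward(level)
            scores.append(flatten_head_map(s, a, self.head_config.num_classes))
            deltas.append(flatten_head_map(d, a, 5))
        return pyramid, concat(scores, axis=1), concat(deltas, axis=1)

    def forward_pair(self, ap_pixels: np.ndarray, la_pixels: np.ndarray,
                     force_fusion_weights: float | None = None,
                     ) -> tuple[Tensor, dict[str, dict[str, Tensor]]]:
        """Run both views and the fusion classifier in one call.

        ``ap_pixels`` / ``la_pixels`` are (N, 1, H, W) float arrays in
        [0, 1].  Returns the (N, 2) fusion probabilities (fracture,
        non-fracture) and per-view raw head outputs aligned to the anchor
        order: ``scores`` (N, M, C) pre-sigmoid, ``deltas`` (N, M, 5) with a
        raw (un-squashed) angle in the last component.
        """
        if ap_pixels is None or la_pixels is None:
            raise ValueError("multi-view model requires both AP and LA crops")
        ap_pyr, ap_scores, ap_deltas = self._view_forward("ap", Tensor(ap_pixels))
        la_pyr, la_scores, la_deltas = self._view_forward("la", Tensor(la_pixels))
        ap_vecs = [global_avg_pool(m) for m in ap_pyr]
        la_vecs = [global_avg_pool(m) for m in la_pyr]
        fused = self.fusion.forward(ap_vecs, la_vecs,
                                    force_weights=force_fusion_weights)
        logits = self.classifier.forward_logits(fused)
        probs = softmax(logits, axis=1)
        return probs, {
            "AP": {"scores": ap_scores, "deltas": ap_deltas},
            "LA": {"scores": la_scores, "deltas": la_deltas},
            "fusion_logits": logits,
        }

    def config_json(self) -> dict:
        return {
            "backbone": self.backbone_config.to_json(),
            "context": self.context_config.to_json(),
            "head": {"anchors_per_location": self.head_config.anchors_per_location,
                     "num_classes": self.head_config.num_classes},
            "fpn_channels": self.fpn_channels,
        }


def build_fracture_net(config_obj: dict, rng: np.random.Generator
                       ) -> MultiViewFractureNet:
    """Rebuild a model from its embedded checkpoint configuration."""
    return MultiViewFractureNet(
        BackboneConfig.from_json(config_obj["backbone"]),
        ContextExtractorConfig.from_json(config_obj["context"]),
        HeadConfig(**config_obj["head"]),
        config_obj["fpn_channels"],
        rng,
    )
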