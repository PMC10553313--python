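"""Three-scale recurrent-attention cascade.

Each scale owns an independent five-stage VGG-style backbone (3x3
convolutions, 2x2 max pooling, so five pooling levels), five pooling-level
softmax heads P1..P5, and a small attention-proposal head (APN) that
regresses a square attention box from the deepest features.  Scale 1
consumes the full image; each scale's box is cropped-and-zoomed (smooth
mask + bilinear resampling, differentiable in the box parameters) to form
the next scale's input.  The deepest head P5 defines the scale's
classification output; P1..P4 exist as fusion inputs for the PSO stage.
Soft voting — a weighted arithmetic mean of probability vectors — combines
the three scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .attention import AttentionBox, CropConfig, attention_crop_tensors, clamp_box
from .autodiff import Tensor

__all__ = [
    "BackboneConfig",
    "ScaleOutput",
    "CascadeOutput",
    "CascadeModel",
    "soft_vote",
]


@dataclass(frozen=True)
class BackboneConfig:
    """Per-scale backbone shape.  n_stages is fixed at 5: the five pooling
    levels are load-bearing for the fusion stage."""

    channels: tuple[int, ...] = (16, 32, 64, 64, 64)
    input_size: int = 64
    n_classes: int = 4
    dropout_rate: float = 0.45
    apn_hidden: int = 32
    # Per-layer parameter multipliers (muP-style): the effective weight is
    # gain * stored weight, with the stored weight initialized at scale/gain.
    # Adam's per-parameter step is the learning rate, so the gain sets how
    # far each layer can move at a fixed protocol learning rate; these
    # defaults make the desk-scale stack trainable in tens of epochs at the
    # small full-scale learning rate without touching the optimizer.
    conv_gain: float = 8.0
    head_gain: float = 32.0
    apn_gain: float = 16.0

    def __post_init__(self):
        if len(self.channels) != 5:
            raise ValueError("exactly five stages (five pooling levels) required")
        if self.input_size % 32 != 0:
            raise ValueError("input_size must be divisible by 2^5")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must be in [0, 1)")

    @staticmethod
    def tiny(n_classes: int = 4, input_size: int = 64) -> "BackboneConfig":
        """Small desk-scale stack trainable in minutes on one CPU."""
        return BackboneConfig(channels=(8, 16, 16, 16, 16),
                              input_size=input_size, n_classes=n_classes)


@dataclass
class ScaleOutput:
    """Numpy view of one scale's outputs for a batch."""

    pool_probs: list[np.ndarray]          # five (N, C) simplex rows
    scale_prob: np.ndarray                # (N, C); == pool_probs[4]
    boxes: np.ndarray                     # (N, 3) tx, ty, tl
    true_class_conf: np.ndarray | None = None  # (N,) P_t(m), training only


@dataclass
class CascadeOutput:
    scales: list[ScaleOutput]
    fused_prob: np.ndarray                # (N, C) soft vote across scales
    scale_inputs: list[np.ndarray] = field(default_factory=list)  # (N,3,H,W) each


def soft_vote(prob_vectors: Sequence[np.ndarray], weights: Sequence[float]) -> np.ndarray:
    """Weighted arithmetic mean of class-probability vectors ("soft voting").

    weights must be nonnegative and sum to 1; the result stays on the
    simplex because it is a convex combination of simplex points.
    """
    if len(prob_vectors) != len(weights):
        raise ValueError("one weight per probability vector required")
    w = np.asarray(weights, dtype=np.float64)
    if w.min() < 0 or abs(w.sum() - 1.0) > 1e-9:
        raise ValueError("weights must be nonnegative and sum to 1")
    stacked = np.stack([np.asarray(p, dtype=np.float64) for p in prob_vectors])
    return np.tensordot(w, stacked, axes=(0, 0))


def _he_conv(rng, cout, cin):
    w = rng.normal(0.0, np.sqrt(2.0 / (cin * 9)), size=(cout, cin, 3, 3))
    return w.astype(np.float32)


class CascadeModel:
    """Parameters and forward pass of the three-scale cascade.

    Parameters live in ``self.params`` as name -> Tensor(requires_grad=True).
    The forward pass is fully deterministic in evaluation mode; training
    mode adds (seeded) dropout before each pooling head's affine map.
    """

    N_SCALES = 3

    def __init__(self, cfg: BackboneConfig, crop_cfg: CropConfig | None = None,
                 seed: int = 0, share_backbone: bool = False):
        self.cfg = cfg
        size = cfg.input_size
        self.crop_cfg = crop_cfg or CropConfig(
            out_size=size, min_half_len=size / 8.0, max_half_frac=0.45)
        self.share_backbone = share_backbone
        self.params: dict[str, Tensor] = {}
        rng = np.random.default_rng(seed)
        n_param_scales = 1 if share_backbone else self.N_SCALES
        for m in range(n_param_scales):
            self._init_scale(m, rng)

    # -- parameter initialization -------------------------------------------

    def _init_scale(self, m: int, rng):
        chans = (3,) + tuple(self.cfg.channels)
        cfg = self.cfg
        p = self.params
        for i in range(5):
            p[f"s{m}.conv{i}.w"] = Tensor(
                _he_conv(rng, chans[i + 1], chans[i]) / cfg.conv_gain,
                requires_grad=True)
            p[f"s{m}.conv{i}.b"] = Tensor(np.zeros(chans[i + 1], np.float32),
                                          requires_grad=True)
        for i in range(5):
            p[f"s{m}.head{i}.w"] = Tensor(
                rng.normal(0, 0.01 / cfg.head_gain,
                           size=(chans[i + 1], self.cfg.n_classes)
                           ).astype(np.float32), requires_grad=True)
            p[f"s{m}.head{i}.b"] = Tensor(np.zeros(self.cfg.n_classes, np.float32),
                                          requires_grad=True)
        # APN reads the flattened stage-4 map (spatial 4x4): box regression
        # needs spatial layout, which global pooling would discard
        apn_in = chans[4] * (self.cfg.input_size // 16) ** 2
        hid = self.cfg.apn_hidden
        p[f"s{m}.apn1.w"] = Tensor(rng.normal(0, np.sqrt(2.0 / apn_in),
                                              size=(apn_in, hid)).astype(np.float32),
                                   requires_grad=True)
        p[f"s{m}.apn1.b"] = Tensor(np.zeros(hid, np.float32), requires_grad=True)
        # zero-init final APN layer: raw outputs 0 -> centered, mid-range box
        p[f"s{m}.apn2.w"] = Tensor(np.zeros((hid, 3), np.float32), requires_grad=True)
        p[f"s{m}.apn2.b"] = Tensor(np.zeros(3, np.float32), requires_grad=True)

    def _key(self, m: int, name: str) -> str:
        mm = 0 if self.share_backbone else m
        return f"s{mm}.{name}"

    def trainable(self) -> dict[str, Tensor]:
        """Parameters updated by the optimizer: backbones, P5 heads, APNs.

        P1..P4 heads feed only the fusion stage and receive no loss
        gradient by default, so they are excluded (the auxiliary
        cross-entropy flag in training re-includes them).
        """
        out = {}
        for k, v in self.params.items():
            if ".head" in k and ".head4" not in k:
                continue
            out[k] = v
        return out

    # -- forward pieces ------------------------------------------------------

    def backbone_forward(self, x: Tensor, m: int) -> list[Tensor]:
        """Five conv-relu-pool stages; stage i output has spatial size
        input_size / 2^(i+1)."""
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected input spatial size {self.cfg.input_size}, "
                f"got {x.shape[2]}x{x.shape[3]}")
        feats = []
        for i in range(5):
            w = self.params[self._key(m, f"conv{i}.w")] * self.cfg.conv_gain
            b = self.params[self._key(m, f"conv{i}.b")] * self.cfg.conv_gain
            x = x.conv3x3(w, b).relu().maxpool2()
            feats.append(x)
        return feats

    def pool_head_predict(self, feat: Tensor, m: int, i: int,
                          train_mode: bool = False,
                          rng: np.random.Generator | None = None) -> Tensor:
        """Global average pool -> (dropout) -> affine -> softmax."""
        z = feat.global_avg_pool()
        if train_mode and self.cfg.dropout_rate > 0:
            z = z.dropout(self.cfg.dropout_rate, rng)
        w = self.params[self._key(m, f"head{i}.w")]
        b = self.params[self._key(m, f"head{i}.b")]
        return ((z @ w + b) * self.cfg.head_gain).softmax()

    def apn_predict(self, feat4: Tensor, m: int) -> tuple[Tensor, Tensor, Tensor]:
        """Regress a valid attention box from the stage-4 feature map.

        The map is flattened, not pooled: the regression needs the spatial
        layout of activations to place the box.  Raw outputs are squashed:
        center coordinates into [0, size-1] by a scaled sigmoid, half length
        into [min_half_len, max_half_frac*size]; the center is then clamped
        so the box lies inside the image.  Validity is guaranteed by
        construction for any parameter values.
        """
        size = self.cfg.input_size
        ccfg = self.crop_cfg
        w1 = self.params[self._key(m, "apn1.w")]
        b1 = self.params[self._key(m, "apn1.b")]
        w2 = self.params[self._key(m, "apn2.w")]
        b2 = self.params[self._key(m, "apn2.b")]
        z = feat4.reshape(feat4.shape[0], -1)
        raw = ((z @ w1 + b1).relu() @ w2 + b2) * self.cfg.apn_gain   # (N, 3)
        n = raw.shape[0]
        sx = raw.take_rows(np.zeros(n, int)).sigmoid()
        sy = raw.take_rows(np.ones(n, int)).sigmoid()
        sl = raw.take_rows(np.full(n, 2)).sigmoid()
        tx = sx * float(size - 1)
        ty = sy * float(size - 1)
        lo, hi = ccfg.min_half_len, ccfg.max_half_frac * size
        tl = sl * float(hi - lo) + float(lo)
        # clamp centers so the box stays inside [-0.5, size-0.5]; relu form
        # keeps (sub)gradients flowing to both the center and tl
        def _lower(c, lo):
            return lo + (c - lo).relu()

        def _upper(c, hi):
            return hi - (hi - c).relu()

        tx = _upper(_lower(tx, tl - 0.5), (tl * -1.0) + float(size - 0.5))
        ty = _upper(_lower(ty, tl - 0.5), (tl * -1.0) + float(size - 0.5))
        return tx, ty, tl

    # -- full cascade ---------------------------------------------------------

    def forward_tensors(self, images: np.ndarray, labels: np.ndarray | None = None,
                        train_mode: bool = False,
                        rng: np.random.Generator | None = None):
        """Run the cascade on a batch, keeping the tape.

        images: (N, 3, H, W) float32 in [0, 1].
        Returns (scale_probs, boxes, scale_inputs): lists of per-scale P5
        probability Tensors (N, C), per-scale (tx, ty, tl) Tensor triples,
        and per-scale input Tensors.
        """
        if train_mode and rng is None:
            raise ValueError("training mode needs an rng for dropout")
        x = Tensor(images)
        scale_probs, boxes, scale_inputs, all_feats = [], [], [], []
        for m in range(self.N_SCALES):
            scale_inputs.append(x)
            feats = self.backbone_forward(x, m)
            all_feats.append(feats)
            prob = self.pool_head_predict(feats[4], m, 4, train_mode, rng)
            scale_probs.append(prob)
            tx, ty, tl = self.apn_predict(feats[3], m)
            boxes.append((tx, ty, tl))
            if m < self.N_SCALES - 1:
                x = attention_crop_tensors(x, tx, ty, tl, self.crop_cfg)
        return scale_probs, boxes, scale_inputs, all_feats

    def cascade_forward(self, images: np.ndarray,
                        scale_weights: Sequence[float] | None = None,
                        batch_size: int = 64) -> CascadeOutput:
        """Evaluation-mode forward pass over a full array of images.

        Returns numpy-only CascadeOutput with all five pooling-level
        probabilities per scale, the per-scale boxes, and a soft-voted
        fused probability (uniform scale weights by default).
        """
        if scale_weights is None:
            scale_weights = [1.0 / self.N_SCALES] * self.N_SCALES
        n = images.shape[0]
        per_scale_pool = [[[] for _ in range(5)] for _ in range(self.N_SCALES)]
        per_scale_boxes = [[] for _ in range(self.N_SCALES)]
        inputs_acc = [[] for _ in range(self.N_SCALES)]
        for start in range(0, n, batch_size):
            batch = images[start:start + batch_size]
            _, boxes, scale_inputs, feats = self.forward_tensors(batch)
            for m in range(self.N_SCALES):
                for i in range(5):
                    p = self.pool_head_predict(feats[m][i], m, i)
                    per_scale_pool[m][i].append(p.data)
                tx, ty, tl = boxes[m]
                per_scale_boxes[m].append(
                    np.stack([tx.data, ty.data, tl.data], axis=1))
                inputs_acc[m].append(scale_inputs[m].data)
        scales = []
        for m in range(self.N_SCALES):
            pool = [np.concatenate(per_scale_pool[m][i]) for i in range(5)]
            scales.append(ScaleOutput(
                pool_probs=pool, scale_prob=pool[4],
                boxes=np.concatenate(per_scale_boxes[m])))
        fused = soft_vote([s.scale_prob for s in scales], scale_weights)
        return CascadeOutput(
            scales=scales, fused_prob=fused,
            scale_inputs=[np.concatenate(a) for a in inputs_acc])

    # -- parameter (de)serialization ------------------------------------------

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for k, v in state.items():
            self.params[k].data = np.asarray(v, dtype=np.float32).copy()

    def predicted_boxes(self, images: np.ndarray, scale: int = 0,
                        batch_size: int = 64) -> list[AttentionBox]:
        """Clamped attention boxes proposed at a given scale (default 1st)."""
        out = self.cascade_forward(images, batch_size=batch_size)
        size = self.cfg.input_size
        return [clamp_box(AttentionBox(tx, ty, tl), size,
                          min_half_len=self.crop_cfg.min_half_len,
                          max_half_frac=self.crop_cfg.max_half_frac)
                for tx, ty, tl in out.scales[scale].boxes]
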