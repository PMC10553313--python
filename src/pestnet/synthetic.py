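"""Synthetic pest-like image benchmark with a planted discriminative patch.

Real fine-grained pest photographs carry their class identity in a small
body region surrounded by leaves, soil and other clutter.  This module
emulates exactly that structure so the attention cascade can be exercised
and *measured* without any external download: each image is a cluttered
background plus a single localized patch whose texture (grating
orientation, spatial frequency and hue) is determined by the class label.
Clutter blobs reuse the class color palette but never the grating texture,
so color alone is uninformative and the discriminative signal is localized
to the recorded ground-truth box — which is what makes attention
localization quantifiable downstream.

Augmentations mirror common photographic jitter: right-angle rotation,
horizontal/vertical mirroring and brightness variation (free-angle rotation
is available but drops the ground-truth box).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .attention import AttentionBox

__all__ = [
    "SceneSpec",
    "LabeledImage",
    "class_palette",
    "generate_scene",
    "generate_dataset",
    "augment",
    "split_dataset",
]


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of the synthetic scene distribution.

    Defaults are the desk-scale configuration used throughout the test
    suite: 64 px images, 4 classes, patches of half side 6-10 px, ~6
    clutter blobs per image and mild additive Gaussian pixel noise.  A
    224 px, 10-class configuration is a one-liner via ``full_scale``.
    """

    image_size: int = 64
    n_classes: int = 4
    patch_half_len_range: tuple[int, int] = (6, 10)
    clutter_density: float = 6.0
    noise_sd: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        lo, hi = self.patch_half_len_range
        if not (0 < lo <= hi):
            raise ValueError("invalid patch_half_len_range")
        if hi >= self.image_size / 2:
            raise ValueError("patch does not fit inside the image")
        if self.clutter_density < 0 or self.noise_sd < 0:
            raise ValueError("clutter_density and noise_sd must be >= 0")

    @staticmethod
    def full_scale(seed: int = 0) -> "SceneSpec":
        """224 px, 10-class configuration mirroring the real-data regime."""
        return SceneSpec(image_size=224, n_classes=10,
                         patch_half_len_range=(18, 34), clutter_density=12.0,
                         noise_sd=0.02, seed=seed)


@dataclass
class LabeledImage:
    """One sample: (H, W, 3) float pixels in [0, 1], class label, optional
    ground-truth patch box, and a train/validation/test split tag."""

    pixels: np.ndarray
    label: int
    truth_box: AttentionBox | None = None
    split_tag: str = "train"
    uid: int = field(default=-1)


def class_palette(n_classes: int) -> list[dict]:
    """Per-class texture parameters: grating orientation, spatial frequency
    and an RGB hue direction.  Orientations are spread over [0, pi) and
    frequencies interleaved so neighboring classes differ in both."""
    palette = []
    for c in range(n_classes):
        theta = np.pi * c / n_classes
        freq = 0.16 + 0.14 * ((c * 2 + 1) % n_classes) / max(n_classes - 1, 1)
        hue_angle = 2 * np.pi * c / n_classes
        color = 0.5 + 0.45 * np.array(
            [np.cos(hue_angle), np.cos(hue_angle - 2 * np.pi / 3),
             np.cos(hue_angle + 2 * np.pi / 3)]
        )
        palette.append({"theta": theta, "freq": freq, "color": color})
    return palette


def _grating_patch(side: int, theta: float, freq: float, color: np.ndarray,
                   phase: float) -> np.ndarray:
    """Oriented sinusoidal grating colored along `color` vs its complement."""
    r = np.arange(side, dtype=np.float64)
    yy, xx = np.meshgrid(r, r, indexing="ij")
    carrier = np.sin(2 * np.pi * freq * (xx * np.cos(theta) + yy * np.sin(theta))
                     + phase)
    g = 0.5 + 0.5 * carrier
    return g[:, :, None] * color[None, None, :] + (1 - g)[:, :, None] * (1 - color)[None, None, :]


def _clutter_blob(img: np.ndarray, rng: np.random.Generator, palette: list[dict]):
    """One smooth elliptical blob; color drawn from the class palette (so
    color statistics match patches) but with no grating texture."""
    h, w = img.shape[:2]
    cy, cx = rng.uniform(0, h), rng.uniform(0, w)
    ay, ax = rng.uniform(3, 10, size=2)
    angle = rng.uniform(0, np.pi)
    color = palette[rng.integers(len(palette))]["color"]
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    dy, dx = yy - cy, xx - cx
    ry = dy * np.cos(angle) + dx * np.sin(angle)
    rx = -dy * np.sin(angle) + dx * np.cos(angle)
    d2 = (ry / ay) ** 2 + (rx / ax) ** 2
    alpha = np.exp(-0.5 * d2 * 4.0)  # smooth radial falloff
    img += alpha[:, :, None] * (color[None, None, :] - img)


def generate_scene(spec: SceneSpec, class_id: int,
                   rng: np.random.Generator) -> LabeledImage:
    """Draw one image of class `class_id`: cluttered background plus exactly
    one class-discriminative grating patch at a uniform-random location.

    Deterministic given (spec, class_id, rng state); pixels clipped to [0, 1];
    the planted patch is recorded in ``truth_box``.
    """
    if not 0 <= class_id < spec.n_classes:
        raise ValueError(f"class_id {class_id} out of range [0, {spec.n_classes})")
    s = spec.image_size
    palette = class_palette(spec.n_classes)
    img = np.full((s, s, 3), 0.5, dtype=np.float64)

    n_blobs = rng.poisson(spec.clutter_density)
    for _ in range(n_blobs):
        _clutter_blob(img, rng, palette)

    lo, hi = spec.patch_half_len_range
    half = int(rng.integers(lo, hi + 1))
    cx = int(rng.integers(half, s - half))
    cy = int(rng.integers(half, s - half))
    side = 2 * half + 1
    p = palette[class_id]
    # fixed phase: the patch is a rigid class template, so its signal is
    # first-order in pixel space (a linear probe on crops can read it)
    patch = _grating_patch(side, p["theta"], p["freq"], p["color"], phase=0.0)
    img[cy - half: cy + half + 1, cx - half: cx + half + 1] = patch

    if spec.noise_sd > 0:
        img += rng.normal(0, spec.noise_sd, size=img.shape)
    np.clip(img, 0.0, 1.0, out=img)
    return LabeledImage(pixels=img.astype(np.float32), label=class_id,
                        truth_box=AttentionBox(float(cx), float(cy), float(half)))


def generate_dataset(spec: SceneSpec, per_class: dict[str, int] | int,
                     seed: int | None = None) -> list[LabeledImage]:
    """Generate a labeled, split-tagged dataset.

    per_class: either a total per-class count (then split 6:3:1 by
    :func:`split_dataset`) or a dict like {"train": 200, "validation": 100,
    "test": 35} of per-class counts per split.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    samples: list[LabeledImage] = []
    uid = 0
    if isinstance(per_class, int):
        for c in range(spec.n_classes):
            for _ in range(per_class):
                im = generate_scene(spec, c, rng)
                im.uid = uid
                uid += 1
                samples.append(im)
        tr, va, te = split_dataset(samples, seed=(spec.seed if seed is None else seed))
        return tr + va + te
    for split, n in per_class.items():
        for c in range(spec.n_classes):
            for _ in range(n):
                im = generate_scene(spec, c, rng)
                im.split_tag = split
                im.uid = uid
                uid += 1
                samples.append(im)
    return samples


_RIGHT_ANGLES = (90, 180, 270)


def _rot90_box(box: AttentionBox, size: int, k: int) -> AttentionBox:
    """Track the patch box through k CCW quarter-turns (np.rot90 convention)."""
    cx, cy = box.tx, box.ty
    for _ in range(k % 4):
        cx, cy = cy, size - 1 - cx
    return AttentionBox(cx, cy, box.tl)


def augment(image: LabeledImage, ops: Iterable[str], rng: np.random.Generator,
            *, brightness_range: tuple[float, float] = (0.7, 1.3),
            free_rotation: bool = False) -> LabeledImage:
    """Apply requested augmentations with randomly drawn parameters.

    ops is a subset of {"rotate", "mirror_h", "mirror_v", "brightness"}.
    The label never changes; the truth box is transformed exactly for
    mirrors and right-angle rotations and dropped for free-angle rotation.
    An empty ops set is the identity.
    """
    ops = set(ops)
    unknown = ops - {"rotate", "mirror_h", "mirror_v", "brightness"}
    if unknown:
        raise ValueError(f"unknown augmentation ops: {sorted(unknown)}")
    px = image.pixels.copy()
    box = image.truth_box
    size = px.shape[0]

    if "rotate" in ops:
        if free_rotation:
            from scipy.ndimage import rotate as nd_rotate

            angle = float(rng.uniform(0, 360))
            px = nd_rotate(px, angle, axes=(1, 0), reshape=False, order=1,
                           mode="nearest")
            box = None
        else:
            k = int(rng.choice((1, 2, 3)))
            px = np.rot90(px, k, axes=(0, 1)).copy()
            if box is not None:
                box = _rot90_box(box, size, k)
    if "mirror_h" in ops:  # flip left-right: x -> W-1-x
        px = px[:, ::-1].copy()
        if box is not None:
            box = AttentionBox(size - 1 - box.tx, box.ty, box.tl)
    if "mirror_v" in ops:  # flip up-down: y -> H-1-y
        px = px[::-1].copy()
        if box is not None:
            box = AttentionBox(box.tx, size - 1 - box.ty, box.tl)
    if "brightness" in ops:
        factor = float(rng.uniform(*brightness_range))
        px = np.clip(px * factor, 0.0, 1.0).astype(np.float32)

    return LabeledImage(pixels=px, label=image.label, truth_box=box,
                        split_tag=image.split_tag, uid=image.uid)


def split_dataset(samples: Sequence[LabeledImage], seed: int
                  ) -> tuple[list[LabeledImage], list[LabeledImage], list[LabeledImage]]:
    """Stratified 6:3:1 train/validation/test partition.

    Per class, base counts are floor(0.6 n), floor(0.3 n), floor(0.1 n); the
    rounding remainder is assigned train -> validation -> test in that
    order.  Deterministic given `seed`; partitions are disjoint and their
    union is the input.
    """
    if len(samples) < 10:
        raise ValueError("need at least 10 samples to split 6:3:1")
    rng = np.random.default_rng(seed)
    labels = sorted({im.label for im in samples})
    out: dict[str, list[LabeledImage]] = {"train": [], "validation": [], "test": []}
    for c in labels:
        group = [im for im in samples if im.label == c]
        if len(group) < 3:
            warnings.warn(f"class {c} has fewer than 3 samples; "
                          "best-effort split", stacklevel=2)
        order = rng.permutation(len(group))
        n = len(group)
        counts = [int(n * 0.6), int(n * 0.3), int(n * 0.1)]
        rem = n - sum(counts)
        for i in range(rem):
            counts[i % 3] += 1
        tags = ["train", "validation", "test"]
        start = 0
        for tag, cnt in zip(tags, counts):
            for idx in order[start:start + cnt]:
                im = group[idx]
                im.split_tag = tag
                out[tag].append(im)
            start += cnt
    return out["train"], out["validation"], out["test"]
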