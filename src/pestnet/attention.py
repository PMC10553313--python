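"""Square attention boxes and the differentiable crop-and-zoom primitive.

An attention region is a square parameterized by its center ``(tx, ty)`` and
half side length ``tl`` in pixel coordinates (origin at the upper-left pixel
center, x rightward, y downward).  Cropping is made differentiable in the
box parameters by multiplying the image with a smooth separable "boxcar"
mask — a product of logistic step approximations along each axis — and then
bilinearly resampling the box interior to a fixed output size.  The gradient
of the mask with respect to the box center is negative just inside the left
edge and positive just inside the right edge, which is the signal that lets
a trained attention head slide and shrink its box toward the discriminative
region.

NumPy reference implementations live here; :mod:`pestnet.autodiff` hosts the
tape-aware twin used inside the model (same arithmetic, same conventions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .autodiff import Tensor

__all__ = [
    "AttentionBox",
    "CropConfig",
    "box_corners",
    "clamp_box",
    "attention_mask",
    "crop_and_zoom",
    "mask_gradient_signs",
    "box_iou",
    "bilinear_sample",
    "attention_crop_tensors",
]


@dataclass(frozen=True)
class AttentionBox:
    """Square attention region: center (tx, ty), half side length tl (pixels)."""

    tx: float
    ty: float
    tl: float

    def __post_init__(self):
        if self.tl <= 0:
            raise ValueError(f"half side length must be positive, got {self.tl}")


@dataclass(frozen=True)
class CropConfig:
    """Settings of the smooth crop operator.

    steepness
        Slope ``k`` of the logistic step approximation; the mask tends to
        the hard 0/1 box indicator as ``k`` grows.
    out_size
        Side length of the resampled output, in pixels.
    min_half_len / max_half_frac
        Bounds imposed on ``tl`` when a raw attention-head output is
        squashed into a valid box (degenerate and out-of-frame crops are
        excluded by construction).
    """

    steepness: float = 10.0
    out_size: int = 64
    min_half_len: float = 8.0
    max_half_frac: float = 0.45

    def __post_init__(self):
        if not (self.steepness > 0 and np.isfinite(self.steepness)):
            raise ValueError("steepness must be finite and positive")
        if self.out_size < 8:
            raise ValueError("out_size must be >= 8")


def box_corners(box: AttentionBox):
    """Upper-left and lower-right corners: (tx-tl, ty-tl, tx+tl, ty+tl)."""
    return (box.tx - box.tl, box.ty - box.tl, box.tx + box.tl, box.ty + box.tl)


def clamp_box(box: AttentionBox, image_size: int, min_half_len: float | None = None,
              max_half_frac: float = 0.45) -> AttentionBox:
    """Clamp a box so it lies fully inside the image extent.

    The image extent in continuous coordinates is [-0.5, size-0.5] on each
    axis (pixel centers at 0 .. size-1).  Idempotent on already-valid boxes.
    """
    lo = min_half_len if min_half_len is not None else min(box.tl, image_size * max_half_frac)
    tl = float(np.clip(box.tl, lo, image_size * max_half_frac))
    tx = float(np.clip(box.tx, tl - 0.5, image_size - 0.5 - tl))
    ty = float(np.clip(box.ty, tl - 0.5, image_size - 0.5 - tl))
    return AttentionBox(tx, ty, tl)


def _soft_step(u: np.ndarray, k: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(k * u, -500, 500)))


def attention_mask(box: AttentionBox, grid_shape: tuple[int, int],
                   steepness: float = 10.0) -> np.ndarray:
    """Smooth separable box indicator on an H x W pixel grid.

    M(x, y) = [s(x - tx_tl) - s(x - tx_br)] * [s(y - ty_tl) - s(y - ty_br)]
    with s the logistic step of slope `steepness`; values in (0, 1),
    approaching the hard indicator of the box as steepness grows.
    """
    h, w = grid_shape
    x_tl, y_tl, x_br, y_br = box_corners(box)
    xs = np.arange(w, dtype=np.float64)
    ys = np.arange(h, dtype=np.float64)
    mx = _soft_step(xs - x_tl, steepness) - _soft_step(xs - x_br, steepness)
    my = _soft_step(ys - y_tl, steepness) - _soft_step(ys - y_br, steepness)
    return my[:, None] * mx[None, :]


def _sample_coords(center: float, half: float, out_size: int) -> np.ndarray:
    """Continuous input coordinates of the out_size output pixel centers.

    Output pixel j samples the box at its (j + 0.5)/out_size fractional
    position (the standard half-pixel-center resize convention), clamped
    half a pixel inside the box so border taps never reach masked-out
    content (the analogue of edge extension in a plain resize).
    """
    j = np.arange(out_size, dtype=np.float64)
    alpha = 2.0 * (j + 0.5) / out_size - 1.0  # in (-1, 1)
    coords = center + half * alpha
    return np.clip(coords, center - half + 0.5, center + half - 0.5)


def _bilinear_gather(img: np.ndarray, v: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Sample a (C, H, W) image at float coords v (rows) x u (cols) -> (C, len(v), len(u))."""
    c, h, w = img.shape
    y0 = np.floor(v).astype(np.int64)
    x0 = np.floor(u).astype(np.int64)
    wy = (v - y0)[None, :, None]
    wx = (u - x0)[None, None, :]
    ya, yb = np.clip(y0, 0, h - 1), np.clip(y0 + 1, 0, h - 1)
    xa, xb = np.clip(x0, 0, w - 1), np.clip(x0 + 1, 0, w - 1)
    iaa = img[:, ya[:, None], xa[None, :]]
    iab = img[:, ya[:, None], xb[None, :]]
    iba = img[:, yb[:, None], xa[None, :]]
    ibb = img[:, yb[:, None], xb[None, :]]
    top = iaa * (1 - wx) + iab * wx
    bot = iba * (1 - wx) + ibb * wx
    return top * (1 - wy) + bot * wy


def crop_and_zoom(image: np.ndarray, box: AttentionBox, cfg: CropConfig) -> np.ndarray:
    """Mask the image with the smooth box indicator, extract the box, and
    bilinearly resample it to cfg.out_size x cfg.out_size.

    Accepts (H, W) or (H, W, C) arrays; returns the same channel layout.
    """
    if np.isnan(image).any():
        raise ValueError("input image contains NaN pixels")
    squeeze = image.ndim == 2
    img = image[..., None] if squeeze else image
    h, w = img.shape[:2]
    m = attention_mask(box, (h, w), cfg.steepness)
    masked = (img.astype(np.float64) * m[:, :, None]).transpose(2, 0, 1)  # C,H,W
    u = _sample_coords(float(box.tx), float(box.tl), cfg.out_size)
    v = _sample_coords(float(box.ty), float(box.tl), cfg.out_size)
    out = _bilinear_gather(masked, v, u).transpose(1, 2, 0)
    return out[:, :, 0] if squeeze else out


def mask_gradient_signs(box: AttentionBox, probe_xs: Sequence[float],
                        steepness: float = 10.0, *, grid_shape=(64, 64),
                        eps: float = 1e-8, step: float = 1e-3) -> list[str]:
    """Classify the sign of dM/d(tx) at probe x locations (y fixed at the
    box center row): 'neg' just inside the left edge, 'pos' just inside the
    right edge, 'zero' deep inside or outside."""
    y = box.ty
    x_tl, _, x_br, _ = box_corners(box)
    signs = []
    for x in probe_xs:
        def m_of_tx(tx):
            b = AttentionBox(tx, box.ty, box.tl)
            bx_tl, by_tl, bx_br, by_br = box_corners(b)
            mx = _soft_step(np.float64(x) - bx_tl, steepness) - _soft_step(np.float64(x) - bx_br, steepness)
            my = _soft_step(np.float64(y) - by_tl, steepness) - _soft_step(np.float64(y) - by_br, steepness)
            return mx * my

        d = (m_of_tx(box.tx + step) - m_of_tx(box.tx - step)) / (2 * step)
        if d < -eps:
            signs.append("neg")
        elif d > eps:
            signs.append("pos")
        else:
            signs.append("zero")
    return signs


def box_iou(a: AttentionBox, b: AttentionBox) -> float:
    """Intersection-over-union of two axis-aligned square boxes."""
    ax0, ay0, ax1, ay1 = box_corners(a)
    bx0, by0, bx1, by1 = box_corners(b)
    ix = max(0.0, min(ax1, bx1) - max(ax0, bx0))
    iy = max(0.0, min(ay1, by1) - max(ay0, by0))
    inter = ix * iy
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return inter / union if union > 0 else 0.0


# ---------------------------------------------------------------------------
# Tape-aware twin used inside the cascade model
# ---------------------------------------------------------------------------

def bilinear_sample(img: Tensor, v: Tensor, u: Tensor) -> Tensor:
    """Differentiable bilinear sampling.

    img: (N, C, H, W); v, u: (N, S) float row/column coordinates.
    Returns (N, C, S, S).  Gradients flow to the image and to both
    coordinate tensors (out-of-range taps clamp to the border, where the
    coordinate gradient vanishes naturally).
    """
    x = img.data
    n, c, h, w = x.shape
    s = u.data.shape[1]
    y0 = np.floor(v.data).astype(np.int64)
    x0 = np.floor(u.data).astype(np.int64)
    wy = (v.data - y0)[:, None, :, None].astype(np.float32)
    wx = (u.data - x0)[:, None, None, :].astype(np.float32)
    ya, yb = np.clip(y0, 0, h - 1), np.clip(y0 + 1, 0, h - 1)
    xa, xb = np.clip(x0, 0, w - 1), np.clip(x0 + 1, 0, w - 1)
    ni = np.arange(n)[:, None, None, None]
    ci = np.arange(c)[None, :, None, None]
    yA = ya[:, None, :, None]
    yB = yb[:, None, :, None]
    xA = xa[:, None, None, :]
    xB = xb[:, None, None, :]
    iaa = x[ni, ci, yA, xA]
    iab = x[ni, ci, yA, xB]
    iba = x[ni, ci, yB, xA]
    ibb = x[ni, ci, yB, xB]
    out_data = ((iaa * (1 - wx) + iab * wx) * (1 - wy)
                + (iba * (1 - wx) + ibb * wx) * wy)

    def bwd(g):
        g = g.astype(np.float32)
        if img.requires_grad:
            waa = (1 - wy) * (1 - wx)
            wab = (1 - wy) * wx
            wba = wy * (1 - wx)
            wbb = wy * wx
            size = n * c * h * w
            base = (ni * c + ci) * h  # (N, C, 1, 1)
            acc = np.zeros(size, dtype=np.float64)
            for yi, xi, wt in ((yA, xA, waa), (yA, xB, wab),
                               (yB, xA, wba), (yB, xB, wbb)):
                flat = ((base + yi) * w + xi + np.zeros((1, 1, s, s), np.int64)).ravel()
                acc += np.bincount(flat, weights=(g * wt).ravel(), minlength=size)
            img._accum(acc.reshape(n, c, h, w).astype(np.float32))
        if u.requires_grad or v.requires_grad:
            du = ((1 - wy) * (iab - iaa) + wy * (ibb - iba)) * g
            dv = ((1 - wx) * (iba - iaa) + wx * (ibb - iab)) * g
            u._accum(du.sum(axis=(1, 2)))
            v._accum(dv.sum(axis=(1, 3)))

    return Tensor._make(out_data, (img, u, v), bwd)


def attention_crop_tensors(img: Tensor, tx: Tensor, ty: Tensor, tl: Tensor,
                           cfg: CropConfig) -> Tensor:
    """Differentiable crop-and-zoom of a batch under per-sample boxes.

    img: (N, C, H, W); tx, ty, tl: (N,).  Multiplies the image by the smooth
    separable box mask (so box-edge gradients exist), then bilinearly
    resamples the box to cfg.out_size.  Same arithmetic as the NumPy
    reference :func:`crop_and_zoom`.
    """
    n, c, h, w = img.shape
    k = cfg.steepness
    s = cfg.out_size
    xs = Tensor(np.arange(w, dtype=np.float32)[None, :])
    ys = Tensor(np.arange(h, dtype=np.float32)[None, :])
    x_tl = (tx - tl).reshape(n, 1)
    x_br = (tx + tl).reshape(n, 1)
    y_tl = (ty - tl).reshape(n, 1)
    y_br = (ty + tl).reshape(n, 1)
    mx = ((xs - x_tl) * k).sigmoid() - ((xs - x_br) * k).sigmoid()   # (N, W)
    my = ((ys - y_tl) * k).sigmoid() - ((ys - y_br) * k).sigmoid()   # (N, H)
    masked = img * my.reshape(n, 1, h, 1) * mx.reshape(n, 1, 1, w)
    j = np.arange(s, dtype=np.float32)
    alpha = Tensor((2.0 * (j + 0.5) / s - 1.0)[None, :])             # (1, S)
    u = tx.reshape(n, 1) + tl.reshape(n, 1) * alpha                  # (N, S)
    v = ty.reshape(n, 1) + tl.reshape(n, 1) * alpha

    def _clamp_inside(c, lo, hi):
        # max(c, lo) then min(., hi), via relu so gradients flow to the box
        c = lo + (c - lo).relu()
        return hi - (hi - c).relu()

    u = _clamp_inside(u, (x_tl + 0.5), (x_br - 0.5))
    v = _clamp_inside(v, (y_tl + 0.5), (y_br - 0.5))
    return bilinear_sample(masked, v, u)
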