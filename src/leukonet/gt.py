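"""Geometric-transformation (GT) augmentation: rotations and flips.

Only label-preserving rigid transforms are offered — random rotation over the
full circle plus horizontal and vertical mirroring. Photometric operations
(zoom, shear, brightness) are deliberately absent: they can alter the
morphological properties that define a WBC class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .dataset import ImageSample

HORIZONTAL = "horizontal"
VERTICAL = "vertical"


@dataclass(frozen=True)
class GTPlan:
    """How many random rotations to draw and whether to add the two flips."""

    rounds: int = 15
    angle_domain: tuple[float, float] = (0.0, 360.0)
    include_flips: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        lo, hi = self.angle_domain
        if not (0.0 <= lo < hi <= 360.0):
            raise ValueError("angle_domain must lie within [0, 360)")


def _corner_background(px: np.ndarray) -> np.ndarray:
    """Per-channel median of the four corner pixels, used as border fill."""
    corners = px[[0, 0, -1, -1], [0, -1, 0, -1], :]
    return np.median(corners, axis=0)


def rotate(img: ImageSample, angle: float) -> ImageSample:
    """Rotate counter-clockwise about the image centre, preserving shape.

    Exact multiples of 90 degrees use a lossless index permutation; other
    angles use bilinear interpolation with the border filled by the median
    corner (background) color. The label is preserved.
    """
    angle = float(angle) % 360.0
    px = img.pixels
    if angle % 90.0 == 0.0:
        k = int(angle // 90) % 4
        out = np.rot90(px, k=k, axes=(0, 1)).copy()
    else:
        bg = _corner_background(px)
        out = np.empty_like(px)
        for c in range(3):
            out[..., c] = ndimage.rotate(
                px[..., c], angle, reshape=False, order=1,
                mode="constant", cval=float(bg[c]),
            )
        out = np.clip(out, 0.0, 1.0)
    return ImageSample(out, label=img.label, source_id=img.source_id)


def flip(img: ImageSample, axis: str) -> ImageSample:
    """Mirror the image horizontally (left-right) or vertically (up-down)."""
    if axis == HORIZONTAL:
        out = img.pixels[:, ::-1, :].copy()
    elif axis == VERTICAL:
        out = img.pixels[::-1, :, :].copy()
    else:
        raise ValueError(f"unknown flip axis {axis!r}; use 'horizontal' or 'vertical'")
    return ImageSample(out, label=img.label, source_id=img.source_id)


def gt_augment(
    img: ImageSample,
    plan: GTPlan,
    rng: np.random.Generator | None = None,
) -> list[ImageSample]:
    """Produce the GT-augmented family of one image.

    One rotation per round at an angle drawn uniformly from the plan's
    domain, plus (once, de-duplicated) a horizontal and a vertical flip of
    the original when ``include_flips`` is set. Output count is
    ``rounds + 2`` with flips, ``rounds`` without; every output carries the
    input's label.
    """
    rng = rng if rng is not None else np.random.default_rng(plan.seed)
    lo, hi = plan.angle_domain
    out = []
    for _ in range(plan.rounds):
        out.append(rotate(img, rng.uniform(lo, hi)))
    if plan.include_flips:
        out.append(flip(img, HORIZONTAL))
        out.append(flip(img, VERTICAL))
    return out
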