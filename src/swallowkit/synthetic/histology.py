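"""Synthetic H&E-like lung section images with known inflamed-pixel fraction.

Real sections show pink eosin-stained tissue with darker red/purple pools of
erythrocytes where there is hemorrhagic inflammation, on a near-white slide
background. The generator paints a tissue ellipse on a background field and
places hard-edged circular "pools" inside it until a target fraction of the
*total image* pixels carries the pool color, then reports the exactly counted
painted fraction as ground truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._rng import make_rng
from .truth import SyntheticTruth


def _luminance(rgb) -> float:
    r, g, b = rgb
    return 0.299 * r + 0.587 * g + 0.114 * b


@dataclass
class HistologyImageSpec:
    """Parameters of one synthetic lung-section image.

    ``pool_area_fraction`` is the target fraction of *all* image pixels
    (the pipeline's denominator is the total pixel count of the original
    image) painted with ``pool_color``. The pool color must be darker than
    the tissue color, as erythrocyte pools are on an H&E section.
    """

    width_px: int = 160
    height_px: int = 120
    pool_area_fraction: float = 0.05
    pool_count: int = 6
    tissue_color: tuple[int, int, int] = (230, 150, 180)
    pool_color: tuple[int, int, int] = (110, 20, 60)
    background_color: tuple[int, int, int] = (245, 245, 245)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_px < 16 or self.height_px < 16:
            raise ValueError("image too small")
        if not 0.0 <= self.pool_area_fraction <= 0.5:
            raise ValueError("pool_area_fraction must be in [0, 0.5]")
        if self.pool_count < 1:
            raise ValueError("pool_count must be >= 1")
        if _luminance(self.pool_color) >= _luminance(self.tissue_color):
            raise ValueError("pool_color must be darker than tissue_color")


def _trim_to_count(
    pool_mask: np.ndarray,
    tissue: np.ndarray,
    target_px: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Grow or shrink the pool mask at its boundary to an exact pixel count.

    Whole disks cannot hit small targets exactly; adjusting single boundary
    pixels keeps the pools compact while making the painted fraction exact
    to the pixel.
    """
    from scipy.ndimage import binary_dilation, binary_erosion

    mask = pool_mask.copy()
    for _ in range(64):  # each pass moves the count by a full boundary ring
        diff = int(mask.sum()) - target_px
        if diff == 0:
            break
        if diff < 0:
            ring = binary_dilation(mask) & ~mask & tissue
            if not ring.any():  # no pool yet: seed one pixel inside tissue
                ys, xs = np.nonzero(tissue)
                k = int(rng.integers(0, len(ys)))
                mask[ys[k], xs[k]] = True
                continue
            idx = np.flatnonzero(ring.ravel())
            take = idx[: min(-diff, idx.size)]
            mask.ravel()[take] = True
        else:
            ring = mask & ~binary_erosion(mask)
            idx = np.flatnonzero(ring.ravel())
            take = idx[: min(diff, idx.size)]
            mask.ravel()[take] = False
    return mask


def gen_histology_image(
    spec: HistologyImageSpec,
) -> tuple[np.ndarray, SyntheticTruth]:
    """Generate an RGB uint8 image plus exact pixel-level ground truth.

    Truth carries ``true_inflamed_fraction`` (painted pool pixels / total
    pixels, within 10% relative of the requested fraction) and boolean masks
    ``pool`` and ``background``.
    """
    h, w = spec.height_px, spec.width_px
    total = h * w
    rng = make_rng(spec.seed)

    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    a, b = 0.45 * w, 0.45 * h  # tissue ellipse semi-axes
    tissue = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0
    background = ~tissue

    img = np.empty((h, w, 3), dtype=np.uint8)
    img[:] = spec.background_color
    img[tissue] = spec.tissue_color

    target = spec.pool_area_fraction * total
    pool_mask = np.zeros((h, w), dtype=bool)
    if target > 0:
        if target > 0.8 * tissue.sum():
            raise ValueError("pool_area_fraction infeasible: pools cannot fit in tissue")
        painted = 0
        pools_left = spec.pool_count
        attempts = 0
        max_attempts = 400 * spec.pool_count
        while painted < target * 0.95 and attempts < max_attempts:
            attempts += 1
            remaining = target - painted
            n_div = max(pools_left, 1)
            r = math.sqrt((remaining / n_div) / math.pi)
            r = max(r, 1.0)
            # center constrained so the whole disk stays inside the tissue
            px = rng.uniform(cx - a + r + 1, cx + a - r - 1)
            py = rng.uniform(cy - b + r + 1, cy + b - r - 1)
            if ((px - cx) / (a - r)) ** 2 + ((py - cy) / (b - r)) ** 2 > 1.0:
                continue
            disk = (xx - px) ** 2 + (yy - py) ** 2 <= r * r
            if np.any(disk & pool_mask):
                continue  # reject overlapping pools
            pool_mask |= disk
            painted = int(pool_mask.sum())
            pools_left = max(pools_left - 1, 1)
        pool_mask = _trim_to_count(pool_mask, tissue, int(round(target)), rng)
        frac = pool_mask.sum() / total
        if abs(frac - spec.pool_area_fraction) > 0.10 * spec.pool_area_fraction:
            raise ValueError(
                "could not place pools within 10% of the requested fraction "
                f"(got {frac:.4f}, wanted {spec.pool_area_fraction:.4f})"
            )
        img[pool_mask] = spec.pool_color

    truth = SyntheticTruth(
        true_parameters={
            "width_px": w,
            "height_px": h,
            "pool_area_fraction": spec.pool_area_fraction,
            "pool_count": spec.pool_count,
            "tissue_color": spec.tissue_color,
            "pool_color": spec.pool_color,
            "background_color": spec.background_color,
            "seed": spec.seed,
        },
        masks={"pool": pool_mask, "background": background},
        true_inflamed_fraction=float(pool_mask.sum()) / total,
    )
    return img, truth
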