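"""Seeded region growing and mask application for nodule ROIs.

A delineated ROI still contains background (muscle, vessel, bone remnants,
air).  Region growing from a seed inside the nodule keeps the maximal
connected set of pixels whose intensity stays close to the running region
mean; everything else is zeroed so that downstream texture statistics see
only nodule tissue.

The growing criterion is deliberately simple and fully deterministic:
4-connected breadth-first expansion (FIFO frontier, neighbours pushed in
row-major order), accepting a pixel when ``|intensity - running_mean| <= tol``
where the mean is updated after every accepted pixel.  8-connectivity is
available via ``connectivity=8``.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, replace
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "RoiImage",
    "DegenerateRoiError",
    "region_grow",
    "apply_mask",
    "centroid_seed",
]


class DegenerateRoiError(ValueError):
    """Raised when an ROI has no foreground pixels left."""


@dataclass
class RoiImage:
    """One segmented nodule region.

    Attributes
    ----------
    pixels : 2-D float array of intensities (arbitrary CT-like units).
    mask : 2-D {0,1} array, same shape; 1 marks nodule tissue.
    patient_id, scan_index, roi_id : provenance identifiers.
    """

    pixels: np.ndarray
    mask: np.ndarray
    patient_id: str = ""
    scan_index: int = 0
    roi_id: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        self.mask = np.asarray(self.mask)
        if self.pixels.ndim != 2:
            raise ValueError("pixels must be a 2-D grid")
        if self.pixels.shape != self.mask.shape:
            raise ValueError(
                f"pixels shape {self.pixels.shape} != mask shape {self.mask.shape}"
            )
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must contain only 0 and 1")
        self.mask = self.mask.astype(np.uint8)

    @property
    def shape(self) -> Tuple[int, int]:
        return self.pixels.shape


def centroid_seed(mask: np.ndarray) -> Tuple[int, int]:
    """Default seed point: the centroid of the foreground (or full grid)."""
    mask = np.asarray(mask)
    rows, cols = np.nonzero(mask) if mask.any() else np.indices(mask.shape).reshape(2, -1)
    return int(round(rows.mean())), int(round(cols.mean()))


_OFFSETS_4 = ((-1, 0), (0, -1), (0, 1), (1, 0))
_OFFSETS_8 = ((-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1))


def region_grow(
    pixels: np.ndarray,
    seed_point: Optional[Tuple[int, int]] = None,
    tol: float = 0.0,
    connectivity: int = 4,
) -> np.ndarray:
    """Grow a region from ``seed_point`` under a running-mean criterion.

    Parameters
    ----------
    pixels : 2-D intensity grid.
    seed_point : (row, col); defaults to the grid centroid.
    tol : non-negative intensity tolerance. A frontier pixel joins the
        region when its intensity differs from the current region mean by
        at most ``tol``.
    connectivity : 4 (default) or 8.

    Returns
    -------
    mask : uint8 {0,1} grid containing the seed, connected by construction.
    """
    pixels = np.asarray(pixels, dtype=float)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError("pixels must be a non-empty 2-D grid")
    if tol < 0:
        raise ValueError("tol must be >= 0")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if seed_point is None:
        seed_point = centroid_seed(np.ones_like(pixels, dtype=np.uint8))
    r0, c0 = int(seed_point[0]), int(seed_point[1])
    nr, nc = pixels.shape
    if not (0 <= r0 < nr and 0 <= c0 < nc):
        raise ValueError(f"seed point {seed_point} outside grid of shape {pixels.shape}")

    offsets = _OFFSETS_4 if connectivity == 4 else _OFFSETS_8
    mask = np.zeros_like(pixels, dtype=np.uint8)
    mask[r0, c0] = 1
    total = pixels[r0, c0]
    count = 1
    frontier = deque([(r0, c0)])
    while frontier:
        r, c = frontier.popleft()
        for dr, dc in offsets:
            rr, cc = r + dr, c + dc
            if 0 <= rr < nr and 0 <= cc < nc and not mask[rr, cc]:
                if abs(pixels[rr, cc] - total / count) <= tol:
                    mask[rr, cc] = 1
                    total += pixels[rr, cc]
                    count += 1
                    frontier.append((rr, cc))
    return mask


def apply_mask(image: RoiImage) -> RoiImage:
    """Zero every background pixel; foreground is untouched. Idempotent."""
    if not image.mask.any():
        raise DegenerateRoiError(
            f"ROI {image.roi_id or '<unnamed>'} has an all-zero mask"
        )
    return replace(image, pixels=image.pixels * image.mask, mask=image.mask.copy())
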