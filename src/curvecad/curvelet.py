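"""Three-scale curvelet-style tight-frame decomposition (34 sub-bands).

The frequency plane of a zero-padded square image is partitioned into

* one low-pass **coarse** band,
* ``n_detail_wedges`` (default 32) oriented **detail** wedges at the middle
  scale, and
* one high-pass **fine** band,

using smooth windows whose *squares* sum to one everywhere (a Parseval
tight frame).  Each sub-band is the inverse FFT of the windowed spectrum.
Because every window is symmetric under frequency negation (wedges are
built on the angle mod pi, so a wedge covers both of its antipodal
half-wedges) the coefficients of a real image are real.

Tight-frame consequences, used heavily by the tests:

* energy conservation: sum of squared coefficients equals the image energy;
* exact reconstruction: the adjoint (re-window and sum) inverts the
  forward transform to machine precision.

Sub-band order is fixed and documented: coarse, then the detail wedges
counter-clockwise starting at angle 0, then fine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import List, Tuple

import numpy as np

__all__ = [
    "CurveletConfig",
    "Subband",
    "CurveletDecomposition",
    "subband_count",
    "fdct_forward",
    "fdct_inverse",
    "dump_decomposition",
]

MIN_IMAGE_SIDE = 32  # smaller grids cannot support three radial scales


@dataclass(frozen=True)
class CurveletConfig:
    """Geometry of the decomposition.

    n_scales : number of radial scales; fixed at 3 (coarse/detail/fine).
    n_detail_wedges : angular wedges at the detail scale (>= 2).
    pad_to : square side after zero-padding; power of two, >= image side.
    """

    n_scales: int = 3
    n_detail_wedges: int = 32
    pad_to: int = 64

    def __post_init__(self) -> None:
        if self.n_scales != 3:
            raise ValueError("only the 3-scale coarse/detail/fine geometry is supported")
        if self.n_detail_wedges < 2:
            raise ValueError("n_detail_wedges must be >= 2 (a detail layer must exist)")
        if self.pad_to < MIN_IMAGE_SIDE or (self.pad_to & (self.pad_to - 1)) != 0:
            raise ValueError("pad_to must be a power of two >= 32")


@dataclass(frozen=True)
class Subband:
    scale: str  # "coarse" | "detail" | "fine"
    wedge: int
    coeffs: np.ndarray


@dataclass
class CurveletDecomposition:
    """Ordered sub-bands plus the original (pre-padding) image shape."""

    subbands: List[Subband]
    source_shape: Tuple[int, int]
    config: CurveletConfig = field(default_factory=CurveletConfig)

    def __len__(self) -> int:
        return len(self.subbands)

    def energy(self) -> float:
        return float(sum((b.coeffs**2).sum() for b in self.subbands))


def subband_count(cfg: CurveletConfig) -> int:
    """1 coarse + detail wedges + 1 fine."""
    return 1 + cfg.n_detail_wedges + 1


def _meyer_ramp(t: np.ndarray) -> np.ndarray:
    # C^3 polynomial step: 0 below 0, 1 above 1, monotone in between.
    t = np.clip(t, 0.0, 1.0)
    return t**4 * (35 - 84 * t + 70 * t**2 - 20 * t**3)


@lru_cache(maxsize=8)
def _frequency_windows(n: int, n_wedges: int) -> Tuple[np.ndarray, ...]:
    """Smooth windows on the n x n FFT grid whose squares sum to 1.

    Radial: cos/sin Meyer transitions at |f| in [0.08, 0.16] (coarse->detail)
    and [0.25, 0.45] (detail->fine), in cycles/pixel.  Angular: smooth bumps
    centred on wedge centres (width two wedge spacings) on the angle mod pi,
    normalised so their squares sum to 1 exactly.
    """
    fy = np.fft.fftfreq(n)[:, None]
    fx = np.fft.fftfreq(n)[None, :]
    r = np.hypot(fy, fx)

    low = np.cos(0.5 * np.pi * _meyer_ramp((r - 0.08) / (0.16 - 0.08)))
    high = np.sin(0.5 * np.pi * _meyer_ramp((r - 0.25) / (0.45 - 0.25)))
    mid = np.sqrt(np.clip(1.0 - low**2 - high**2, 0.0, None))

    phi = np.arctan2(fy, fx) % np.pi
    spacing = np.pi / n_wedges
    bumps = []
    for w in range(n_wedges):
        centre = (w + 0.5) * spacing
        dist = np.abs(((phi - centre + np.pi / 2) % np.pi) - np.pi / 2)
        bumps.append(np.cos(0.5 * np.pi * _meyer_ramp(dist / spacing)))
    stack = np.array(bumps)
    norm = np.sqrt((stack**2).sum(axis=0))
    norm[norm == 0] = 1.0
    stack /= norm

    windows = [low] + [mid * stack[w] for w in range(n_wedges)] + [high]
    for win in windows:
        win.setflags(write=False)
    return tuple(windows)


def _pad(image: np.ndarray, pad_to: int) -> np.ndarray:
    out = np.zeros((pad_to, pad_to), dtype=float)
    out[: image.shape[0], : image.shape[1]] = image
    return out


def fdct_forward(image: np.ndarray, cfg: CurveletConfig = CurveletConfig()) -> CurveletDecomposition:
    """Decompose a 2-D image into 1 + n_detail_wedges + 1 real sub-bands."""
    image = np.asarray(image, dtype=float)
    if image.ndim != 2 or image.size == 0:
        raise ValueError("image must be a non-empty 2-D grid")
    if min(image.shape) < MIN_IMAGE_SIDE:
        raise ValueError(
            f"image {image.shape} too small for a 3-scale decomposition "
            f"(needs at least {MIN_IMAGE_SIDE}x{MIN_IMAGE_SIDE})"
        )
    if cfg.pad_to < max(image.shape):
        raise ValueError(f"pad_to={cfg.pad_to} smaller than image {image.shape}")

    spectrum = np.fft.fft2(_pad(image, cfg.pad_to))
    windows = _frequency_windows(cfg.pad_to, cfg.n_detail_wedges)
    labels = (
        [("coarse", 0)]
        + [("detail", w) for w in range(cfg.n_detail_wedges)]
        + [("fine", 0)]
    )
    subbands = [
        Subband(scale, wedge, np.fft.ifft2(spectrum * win).real)
        for (scale, wedge), win in zip(labels, windows)
    ]
    return CurveletDecomposition(subbands, image.shape, cfg)


def fdct_inverse(d: CurveletDecomposition, cfg: CurveletConfig | None = None) -> np.ndarray:
    """Reconstruct the image from its decomposition (tight-frame adjoint)."""
    cfg = cfg or d.config
    if cfg != d.config:
        raise ValueError("configuration does not match the decomposition")
    if len(d.subbands) != subband_count(cfg):
        raise ValueError(
            f"expected {subband_count(cfg)} sub-bands, got {len(d.subbands)}"
        )
    windows = _frequency_windows(cfg.pad_to, cfg.n_detail_wedges)
    acc = np.zeros((cfg.pad_to, cfg.pad_to), dtype=complex)
    for band, win in zip(d.subbands, windows):
        if band.coeffs.shape != (cfg.pad_to, cfg.pad_to):
            raise ValueError("sub-band shape does not match pad_to")
        acc += np.fft.fft2(band.coeffs) * win
    full = np.fft.ifft2(acc).real
    nr, nc = d.source_shape
    return full[:nr, :nc]


def dump_decomposition(d: CurveletDecomposition, directory: str | Path) -> Path:
    """Debug helper: write each sub-band as a text array plus an index JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    index = []
    for i, band in enumerate(d.subbands):
        name = f"band_{i:02d}_{band.scale}_w{band.wedge}.txt"
        np.savetxt(directory / name, band.coeffs)
        index.append(
            {"order": i, "scale": band.scale, "wedge": band.wedge,
             "shape": list(band.coeffs.shape), "file": name}
        )
    (directory / "index.json").write_text(
        json.dumps({"source_shape": list(d.source_shape), "subbands": index}, indent=2)
    )
    return directory
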