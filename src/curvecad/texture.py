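"""Gray-level co-occurrence texture statistics over curvelet sub-bands.

Each of the 34 sub-bands is quantized to ``n_levels`` equal-width bins,
a symmetric co-occurrence matrix is accumulated at four offsets
((0,1), (1,0), (1,1), (1,-1)), and fourteen Haralick-style statistics are
computed per offset and averaged.  34 sub-bands x 14 features = 476
texture values per ROI; appending age, sex, smoking and the nine
morphological covariates gives the 488-dimensional model input.

Notation: ``p(i,j)`` is the joint probability of levels i and j at an
offset (matrix symmetric, so the marginals coincide: mu_x = mu_y,
sigma_x = sigma_y); ``p_{x+y}(k)`` and ``p_{x-y}(k)`` are the
distributions of i+j and |i-j|.  Logarithms are base 2 with 0*log(0) = 0;
Correlation is defined as 0 when either marginal variance vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .curvelet import CurveletConfig, fdct_forward
from .roi_segment import RoiImage, apply_mask

__all__ = [
    "FEATURE_NAMES",
    "MORPHOLOGY_NAMES",
    "CLINICAL_NAMES",
    "DEFAULT_OFFSETS",
    "CooccurrenceMatrix",
    "FeatureVector",
    "quantize",
    "cooccurrence",
    "texture_features_14",
    "roi_texture_vector",
    "full_feature_vector",
    "texture_feature_names",
]

FEATURE_NAMES: Tuple[str, ...] = (
    "entropy",
    "mean",
    "correlation",
    "energy",
    "homogeneity",
    "stddev",
    "max_prob",
    "idm",
    "cluster_tendency",
    "inertia",
    "sum_mean",
    "diff_mean",
    "sum_entropy",
    "diff_entropy",
)

MORPHOLOGY_NAMES: Tuple[str, ...] = (
    "substantial_change",
    "density",
    "spicule",
    "cavern",
    "vacuole",
    "lobulation",
    "calcification",
    "ground_glass",
    "area_class",
)

CLINICAL_NAMES: Tuple[str, ...] = ("age", "sex", "smoking") + MORPHOLOGY_NAMES

DEFAULT_OFFSETS: Tuple[Tuple[int, int], ...] = ((0, 1), (1, 0), (1, 1), (1, -1))

_SCALE_ID = {"coarse": 0, "detail": 1, "fine": 2}


@dataclass
class CooccurrenceMatrix:
    """Symmetric joint probability matrix of quantized level pairs."""

    p: np.ndarray
    n_levels: int
    offsets: Tuple[Tuple[int, int], ...]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (self.n_levels, self.n_levels):
            raise ValueError("p must be n_levels x n_levels")


@dataclass
class FeatureVector:
    values: np.ndarray
    names: List[str]
    label: Optional[str] = None
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != len(self.names):
            raise ValueError("values and names lengths differ")
        if len(set(self.names)) != len(self.names):
            raise ValueError("feature names must be unique")

    def __len__(self) -> int:
        return len(self.values)


def quantize(
    coeffs: np.ndarray, n_levels: int, mask: Optional[np.ndarray] = None
) -> np.ndarray:
    """Equal-width quantization of a 2-D grid into levels 1..n_levels.

    Bin edges span the grid's min..max (within ``mask`` if given); a
    constant grid maps everywhere to level 1.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    coeffs = np.asarray(coeffs, dtype=float)
    sel = coeffs if mask is None else coeffs[np.asarray(mask) != 0]
    if sel.size == 0:
        raise ValueError("empty grid (or empty mask)")
    lo, hi = float(sel.min()), float(sel.max())
    if hi == lo:
        return np.ones(coeffs.shape, dtype=np.int64)
    idx = np.floor((coeffs - lo) / (hi - lo) * n_levels).astype(np.int64)
    return np.clip(idx, 0, n_levels - 1) + 1


def cooccurrence(
    levels: np.ndarray,
    n_levels: int,
    offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
) -> CooccurrenceMatrix:
    """Count level pairs at each offset and its reverse; normalize to sum 1."""
    levels = np.asarray(levels)
    if levels.ndim != 2 or levels.size == 0:
        raise ValueError("levels must be a non-empty 2-D grid")
    if levels.min() < 1 or levels.max() > n_levels:
        raise ValueError("levels must lie in 1..n_levels")
    counts = np.zeros((n_levels, n_levels), dtype=float)
    total_pairs = 0
    for dr, dc in offsets:
        a, b = _offset_pairs(levels, dr, dc)
        if a.size == 0:
            continue
        flat = np.bincount(
            (a - 1) * n_levels + (b - 1), minlength=n_levels * n_levels
        ).reshape(n_levels, n_levels)
        counts += flat + flat.T  # symmetric: count both directions
        total_pairs += 2 * a.size
    if total_pairs == 0:
        raise ValueError("no ordered pixel pair exists at any offset")
    return CooccurrenceMatrix(counts / total_pairs, n_levels, tuple(offsets))


def _offset_pairs(levels: np.ndarray, dr: int, dc: int) -> Tuple[np.ndarray, np.ndarray]:
    nr, nc = levels.shape
    r0, r1 = max(0, -dr), min(nr, nr - dr)
    c0, c1 = max(0, -dc), min(nc, nc - dc)
    a = levels[r0:r1, c0:c1]
    b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    return a.ravel(), b.ravel()


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-(nz * np.log2(nz)).sum())


def texture_features_14(P: CooccurrenceMatrix) -> Dict[str, float]:
    """The fourteen co-occurrence statistics, in the documented order."""
    p = P.p
    n = P.n_levels
    i = np.arange(1, n + 1)
    px = p.sum(axis=1)
    mu = float(i @ px)
    var = float(((i - mu) ** 2) @ px)
    sigma = np.sqrt(var)

    ii = i[:, None]
    jj = i[None, :]
    diff = ii - jj

    if sigma > 0:
        correlation = float((((ii - mu) * (jj - mu)) * p).sum() / (sigma * sigma))
    else:
        correlation = 0.0

    # distributions of i+j (2..2n) and |i-j| (0..n-1)
    ks_sum = np.arange(2, 2 * n + 1)
    p_sum = np.zeros(2 * n - 1)
    np.add.at(p_sum, (ii + jj).ravel() - 2, p.ravel())
    ks_diff = np.arange(0, n)
    p_diff = np.zeros(n)
    np.add.at(p_diff, np.abs(diff).ravel(), p.ravel())

    return {
        "entropy": _entropy_bits(p),
        "mean": mu,
        "correlation": correlation,
        "energy": float((p**2).sum()),
        "homogeneity": float((p / (1.0 + np.abs(diff))).sum()),
        "stddev": float(sigma),
        "max_prob": float(p.max()),
        "idm": float((p / (1.0 + diff**2)).sum()),
        "cluster_tendency": float((((ii + jj) - 2 * mu) ** 2 * p).sum()),
        "inertia": float((diff**2 * p).sum()),
        "sum_mean": float(ks_sum @ p_sum),
        "diff_mean": float(ks_diff @ p_diff),
        "sum_entropy": _entropy_bits(p_sum),
        "diff_entropy": _entropy_bits(p_diff),
    }


def texture_feature_names(cfg: CurveletConfig = CurveletConfig()) -> List[str]:
    """Stable names ``s{scale}_w{wedge}_{feature}`` for the texture block."""
    names: List[str] = []
    labels = (
        [("coarse", 0)]
        + [("detail", w) for w in range(cfg.n_detail_wedges)]
        + [("fine", 0)]
    )
    for scale, wedge in labels:
        for feat in FEATURE_NAMES:
            names.append(f"s{_SCALE_ID[scale]}_w{wedge}_{feat}")
    return names


def roi_texture_vector(
    image: RoiImage,
    cfg: CurveletConfig = CurveletConfig(),
    n_levels: int = 64,
    offsets: Sequence[Tuple[int, int]] = DEFAULT_OFFSETS,
    magnitude: bool = False,
) -> FeatureVector:
    """Texture block for one ROI: 14 features per sub-band, offset-averaged.

    The masked image (background zeroed) is decomposed; per sub-band the raw
    real coefficients (or their absolute values with ``magnitude=True``) are
    quantized over the sub-band's own range and the 14 statistics are
    computed per offset, then averaged over the four offsets.
    """
    masked = apply_mask(image)
    dec = fdct_forward(masked.pixels, cfg)
    values: List[float] = []
    for band in dec.subbands:
        coeffs = np.abs(band.coeffs) if magnitude else band.coeffs
        levels = quantize(coeffs, n_levels)
        per_offset = np.array(
            [
                list(texture_features_14(cooccurrence(levels, n_levels, [off])).values())
                for off in offsets
            ]
        )
        values.extend(per_offset.mean(axis=0))
    return FeatureVector(
        np.array(values),
        texture_feature_names(cfg),
        meta={
            "patient_id": image.patient_id,
            "scan_index": image.scan_index,
            "roi_id": image.roi_id,
        },
    )


def full_feature_vector(
    texture: FeatureVector,
    demographics: Tuple[float, float, float],
    morphology: Iterable[float],
    label: Optional[str] = None,
) -> FeatureVector:
    """Append age, sex (0/1), smoking (0/1) and the 9 morphology values."""
    expected = len(texture_feature_names())
    if len(texture) != expected:
        raise ValueError(
            f"texture block must have {expected} entries, got {len(texture)}"
        )
    morphology = list(morphology)
    if len(demographics) != 3:
        raise ValueError("demographics must be (age, sex, smoking)")
    if len(morphology) != len(MORPHOLOGY_NAMES):
        raise ValueError(f"expected {len(MORPHOLOGY_NAMES)} morphology values")
    values = np.concatenate([texture.values, np.asarray(demographics, float), morphology])
    names = list(texture.names) + list(CLINICAL_NAMES)
    return FeatureVector(values, names, label=label, meta=dict(texture.meta))
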