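"""Synthetic nodule cohorts with the statistical structure the CAD analysis assumes.

No CT archive ships with this package, so every downstream stage is
exercised on synthetic data built to carry the three properties the
analysis must detect:

1. *Class-separated texture*: benign and malignant ROIs are elliptical
   nodules filled with Gaussian-smoothed noise plus radial spicule
   ridges; the classes differ in noise level, smoothing and spicule
   count, so within-mask variability separates them.
2. *Reference demographics*: ages, sex and smoking are drawn from the
   class-conditional marginals of the reference training cohort
   (benign age ~ N(50.8, 13.26^2), malignant ~ N(62, 11.54^2); smoking
   39.62% vs 49.53%; male 54.72% vs 59.91%).
3. *Longitudinal drift*: over follow-up, the benign class's noise level
   rises (``drift_per_month``) while the malignant class stays flat —
   the direction the standard-deviation change analysis must recover.

The texture mechanism is a controllable stand-in, not a model of CT
physics.  All generators are fully deterministic under a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .roi_segment import RoiImage
from .texture import MORPHOLOGY_NAMES

__all__ = [
    "TextureParams",
    "CohortTable",
    "BENIGN_DEFAULTS",
    "MALIGNANT_DEFAULTS",
    "OVERLAP_BENIGN",
    "OVERLAP_MALIGNANT",
    "AGE_BY_CLASS",
    "SMOKING_P",
    "MALE_P",
    "REFERENCE_COHORT_COMPOSITION",
    "DEFAULT_MORPH_P",
    "gen_roi_image",
    "gen_cohort",
    "gen_longitudinal_cohort",
    "write_cohort",
    "read_cohort",
]

logger = logging.getLogger(__name__)

# Class-conditional marginals of the reference training cohort the
# generator emulates (age mean/sd in years; probabilities as fractions).
AGE_BY_CLASS = {"benign": (50.8, 13.26), "malignant": (62.0, 11.54)}
SMOKING_P = {"benign": 0.3962, "malignant": 0.4953}
MALE_P = {"benign": 0.5472, "malignant": 0.5991}
AGE_RANGE = (18.0, 95.0)

# Reference training-cohort composition (diagnosis, cases, ROI count):
# 3131 benign ROIs from 106 cases, 6977 malignant ROIs from 211 cases.
REFERENCE_COHORT_COMPOSITION = (
    ("benign", "tuberculosis", 33, 1150),
    ("benign", "inflammatory_pseudotumor", 27, 808),
    ("benign", "hamartoma", 30, 812),
    ("benign", "pulmonary_interstitial_edema", 1, 189),
    ("benign", "sclerosing_hemangioma", 9, 93),
    ("benign", "clear_cell_tumor", 1, 11),
    ("benign", "chondroma", 5, 68),
    ("malignant", "glandular_cancer", 155, 5571),
    ("malignant", "squamous_carcinoma", 47, 1125),
    ("malignant", "adenosquamous_carcinoma", 7, 244),
    ("malignant", "malignant_carcinoid_tumor", 2, 37),
)

# Bernoulli probabilities (benign, malignant) for the morphology covariates.
DEFAULT_MORPH_P: Dict[str, Tuple[float, float]] = {
    name: ((0.2, 0.6) if name in ("spicule", "lobulation", "vacuole") else (0.5, 0.5))
    for name in MORPHOLOGY_NAMES
}

MIN_SIDE = 32  # a 3-scale decomposition needs at least this


@dataclass(frozen=True)
class TextureParams:
    """Per-class texture recipe for synthetic nodules.

    base_intensity : mean intensity inside the nodule (CT-like units).
    noise_sd : sd of the Gaussian noise field before smoothing.
    smoothing_sigma : Gaussian smoothing of the noise, pixels.
    spicule_count : number of radial intensity ridges.
    drift_per_month : added to noise_sd per month of follow-up.
    """

    class_label: str
    base_intensity: float = 120.0
    noise_sd: float = 6.0
    smoothing_sigma: float = 1.8
    spicule_count: int = 2
    drift_per_month: float = 0.0

    def __post_init__(self) -> None:
        if self.class_label not in ("benign", "malignant"):
            raise ValueError("class_label must be 'benign' or 'malignant'")
        if self.noise_sd < 0 or self.smoothing_sigma < 0:
            raise ValueError("noise_sd and smoothing_sigma must be >= 0")
        if self.spicule_count < 0:
            raise ValueError("spicule_count must be >= 0")


BENIGN_DEFAULTS = TextureParams(
    "benign", base_intensity=120.0, noise_sd=6.0, smoothing_sigma=0.5,
    spicule_count=2, drift_per_month=0.8,
)
MALIGNANT_DEFAULTS = TextureParams(
    "malignant", base_intensity=140.0, noise_sd=14.0, smoothing_sigma=0.7,
    spicule_count=8, drift_per_month=0.0,
)

# A deliberately hard scenario for class-imbalance experiments: the classes
# share geometry and differ only moderately in noise level, so single-ROI
# classification is error-prone and balancing has room to matter.
OVERLAP_BENIGN = TextureParams(
    "benign", base_intensity=130.0, noise_sd=8.0, smoothing_sigma=1.2,
    spicule_count=4, drift_per_month=0.0,
)
OVERLAP_MALIGNANT = TextureParams(
    "malignant", base_intensity=130.0, noise_sd=11.0, smoothing_sigma=1.2,
    spicule_count=4, drift_per_month=0.0,
)


@dataclass
class CohortTable:
    """Per-patient covariates plus the scan/ROI registry.

    patients : one row per patient — patient_id, age, sex, smoking, the 9
        morphology covariates, label.
    scans : one row per ROI — patient_id, scan_index, months_from_first,
        roi_id.
    """

    patients: pd.DataFrame
    scans: pd.DataFrame

    def validate(self, images: Optional[Dict[str, RoiImage]] = None) -> None:
        if self.patients["patient_id"].duplicated().any():
            raise ValueError("patient_id values must be unique")
        if self.scans["roi_id"].duplicated().any():
            raise ValueError("roi_id values must be unique")
        for pid, grp in self.scans.groupby("patient_id"):
            g = grp.sort_values("scan_index")
            months = g.groupby("scan_index")["months_from_first"].first()
            if months.iloc[0] != 0:
                raise ValueError(f"patient {pid}: first scan must be at month 0")
            if not months.is_monotonic_increasing:
                raise ValueError(f"patient {pid}: months_from_first must be non-decreasing")
        if images is not None:
            missing = set(self.scans["roi_id"]) - set(images)
            if missing:
                raise ValueError(f"roi_ids without images: {sorted(missing)[:5]}")


def gen_roi_image(
    params: TextureParams,
    side: int = 64,
    seed: int = 0,
    months_from_first: float = 0.0,
    patient_id: str = "",
    scan_index: int = 0,
    roi_id: str = "",
) -> RoiImage:
    """One synthetic nodule ROI: centrally placed ellipse, class texture.

    Inside the elliptical mask the intensity is ``base_intensity`` plus
    Gaussian-smoothed noise of sd ``noise_sd + drift_per_month * months``
    and ``spicule_count`` radial ridges; outside both image and mask are 0.
    Identical arguments give bit-identical images.
    """
    if side < MIN_SIDE:
        raise ValueError(f"side must be >= {MIN_SIDE} for a 3-scale decomposition")
    rng = np.random.default_rng(seed)
    c = (side - 1) / 2.0
    yy, xx = np.mgrid[0:side, 0:side]
    dy, dx = yy - c, xx - c

    a = side * rng.uniform(0.30, 0.40)  # semi-axes, pixels
    b = side * rng.uniform(0.30, 0.40)
    mask = ((dx / a) ** 2 + (dy / b) ** 2 <= 1.0).astype(np.uint8)

    sd = max(0.0, params.noise_sd + params.drift_per_month * months_from_first)
    noise = rng.normal(0.0, 1.0, size=(side, side)) * sd
    if params.smoothing_sigma > 0:
        noise = gaussian_filter(noise, params.smoothing_sigma)
    tex = params.base_intensity + noise

    if params.spicule_count > 0:
        theta = np.arctan2(dy, dx)
        radius = np.hypot(dy, dx)
        amp = 0.25 * params.base_intensity
        for _ in range(params.spicule_count):
            angle = rng.uniform(-np.pi, np.pi)
            dtheta = np.abs(((theta - angle + np.pi) % (2 * np.pi)) - np.pi)
            ridge = amp * np.exp(-(dtheta**2) / (2 * 0.06**2))
            tex = tex + np.where(radius > 1.0, ridge, 0.0)

    return RoiImage(
        pixels=tex * mask,
        mask=mask,
        patient_id=patient_id,
        scan_index=scan_index,
        roi_id=roi_id,
    )


def _draw_patient_row(
    rng: np.random.Generator,
    pid: str,
    label: str,
    morph_p: Dict[str, Tuple[float, float]],
) -> Dict[str, object]:
    mean, sd = AGE_BY_CLASS[label]
    age = float(rng.normal(mean, sd))
    clamped = float(np.clip(age, *AGE_RANGE))
    if clamped != age:
        logger.info("age %.1f for %s clamped into %s", age, pid, AGE_RANGE)
    row: Dict[str, object] = {
        "patient_id": pid,
        "age": clamped,
        "sex": "male" if rng.uniform() < MALE_P[label] else "female",
        "smoking": "yes" if rng.uniform() < SMOKING_P[label] else "no",
    }
    idx = 0 if label == "benign" else 1
    for name in MORPHOLOGY_NAMES:
        row[name] = int(rng.uniform() < morph_p[name][idx])
    row["label"] = label
    return row


def gen_cohort(
    n_benign: int,
    n_malignant: int,
    rois_per_patient: Tuple[int, int] = (3, 6),
    seed: int = 0,
    side: int = 64,
    benign_params: TextureParams = BENIGN_DEFAULTS,
    malignant_params: TextureParams = MALIGNANT_DEFAULTS,
    morph_probs: Optional[Dict[str, Tuple[float, float]]] = None,
    generate_images: bool = True,
) -> Tuple[CohortTable, Dict[str, RoiImage]]:
    """A single-scan cohort: covariates per patient plus ROI images."""
    if n_benign < 1 or n_malignant < 1:
        raise ValueError("both class counts must be >= 1")
    lo, hi = rois_per_patient
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid rois_per_patient range {rois_per_patient}")
    morph_p = dict(DEFAULT_MORPH_P)
    if morph_probs:
        morph_p.update(morph_probs)

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    img_seeds = np.random.SeedSequence([seed, 2])

    patient_rows, scan_rows = [], []
    images: Dict[str, RoiImage] = {}
    specs = [("benign", benign_params, n_benign), ("malignant", malignant_params, n_malignant)]
    for label, params, count in specs:
        for i in range(count):
            pid = f"{label[:3]}{i:04d}"
            patient_rows.append(_draw_patient_row(rng, pid, label, morph_p))
            n_rois = int(rng.integers(lo, hi + 1))
            for r in range(n_rois):
                roi_id = f"{pid}_s0_r{r}"
                scan_rows.append(
                    {"patient_id": pid, "scan_index": 0,
                     "months_from_first": 0.0, "roi_id": roi_id}
                )
                if generate_images:
                    child = img_seeds.spawn(1)[0]
                    images[roi_id] = gen_roi_image(
                        params, side=side,
                        seed=int(child.generate_state(1)[0] % 2**31),
                        patient_id=pid, scan_index=0, roi_id=roi_id,
                    )
    cohort = CohortTable(pd.DataFrame(patient_rows), pd.DataFrame(scan_rows))
    cohort.validate(images if generate_images else None)
    return cohort, images


def gen_longitudinal_cohort(
    n_per_class: int,
    scans_per_patient: int = 2,
    seed: int = 0,
    side: int = 64,
    rois_per_scan: Tuple[int, int] = (1, 2),
    benign_params: TextureParams = BENIGN_DEFAULTS,
    malignant_params: TextureParams = MALIGNANT_DEFAULTS,
    mean_followup_months: float = 6.9,
    median_followup_months: float = 2.0,
) -> Tuple[CohortTable, Dict[str, RoiImage]]:
    """A follow-up cohort in which only the benign class's texture drifts.

    Each patient's total follow-up is lognormal, parameterised to match
    the configured mean and median (right-skewed, default mean 6.9 and
    median 2.0 months); scans are evenly spaced over that span.  The
    noise level at a later scan is ``noise_sd + drift_per_month * months``.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if scans_per_patient < 2:
        raise ValueError("scans_per_patient must be >= 2")
    lo, hi = rois_per_scan
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid rois_per_scan range {rois_per_scan}")
    if not (0 < median_followup_months <= mean_followup_months):
        raise ValueError("need 0 < median <= mean follow-up")

    mu = np.log(median_followup_months)
    sigma = np.sqrt(2.0 * np.log(mean_followup_months / median_followup_months))

    rng = np.random.default_rng(np.random.SeedSequence([seed, 3]))
    img_seeds = np.random.SeedSequence([seed, 4])
    morph_p = dict(DEFAULT_MORPH_P)

    patient_rows, scan_rows = [], []
    images: Dict[str, RoiImage] = {}
    for label, params in (("benign", benign_params), ("malignant", malignant_params)):
        for i in range(n_per_class):
            pid = f"L{label[:3]}{i:04d}"
            patient_rows.append(_draw_patient_row(rng, pid, label, morph_p))
            total = float(rng.lognormal(mu, sigma))
            n_rois = int(rng.integers(lo, hi + 1))
            # one seed per nodule, shared across scans: a follow-up scan
            # images the same lesion (same shape, spicules and noise
            # realization); only the noise amplitude drifts with time
            roi_seeds = [
                int(c.generate_state(1)[0] % 2**31) for c in img_seeds.spawn(n_rois)
            ]
            for s in range(scans_per_patient):
                months = total * s / (scans_per_patient - 1)
                for r in range(n_rois):
                    roi_id = f"{pid}_s{s}_r{r}"
                    scan_rows.append(
                        {"patient_id": pid, "scan_index": s,
                         "months_from_first": months, "roi_id": roi_id}
                    )
                    images[roi_id] = gen_roi_image(
                        params, side=side, seed=roi_seeds[r],
                        months_from_first=months,
                        patient_id=pid, scan_index=s, roi_id=roi_id,
                    )
    cohort = CohortTable(pd.DataFrame(patient_rows), pd.DataFrame(scan_rows))
    cohort.validate(images)
    return cohort, images


_PNG_SCALE = 100.0  # stored value = round(intensity * 100), uint16


def write_cohort(
    directory: str | Path,
    cohort: CohortTable,
    images: Dict[str, RoiImage],
    manifest: Optional[Dict[str, object]] = None,
    write_images: bool = True,
) -> Path:
    """Persist a cohort: CSV metadata, 16-bit PNG images + masks, manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cohort.patients.to_csv(directory / "patients.csv", index=False)
    cohort.scans.to_csv(directory / "scans.csv", index=False)
    if write_images:
        img_dir = directory / "images"
        img_dir.mkdir(exist_ok=True)
        for roi_id, img in images.items():
            stored = np.clip(img.pixels * _PNG_SCALE, 0, 65535).round().astype(np.uint16)
            iio.imwrite(img_dir / f"{roi_id}.png", stored)
            iio.imwrite(img_dir / f"{roi_id}_mask.png", (img.mask * 255).astype(np.uint8))
    meta = dict(manifest or {})
    meta.setdefault("png_intensity_scale", _PNG_SCALE)
    meta["n_patients"] = int(len(cohort.patients))
    meta["n_rois"] = int(len(cohort.scans))
    (directory / "manifest.json").write_text(json.dumps(meta, indent=2, default=str))
    return directory


def read_cohort(directory: str | Path) -> Tuple[CohortTable, Dict[str, RoiImage]]:
    """Load a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    patients = pd.read_csv(directory / "patients.csv")
    scans = pd.read_csv(directory / "scans.csv")
    manifest = json.loads((directory / "manifest.json").read_text())
    scale = float(manifest.get("png_intensity_scale", _PNG_SCALE))
    images: Dict[str, RoiImage] = {}
    img_dir = directory / "images"
    if img_dir.is_dir():
        for _, row in scans.iterrows():
            roi_id = row["roi_id"]
            pixels = iio.imread(img_dir / f"{roi_id}.png").astype(float) / scale
            mask = (iio.imread(img_dir / f"{roi_id}_mask.png") > 0).astype(np.uint8)
            images[roi_id] = RoiImage(
                pixels, mask, patient_id=row["patient_id"],
                scan_index=int(row["scan_index"]), roi_id=roi_id,
            )
    cohort = CohortTable(patients, scans)
    cohort.validate(images if images else None)
    return cohort, images
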