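"""End-to-end orchestration: simulate -> segment -> extract -> balance -> evaluate.

A run is fully described by a :class:`RunConfig` (serializable to YAML)
plus its root seed; per-stage seeds are derived from the root seed with
``numpy.random.SeedSequence`` so that identical configs produce
byte-identical feature tables.  Each stage logs its name, elapsed time
and derived seed; output CSVs are checksummed into ``manifest.json``.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
import yaml

from . import model_eval, synth_cohort
from .balance import LabeledTable, balance_dataset
from .curvelet import CurveletConfig
from .roi_segment import RoiImage, apply_mask, centroid_seed, region_grow
from .synth_cohort import CohortTable, TextureParams
from .texture import CLINICAL_NAMES, roi_texture_vector, texture_feature_names

__all__ = [
    "RunConfig",
    "run_pipeline",
    "extract_features",
    "segment_rois",
    "feature_table_to_labeled",
    "minority_recall_trial",
]

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Everything needed to reproduce a run (plus the root seed)."""

    seed: int = 0
    out_dir: str = "curvecad_run"
    # cohort
    n_benign: int = 20
    n_malignant: int = 20
    rois_per_patient: Tuple[int, int] = (3, 5)
    side: int = 64
    benign_params: TextureParams = field(default_factory=lambda: synth_cohort.BENIGN_DEFAULTS)
    malignant_params: TextureParams = field(default_factory=lambda: synth_cohort.MALIGNANT_DEFAULTS)
    # segmentation
    region_tol: float = 60.0
    # texture
    pad_to: int = 64
    n_detail_wedges: int = 32
    n_levels: int = 64
    # balancing
    balance_target: str | int = "match_majority"
    smote_k: int = 5
    # model / CV
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    cv_k: int = 10
    grouping: str = "patient"
    # longitudinal stage (0 disables it)
    longitudinal_n_per_class: int = 10
    scans_per_patient: int = 2
    write_images: bool = False

    def curvelet_config(self) -> CurveletConfig:
        return CurveletConfig(pad_to=self.pad_to, n_detail_wedges=self.n_detail_wedges)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["schema_version"] = SCHEMA_VERSION
        d["rois_per_patient"] = list(self.rois_per_patient)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text())
        version = d.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {version}")
        for key in ("benign_params", "malignant_params"):
            if key in d and isinstance(d[key], dict):
                d[key] = TextureParams(**d[key])
        if "rois_per_patient" in d:
            d["rois_per_patient"] = tuple(d["rois_per_patient"])
        return cls(**d)


def _stage_seeds(root: int, n: int = 8) -> list[int]:
    children = np.random.SeedSequence(root).spawn(n)
    return [int(c.generate_state(1)[0] % 2**31) for c in children]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def segment_rois(
    images: Dict[str, RoiImage], tol: float
) -> Dict[str, RoiImage]:
    """Re-derive each ROI's mask by region growing from its centroid."""
    out: Dict[str, RoiImage] = {}
    for roi_id, img in images.items():
        seed_pt = centroid_seed(img.mask if img.mask.any() else np.ones_like(img.mask))
        mask = region_grow(img.pixels, seed_pt, tol=tol)
        out[roi_id] = apply_mask(RoiImage(img.pixels, mask, img.patient_id, img.scan_index, roi_id))
    return out


def extract_features(
    cohort: CohortTable,
    images: Dict[str, RoiImage],
    cfg: CurveletConfig = CurveletConfig(),
    n_levels: int = 64,
) -> pd.DataFrame:
    """One row per ROI: 488 model inputs plus identifiers and label.

    Column order: the 476 texture names, then age/sex/smoking and the 9
    morphology covariates, then patient_id, scan_index, roi_id, label.
    """
    pat = cohort.patients.set_index("patient_id")
    rows = []
    for _, scan in cohort.scans.iterrows():
        roi_id = scan["roi_id"]
        img = images[roi_id]
        fv = roi_texture_vector(img, cfg, n_levels=n_levels)
        p = pat.loc[scan["patient_id"]]
        row = dict(zip(fv.names, fv.values))
        row["age"] = float(p["age"])
        row["sex"] = 1.0 if p["sex"] == "male" else 0.0
        row["smoking"] = 1.0 if p["smoking"] == "yes" else 0.0
        for name in CLINICAL_NAMES[3:]:
            row[name] = float(p[name])
        row["patient_id"] = scan["patient_id"]
        row["scan_index"] = int(scan["scan_index"])
        row["roi_id"] = roi_id
        row["label"] = p["label"]
        rows.append(row)
    cols = texture_feature_names(cfg) + list(CLINICAL_NAMES) + [
        "patient_id", "scan_index", "roi_id", "label",
    ]
    return pd.DataFrame(rows, columns=cols)


def feature_table_to_labeled(df: pd.DataFrame) -> Tuple[LabeledTable, np.ndarray]:
    """Split a feature table into (LabeledTable, per-row patient groups)."""
    feature_cols = [c for c in df.columns if c not in ("patient_id", "scan_index", "roi_id", "label")]
    t = LabeledTable.from_arrays(df[feature_cols].to_numpy(float), df["label"].to_numpy())
    return t, df["patient_id"].to_numpy()


def _patient_rates(
    df: pd.DataFrame, oof_predictions: np.ndarray
) -> pd.DataFrame:
    work = df[["patient_id", "label"]].copy()
    work["pred"] = oof_predictions
    rows = [
        {
            "patient_id": pid,
            "label": grp["label"].iloc[0],
            "malignance_rate": model_eval.malignance_rate(grp["pred"]),
        }
        for pid, grp in work.groupby("patient_id", sort=True)
    ]
    return pd.DataFrame(rows)


def minority_recall_trial(
    seed: int,
    n_benign: int = 16,
    n_malignant: int = 32,
    rois_per_patient: Tuple[int, int] = (2, 3),
    region_tol: float = 60.0,
) -> Tuple[float, float]:
    """Benign (minority) recall without vs with SMOTE on one 2:1 cohort.

    Uses the overlapping-texture scenario (classes differ only in noise
    level), a patient-grouped 50/50 train/test split, and the default SVM.
    Returns (recall_without_smote, recall_with_smote) on held-out benign ROIs.
    """
    from sklearn.model_selection import GroupShuffleSplit

    cohort, images = synth_cohort.gen_cohort(
        n_benign, n_malignant, rois_per_patient, seed=seed,
        benign_params=synth_cohort.OVERLAP_BENIGN,
        malignant_params=synth_cohort.OVERLAP_MALIGNANT,
    )
    features = extract_features(cohort, segment_rois(images, tol=region_tol))
    table, groups = feature_table_to_labeled(features)
    splitter = GroupShuffleSplit(n_splits=1, test_size=0.5, random_state=seed)
    tr, te = next(splitter.split(table.X, table.y, groups))
    train = LabeledTable.from_arrays(table.X[tr], table.y[tr])
    plain = model_eval.train_svm(train, seed=seed)
    smoted = model_eval.train_svm(balance_dataset(train, seed=seed), seed=seed)
    te_benign = te[table.y[te] == "benign"]
    recall = lambda m: float(
        (model_eval.predict(m, table.X[te_benign]) == "benign").mean()
    )
    return recall(plain), recall(smoted)


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute every stage; returns the run directory."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("curvecad")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    seeds = _stage_seeds(cfg.seed)
    manifest: Dict[str, object] = {
        "schema_version": SCHEMA_VERSION,
        "root_seed": cfg.seed,
        "stage_seeds": seeds,
        "checksums": {},
    }
    cfg.to_yaml(out / "config.yaml")

    def stage(name: str):
        return _StageTimer(name)

    try:
        with stage("simulate"):
            cohort, images = synth_cohort.gen_cohort(
                cfg.n_benign, cfg.n_malignant, cfg.rois_per_patient,
                seed=seeds[0], side=cfg.side,
                benign_params=cfg.benign_params, malignant_params=cfg.malignant_params,
            )
            synth_cohort.write_cohort(out / "cohort", cohort, images,
                                      manifest={"seed": seeds[0]},
                                      write_images=cfg.write_images)

        with stage("segment"):
            segmented = segment_rois(images, tol=cfg.region_tol)

        with stage("extract"):
            features = extract_features(cohort, segmented, cfg.curvelet_config(), cfg.n_levels)
            fpath = out / "features.csv"
            features.to_csv(fpath, index=False)
            manifest["checksums"]["features.csv"] = _sha256(fpath)

        with stage("balance"):
            table, groups = feature_table_to_labeled(features)
            balanced = balance_dataset(table, target=cfg.balance_target,
                                       k=cfg.smote_k, seed=seeds[1])
            bdf = pd.DataFrame(balanced.X, columns=[
                c for c in features.columns
                if c not in ("patient_id", "scan_index", "roi_id", "label")
            ])
            bdf["label"] = balanced.y
            bdf["provenance"] = balanced.provenance
            bpath = out / "balanced.csv"
            bdf.to_csv(bpath, index=False)
            manifest["checksums"]["balanced.csv"] = _sha256(bpath)

        with stage("evaluate"):
            cv_raw = model_eval.kfold_cv(
                table, k=cfg.cv_k, grouping=cfg.grouping, groups=groups,
                C=cfg.svm_C, gamma=cfg.svm_gamma, seed=seeds[2],
            )
            # balanced rows include synthetic vectors with no patient, so
            # the balanced-accuracy CV stratifies rows directly
            cv_bal = model_eval.kfold_cv(
                balanced, k=cfg.cv_k, grouping="roi",
                C=cfg.svm_C, gamma=cfg.svm_gamma, seed=seeds[2],
            )
            rates = _patient_rates(features, cv_raw["oof_predictions"])
            roc = model_eval.roc_auc(rates["malignance_rate"], rates["label"])
            model = model_eval.train_svm(balanced, C=cfg.svm_C,
                                         gamma=cfg.svm_gamma, seed=seeds[3])
            model.to_json(out / "model.json")
            rates.to_csv(out / "patient_rates.csv", index=False)
            pd.DataFrame(roc["roc"], columns=["fpr", "tpr", "threshold"]).to_csv(
                out / "roc.csv", index=False
            )
            eval_payload = {
                "cv_unbalanced": {
                    "fold_accuracies": cv_raw["fold_accuracies"],
                    "mean_accuracy": cv_raw["mean_accuracy"],
                },
                "cv_balanced": {
                    "fold_accuracies": cv_bal["fold_accuracies"],
                    "mean_accuracy": cv_bal["mean_accuracy"],
                },
                "patient_level": {"auc": roc["auc"], "auc_p": roc["auc_p"]},
            }
            (out / "eval.json").write_text(json.dumps(eval_payload, indent=2))

        if cfg.longitudinal_n_per_class > 0:
            with stage("longitudinal"):
                lcohort, limages = synth_cohort.gen_longitudinal_cohort(
                    cfg.longitudinal_n_per_class, cfg.scans_per_patient,
                    seed=seeds[4], side=cfg.side,
                    benign_params=cfg.benign_params,
                    malignant_params=cfg.malignant_params,
                )
                lseg = segment_rois(limages, tol=cfg.region_tol)
                lfeat = extract_features(lcohort, lseg, cfg.curvelet_config(), cfg.n_levels)
                per_patient, summary = model_eval.feature_change(lfeat)
                per_patient.to_csv(out / "longitudinal_patients.csv", index=False)
                summary.to_csv(out / "longitudinal_summary.csv", index=False)
                (out / "longitudinal.json").write_text(
                    summary.to_json(orient="records", indent=2)
                )
    except Exception as exc:  # annotate failing stage for the caller
        logger.error("pipeline aborted: %s", exc)
        raise
    finally:
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        root_logger.removeHandler(handler)
        handler.close()
    return out


class _StageTimer:
    def __init__(self, name: str):
        self.name = name

    def __enter__(self):
        self.t0 = time.perf_counter()
        logger.info("stage %s: start", self.name)
        return self

    def __exit__(self, exc_type, exc, tb):
        elapsed = time.perf_counter() - self.t0
        if exc_type is None:
            logger.info("stage %s: done in %.1fs", self.name, elapsed)
        else:
            logger.error("stage %s: failed after %.1fs (%s)", self.name, elapsed, exc)
        return False
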