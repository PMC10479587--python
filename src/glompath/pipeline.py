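"""End-to-end orchestration: cohort -> preprocess -> segment -> extract ->
select/train -> glomerulus- and patient-level evaluation -> reports.

A run is fully described by a :class:`RunConfig`; every stochastic stage has
its own explicit seed so stages are independently reproducible, and all
artifacts (feature table, model, predictions, metrics, patient report,
config) are written to the output directory.  Re-running an identical
config reproduces byte-identical metrics JSON.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import features as feat
from . import metrics as met
from . import patient_level as pat
from . import phantom as ph
from . import preprocess as pre
from . import segmentation as seg
from .classify import (
    glomerulus_predictions,
    holdout_split,
    make_bfe_classifier,
    patient_grouped_cv,
    split_feature_table,
)
from .reference import (
    REFERENCE_GLOMERULAR_CONFUSION,
    REFERENCE_METRICS,
    REFERENCE_PATIENT_CONFUSION,
)


@dataclass
class RunConfig:
    out_dir: str = "glompath_run"
    # phantom cohort settings (used when no manifest is given)
    n_patients_per_disease: int = 15
    glom_range: tuple[int, int] = (6, 10)
    image_size: int = 384
    # preprocessing
    normalize: bool = True
    fence_factor: float = 1.5
    out_size: int = 384
    # classification
    top_k: int = 10
    n_folds: int = 5
    # per-stage seeds
    phantom_seed: int = 11
    split_seed: int = 12
    forest_seed: int = 13
    nb_seed: int = 14
    registry_version: str = feat.REGISTRY_VERSION

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True)


@dataclass
class RunResult:
    feature_table: pd.DataFrame
    cv: dict
    glomerular_metrics: dict
    patient_metrics: dict
    patient_report: pd.DataFrame
    glom_predictions: pd.DataFrame
    dice: dict
    n_excluded: int
    train_patients: list
    test_patients: list
    metrics_json: str


def _log(msg: str) -> None:
    print(f"[glompath] {msg}", file=sys.stderr, flush=True)


def load_manifest(manifest_path) -> list[ph.Phantom]:
    """Load a cohort written by :func:`glompath.phantom.write_cohort`."""
    import imageio.v3 as iio

    manifest_path = Path(manifest_path)
    base = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    records = []
    for _, row in manifest.iterrows():
        for col in ("image_path", "mask_path", "structmap_path"):
            if not (base / row[col]).exists():
                raise FileNotFoundError(f"ROI {row['glom_id']}: missing file {row[col]} (load stage)")
        records.append(
            ph.Phantom(
                image=iio.imread(base / row["image_path"]),
                boundary_mask=iio.imread(base / row["mask_path"]) > 0,
                structure_map=iio.imread(base / row["structmap_path"]),
                label=row["label"],
                patient_id=row["patient_id"],
                glom_id=row["glom_id"],
                seed=-1,
            )
        )
    return records


def run_bfe(config: RunConfig, records: list[ph.Phantom] | None = None) -> RunResult:
    """Execute the full biomarker-feature-extraction pipeline.

    If ``records`` is None, a phantom cohort is generated from the config.
    Artifacts are written under ``config.out_dir``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    if records is None:
        _log("stage phantom: generating cohort")
        records, _manifest = ph.generate_cohort(
            config.n_patients_per_disease,
            config.glom_range,
            config.phantom_seed,
            image_size=config.image_size,
        )
    _log(f"stage phantom: {len(records)} glomeruli")

    # --- size-outlier exclusion
    areas = [int(r.boundary_mask.sum()) for r in records]
    flags = pre.detect_size_outliers(areas, config.fence_factor)
    n_excluded = int(flags.sum())
    records = [r for r, f in zip(records, flags) if not f]
    _log(f"stage outliers: excluded {n_excluded}")

    # --- color normalization (masked Lab statistics)
    if config.normalize:
        ref = min(records, key=lambda r: r.glom_id)
        target = pre.NormalizationTarget.from_image(ref.image, ref.boundary_mask)
        (Path(out) / "normalization_target.json").write_text(target.to_json())
        for r in records:
            r.image = pre.reinhard_normalize(r.image, r.boundary_mask, target)
        _log("stage normalize: done")

    # --- Naive Bayes segmentation model from training-patient annotations
    train_pat, test_pat = holdout_split(
        pd.DataFrame({"patient_id": [r.patient_id for r in records], "label": [r.label for r in records]}),
        seed=config.split_seed,
    )
    train_records = [r for r in records if r.patient_id in set(train_pat)]
    rng = np.random.default_rng(config.nb_seed)
    px, py = seg.sample_training_pixels(train_records, rng)
    nb = seg.fit_nb(px, py, required_classes=seg.SEGMENT_CLASSES)
    (out / "nb_model.json").write_text(seg.model_to_json(nb))

    # --- re-center / crop / resize, then segment
    side = pre.compute_global_crop_side([r.boundary_mask for r in records])
    _log(f"stage crop: global side {side} -> out size {config.out_size}")
    dice_acc = {c: [] for c in seg.SEGMENT_CLASSES}
    processed = []
    for r in records:
        pred_map_full = nb.segment(r.image, r.boundary_mask)
        d = seg.dice_per_class(pred_map_full, r.structure_map)
        for c in dice_acc:
            dice_acc[c].append(d[c])
        img, mask = pre.recenter_crop_resize(
            r.image, r.boundary_mask, side, config.out_size, return_mask=True
        )
        pred_map = nb.segment(img, mask)
        processed.append(
            ph.Phantom(
                image=img, structure_map=pred_map, boundary_mask=mask,
                label=r.label, patient_id=r.patient_id, glom_id=r.glom_id, seed=r.seed,
            )
        )
    dice = {ph.STRUCTURE_NAMES[c]: float(np.mean(v)) for c, v in dice_acc.items()}
    _log(f"stage segment: mean Dice {dice}")

    # --- biomarker extraction
    registry = feat.DEFAULT_REGISTRY
    table = feat.extract_table(processed, registry)
    table.to_csv(out / "features.csv", index=False)
    (out / "registry.json").write_text(registry.to_json())
    _log(f"stage features: {table.shape[0]} x {len(registry)}")

    # --- cross-validation on the training patients only
    train_table = table[table["patient_id"].isin(set(train_pat))].reset_index(drop=True)
    test_table = table[table["patient_id"].isin(set(test_pat))].reset_index(drop=True)
    cv = patient_grouped_cv(train_table, n_folds=config.n_folds, seed=config.forest_seed, top_k=config.top_k)
    _log(f"stage cv: {100 * cv['mean_accuracy']:.1f} +/- {100 * cv['sd_accuracy']:.1f}%")

    # --- final model on all training patients, evaluate held-out patients
    clf = make_bfe_classifier(top_k=config.top_k, seed=config.forest_seed)
    Xtr, ytr, _ = split_feature_table(train_table)
    clf.fit(Xtr.to_numpy(dtype=np.float64), ytr)
    selected = [Xtr.columns[i] for i in clf.named_steps["select"].selected_idx_]
    glom_preds = glomerulus_predictions(clf, test_table)
    glom_preds.to_csv(out / "predictions.csv", index=False)
    (out / "model.json").write_text(
        json.dumps(
            {
                "selected_features": selected,
                "classes": list(clf.named_steps["lda"].classes_),
                "coef": clf.named_steps["lda"].coef_.tolist(),
                "intercept": clf.named_steps["lda"].intercept_.tolist(),
                "priors": clf.named_steps["lda"].priors_.tolist(),
            },
            sort_keys=True,
        )
    )

    m_glom = met.confusion(glom_preds["true"], glom_preds["predicted"])
    glom_metrics = met.summarize(m_glom, level="glomerular")

    patient_preds = pat.aggregate_cohort(glom_preds)
    truths = test_table[["patient_id", "label"]].drop_duplicates()
    report = pat.cohort_report(patient_preds, truths)
    report["table"].to_csv(out / "patient_report.csv", index=False)
    m_pat = met.confusion(report["table"]["true"], report["table"]["predicted"])
    pat_metrics = met.summarize(m_pat, level="patient")
    _log(
        f"stage evaluate: glomerular acc {glom_metrics['accuracy']}%, "
        f"patient acc {pat_metrics['accuracy']}%"
    )

    config_provenance = {k: v for k, v in json.loads(config.to_json()).items() if k != "out_dir"}
    metrics_json = json.dumps(
        {
            "config": config_provenance,
            "n_glomeruli": int(table.shape[0]),
            "n_excluded": n_excluded,
            "train_patients": train_pat,
            "test_patients": test_pat,
            "selected_features": selected,
            "dice": dice,
            "cv": {k: cv[k] for k in ("fold_accuracies", "mean_accuracy", "sd_accuracy")},
            "glomerular": glom_metrics,
            "patient": pat_metrics,
            "mean_confidence": report["mean_confidence"],
            "sd_confidence": report["sd_confidence"],
        },
        sort_keys=True,
        indent=2,
    )
    (out / "metrics.json").write_text(metrics_json)
    (out / "config.json").write_text(config.to_json())
    _log(f"done in {time.perf_counter() - t0:.1f}s")

    return RunResult(
        feature_table=table,
        cv=cv,
        glomerular_metrics=glom_metrics,
        patient_metrics=pat_metrics,
        patient_report=report["table"],
        glom_predictions=glom_preds,
        dice=dice,
        n_excluded=n_excluded,
        train_patients=train_pat,
        test_patients=test_pat,
        metrics_json=metrics_json,
    )


def verify_tables(glomerular_matrix=None, patient_matrix=None) -> dict:
    """Recompute every reference metric from the embedded confusion matrices
    and compare with the published values; returns a pass/fail report.

    The matrices default to the shipped reference fixtures; passing a
    perturbed matrix makes the corresponding targets fail (sensitivity).
    """
    if glomerular_matrix is None:
        glomerular_matrix = REFERENCE_GLOMERULAR_CONFUSION
    if patient_matrix is None:
        patient_matrix = REFERENCE_PATIENT_CONFUSION
    checks = []

    def add(name, computed, expected, tol):
        checks.append(
            {
                "target": name,
                "computed": computed,
                "expected": expected,
                "pass": abs(computed - expected) <= tol,
            }
        )

    for level, m in (("glomerular", glomerular_matrix), ("patient", patient_matrix)):
        ref = REFERENCE_METRICS[level]
        s = met.summarize(m, level)
        add(f"{level}_accuracy", s["accuracy"], ref["accuracy"], 0.005)
        add(f"{level}_macro_precision", s["macro_precision"], ref["macro_precision"], 0.005)
        add(f"{level}_macro_recall", s["macro_recall"], ref["macro_recall"], 0.005)
        add(f"{level}_f1", s["f1"], ref["f1"], 0.005)
        for cls, expected in ref["per_class_recall"].items():
            add(
                f"{level}_recall_{cls}",
                round(s["per_class"][cls]["recall"]),
                expected,
                0,
            )
    return {"all_pass": all(c["pass"] for c in checks), "checks": checks}
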