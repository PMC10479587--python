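"""Patient-level diagnosis by top-4 probability aggregation.

A patient's glomeruli are ranked by their maximum class probability (the
classifier's confidence in its own call); the probability triplets of the
top four (or all, if fewer) are averaged element-wise.  The argmax of the
mean triplet is the patient diagnosis and its value is the confidence
rating — emulating how a pathologist may diagnose from the few glomeruli
that best exemplify a disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import BFE_CLASSES

TOP_K_GLOMERULI = 4


@dataclass(frozen=True)
class PatientPrediction:
    patient_id: str
    probabilities: tuple[float, float, float]  # over (MCD, MN, TBMN)
    predicted: str
    confidence: float
    contributing_gloms: tuple[str, ...]


def aggregate_patient(preds: pd.DataFrame, top_k: int = TOP_K_GLOMERULI) -> PatientPrediction:
    """Aggregate one patient's glomerulus predictions.

    ``preds`` needs columns glom_id, patient_id, p_MCD, p_MN, p_TBMN.
    Glomeruli are ranked by max probability (descending, ties by glom_id
    ascending); the top min(top_k, n) triplets are averaged.
    """
    if len(preds) == 0:
        raise ValueError("no predictions given")
    pids = preds["patient_id"].unique()
    if len(pids) != 1:
        raise ValueError(f"mixed patient ids: {sorted(pids)}")
    prob_cols = [f"p_{c}" for c in BFE_CLASSES]
    ranked = preds.assign(_maxp=preds[prob_cols].max(axis=1)).sort_values(
        ["_maxp", "glom_id"], ascending=[False, True], kind="stable"
    )
    top = ranked.head(min(top_k, len(ranked)))
    mean_triplet = top[prob_cols].to_numpy(dtype=np.float64).mean(axis=0)
    winner = int(np.argmax(mean_triplet))
    return PatientPrediction(
        patient_id=str(pids[0]),
        probabilities=tuple(float(v) for v in mean_triplet),
        predicted=BFE_CLASSES[winner],
        confidence=float(mean_triplet[winner]),
        contributing_gloms=tuple(top["glom_id"]),
    )


def aggregate_cohort(glom_preds: pd.DataFrame, top_k: int = TOP_K_GLOMERULI) -> pd.DataFrame:
    """One aggregated prediction row per patient."""
    rows = []
    for pid, grp in glom_preds.groupby("patient_id", sort=True):
        p = aggregate_patient(grp, top_k=top_k)
        row = {"patient_id": p.patient_id, "predicted": p.predicted, "confidence": p.confidence}
        for c, v in zip(BFE_CLASSES, p.probabilities):
            row[f"p_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


def cohort_report(patient_preds: pd.DataFrame, truths: pd.DataFrame) -> dict:
    """Join predictions with truths and summarize confidence.

    ``truths`` needs columns patient_id, label.  Returns the per-patient
    table (truth, prediction, correct flag, probability triplet, confidence)
    and the cohort mean +/- sd of the predicted-class confidence.
    """
    truths = truths[["patient_id", "label"]].drop_duplicates()
    merged = patient_preds.merge(truths, on="patient_id", how="outer", indicator=True)
    if (merged["_merge"] != "both").any():
        missing = merged.loc[merged["_merge"] != "both", "patient_id"].tolist()
        raise ValueError(f"unmatched patient ids: {missing}")
    merged = merged.drop(columns="_merge").rename(columns={"label": "true"})
    merged["correct"] = merged["predicted"] == merged["true"]
    conf = merged["confidence"].to_numpy(dtype=np.float64)
    cols = ["patient_id", "true", "predicted", "correct"] + [f"p_{c}" for c in BFE_CLASSES] + ["confidence"]
    return {
        "table": merged[cols].sort_values("patient_id").reset_index(drop=True),
        "mean_confidence": float(conf.mean()),
        "sd_confidence": float(conf.std()),
        "accuracy": float(merged["correct"].mean()),
    }
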