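"""End-to-end evaluation: signals -> features -> Youth METs -> labels -> agreement.

Given a study dataset (simulated or read from CSV), this module
autocalibrates each device, summarizes every retained trial into
windowed features, derives measured Youth METs and ground-truth
intensity, classifies each trial with every cut-point set, and computes
the agreement statistics.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .agreement import (CLASS_NAMES, ConfusionMatrix, KappaResult,
                        confusion_matrix, direction_summary,
                        per_class_accuracy, weighted_kappa)
from .config import RunConfig
from .cutpoints import CutPointSet, builtin_cutpoints, classify_trial
from .energy import Intensity, label_intensity, schofield_ree, youth_mets
from .signal import CalibrationParams, TrialFeatures, autocalibrate, summarize_trial
from .synth import StudyDataset

__all__ = ["EvaluationResult", "calibrate_devices", "evaluate_dataset", "write_reports"]


@dataclass
class EvaluationResult:
    """All pipeline outputs for one dataset."""

    trials: pd.DataFrame  # one row per analyzable trial: features, METs, truth, predictions
    agreement: dict[str, KappaResult]
    confusions: dict[str, ConfusionMatrix]
    accuracy: pd.DataFrame  # cut-point set x class
    direction: dict[str, pd.DataFrame]
    calibration: dict[tuple[str, str], CalibrationParams]
    exclusions: dict[str, int]
    weighting: str
    timings: dict[str, float] = field(default_factory=dict)

    @property
    def n_analyzed(self) -> int:
        return len(self.trials)


def calibrate_devices(ds: StudyDataset) -> dict[tuple[str, str], CalibrationParams]:
    """Autocalibrate each (participant, side) device.

    Concatenates the raw signal of all non-excluded trials of a device,
    so that still periods across postures give the sphere fit enough
    orientation coverage.  Devices with too little signal keep identity
    parameters.
    """
    out: dict[tuple[str, str], CalibrationParams] = {}
    for p in ds.participants:
        for side in ("left", "right"):
            chunks = [t.raw(side) for t in ds.retained
                      if t.participant_id == p.id and t.raw(side) is not None]
            if not chunks:
                continue
            raw = np.concatenate(chunks, axis=0)
            try:
                out[(p.id, side)] = autocalibrate(raw)
            except ValueError:
                out[(p.id, side)] = CalibrationParams()
    return out


def evaluate_dataset(ds: StudyDataset, config: RunConfig | None = None,
                     cutpoint_sets: list[CutPointSet] | None = None) -> EvaluationResult:
    """Run the full evaluation pipeline on a dataset.

    Trials flagged at collection, or failing the steady-state check, are
    dropped before agreement analysis.  Raises if no analyzable trials
    remain.
    """
    cfg = config or ds.config or RunConfig()
    sets = cutpoint_sets if cutpoint_sets is not None else builtin_cutpoints()
    people = {p.id: p for p in ds.participants}
    postures = {p.code: p.posture for p in ds.profiles}
    timings: dict[str, float] = {}

    t0 = time.perf_counter()
    calibration = calibrate_devices(ds)
    timings["autocalibration_s"] = time.perf_counter() - t0

    exclusions: dict[str, int] = {}
    rows = []
    truth_labels: list[Intensity] = []
    preds: dict[str, list[Intensity]] = {s.name: [] for s in sets}
    codes: list[str] = []

    t0 = time.perf_counter()
    for trial in ds.trials:
        if trial.exclusion_flag is not None:
            exclusions[trial.exclusion_flag] = exclusions.get(trial.exclusion_flag, 0) + 1
            continue
        p = people[trial.participant_id]
        cal = {s: calibration[(p.id, s)] for s in ("left", "right")
               if (p.id, s) in calibration}
        feats: TrialFeatures = summarize_trial(trial, cal)
        if not feats.steady_state:
            exclusions["steady_state_failed"] = exclusions.get("steady_state_failed", 0) + 1
            continue
        ree = schofield_ree(p.sex, p.age, p.mass, p.height, cfg.o2_energy_kj_per_l)
        mets = youth_mets(feats.mean_vo2, p.mass, ree)
        truth = label_intensity(mets, postures[trial.activity_code])
        row = {
            "participant": p.id, "activity": trial.activity_code,
            "mean_vo2": feats.mean_vo2, "youth_mets": mets,
            "true_label": truth.name,
        }
        for side in ("left", "right"):
            for metric, d in (("va", feats.mean_va), ("vm", feats.mean_vm),
                              ("enmo", feats.mean_enmo)):
                if side in d:
                    row[f"mean_{metric}_{side}"] = d[side]
        for s in sets:
            pred = classify_trial(feats, s, p.handedness)
            preds[s.name].append(pred)
            row[f"pred_{s.name}"] = pred.name
        truth_labels.append(truth)
        codes.append(trial.activity_code)
        rows.append(row)
    timings["feature_extraction_s"] = time.perf_counter() - t0

    if not rows:
        raise ValueError("no analyzable trials: every trial was excluded")

    confusions = {}
    agreement = {}
    direction = {}
    acc_rows = []
    for s in sets:
        cm = confusion_matrix(truth_labels, preds[s.name])
        confusions[s.name] = cm
        agreement[s.name] = weighted_kappa(cm, cfg.weighting)
        direction[s.name] = direction_summary(truth_labels, preds[s.name], codes)
        acc_rows.append({"cutpoint": s.name, **per_class_accuracy(cm)})

    return EvaluationResult(
        trials=pd.DataFrame(rows),
        agreement=agreement,
        confusions=confusions,
        accuracy=pd.DataFrame(acc_rows).set_index("cutpoint"),
        direction=direction,
        calibration=calibration,
        exclusions=exclusions,
        weighting=cfg.weighting,
        timings=timings,
    )


def write_reports(result: EvaluationResult, outdir: str | Path) -> Path:
    """Write every CSV report plus a short run log to ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    kw = dict(lineterminator="\n")

    result.trials.to_csv(outdir / "features.csv", index=False,
                         float_format="%.4f", **kw)
    result.trials[["participant", "activity", "youth_mets", "true_label"]].to_csv(
        outdir / "mets.csv", index=False, float_format="%.4f", **kw)

    pred_cols = [c for c in result.trials.columns if c.startswith("pred_")]
    long = result.trials.melt(
        id_vars=["participant", "activity"], value_vars=pred_cols,
        var_name="cutpoint_name", value_name="predicted_label")
    long["cutpoint_name"] = long["cutpoint_name"].str.removeprefix("pred_")
    long.to_csv(outdir / "predictions.csv", index=False, **kw)

    pd.DataFrame([
        {"cutpoint": name, "kappa": k.kappa, "se": k.se,
         "ci_lo": k.ci95[0], "ci_hi": k.ci95[1], "weighting": k.weighting,
         "rating": k.landis_koch}
        for name, k in result.agreement.items()
    ]).to_csv(outdir / "agreement.csv", index=False, float_format="%.4f", **kw)

    for name, cm in result.confusions.items():
        df = cm.to_frame()
        row_sums = df.sum(axis=1).replace(0, np.nan)
        pct = (100.0 * df.div(row_sums, axis=0)).round(1)
        pct.columns = [f"{c}_rowpct" for c in pct.columns]
        pd.concat([df, pct], axis=1).to_csv(outdir / f"confusion_{name}.csv", **kw)

    pd.concat(
        [d.assign(cutpoint=name) for name, d in result.direction.items()]
    ).reset_index()[["cutpoint", "activity", "over", "correct", "under", "n"]].to_csv(
        outdir / "direction.csv", index=False, float_format="%.4f", **kw)

    result.accuracy.to_csv(outdir / "accuracy.csv", float_format="%.4f", **kw)

    log = [
        f"analyzed trials: {result.n_analyzed}",
        f"kappa weighting: {result.weighting}",
        "exclusions: " + (", ".join(f"{k}={v}" for k, v in sorted(result.exclusions.items()))
                          or "none"),
        "timings: " + ", ".join(f"{k}={v:.2f}" for k, v in result.timings.items()),
        "classes: " + ", ".join(CLASS_NAMES),
    ]
    (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return outdir
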