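"""Metrics and the seen / unseen / over-time evaluation protocol.

The fraud-detection operating point is judged the way biometric verifiers
are: sweep a decision threshold, record the false-negative rate (auto-walker
windows accepted as genuine) and false-positive rate (genuine windows
rejected), and summarize with the equal error rate where the two curves
cross.  Conventions, frozen here: a window is called genuine iff its score is
strictly above the threshold; each model family is swept over its own range
with 1,001 uniform grid points; the EER is linearly interpolated between the
bracketing grid points.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import confusion_matrix as _sk_confusion

from .features import feature_matrix
from .models import (
    DEFAULT_THRESHOLDS,
    BaselineModel,
    CnnHyper,
    HybridModel,
    decision_values,
    train_baseline,
    train_hybrid,
)
from .signals_io import LabeledDataset

#: decision-score sweep range per model family
THRESHOLD_RANGES = {
    "hybrid": (-2.0, 2.0),
    "svm": (-4.0, 4.0),
    "knn": (-0.25, 1.5),
    "rf": (-0.25, 1.5),
}

N_GRID = 1001


def round3(x: float) -> float:
    """Report rounding: 3 decimals, half away from zero."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def confusion_matrix(y_true: Sequence, y_pred: Sequence, classes: Sequence,
                     normalize: bool = False) -> np.ndarray:
    """Counts (or row-normalized rates) of true class x predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    outside = set(y_true) | set(y_pred)
    outside -= set(classes)
    if outside:
        raise ValueError(f"labels outside the class set: {sorted(outside)}")
    mat = _sk_confusion(y_true, y_pred, labels=list(classes))
    if normalize:
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = np.nan_to_num(mat / mat.sum(axis=1, keepdims=True))
    return mat


def precision_recall_f1(y_true: Sequence, y_pred: Sequence,
                        positive) -> tuple[float, float, float]:
    """Precision, recall and their harmonic mean for one positive class.

    With no predicted positives precision is defined as 0 (with a warning);
    F1 is 0 whenever precision + recall is 0.
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("label sequences must have equal length")
    pred_pos = y_pred == positive
    true_pos = y_true == positive
    tp = int(np.sum(pred_pos & true_pos))
    if pred_pos.sum() == 0:
        warnings.warn(f"no predicted positives for class {positive!r}; precision set to 0",
                      stacklevel=2)
        precision = 0.0
    else:
        precision = tp / int(pred_pos.sum())
    recall = tp / int(true_pos.sum()) if true_pos.sum() else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return precision, recall, f1


@dataclass
class ThresholdCurve:
    """FNR and FPR as functions of the decision threshold."""

    thresholds: np.ndarray
    fnr: np.ndarray
    fpr: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"threshold": self.thresholds, "fnr": self.fnr,
                             "fpr": self.fpr})


def fnr_fpr_curve(scores: Sequence[float], y_true: Sequence[int],
                  family: str | tuple[float, float] = "hybrid",
                  n_points: int = N_GRID) -> ThresholdCurve:
    """Sweep a uniform threshold grid over a family range.

    At each threshold t: FNR = fraction of auto-walker (label 0) scores
    strictly above t (frauds accepted); FPR = fraction of genuine (label 1)
    scores at or below t (genuine rejected).
    """
    scores = np.asarray(scores, dtype=float)
    y_true = np.asarray(y_true, dtype=int)
    if len(scores) != len(y_true):
        raise ValueError("scores and labels must align")
    if set(np.unique(y_true)) != {0, 1}:
        raise ValueError("need both genuine (1) and auto-walker (0) labels")
    lo, hi = THRESHOLD_RANGES[family] if isinstance(family, str) else family
    thresholds = np.linspace(lo, hi, n_points)
    fraud = np.sort(scores[y_true == 0])
    genuine = np.sort(scores[y_true == 1])
    # count via binary search: #(fraud > t) and #(genuine <= t)
    fnr = 1.0 - np.searchsorted(fraud, thresholds, side="right") / len(fraud)
    fpr = np.searchsorted(genuine, thresholds, side="right") / len(genuine)
    return ThresholdCurve(thresholds, fnr, fpr)


def equal_error_rate(curve: ThresholdCurve) -> tuple[float, float]:
    """The rate (and threshold) where the FNR and FPR curves cross.

    Linearly interpolates between the bracketing grid points; if the curves
    never cross inside the range, returns the grid point minimizing |FNR-FPR|
    with a warning.
    """
    d = curve.fnr - curve.fpr
    sign_change = np.flatnonzero(np.diff(np.sign(d)) != 0)
    if sign_change.size == 0:
        if np.all(d == 0):
            i = int(np.argmin(curve.fnr + curve.fpr))
            return float(curve.fnr[i]), float(curve.thresholds[i])
        warnings.warn("FNR and FPR never cross within the threshold range; "
                      "returning the closest grid point", stacklevel=2)
        i = int(np.argmin(np.abs(d)))
        return float((curve.fnr[i] + curve.fpr[i]) / 2), float(curve.thresholds[i])
    i = int(sign_change[0])
    d0, d1 = d[i], d[i + 1]
    if d0 == d1:
        alpha = 0.0
    else:
        alpha = d0 / (d0 - d1)
    eer = float(curve.fnr[i] + alpha * (curve.fnr[i + 1] - curve.fnr[i]))
    thr = float(curve.thresholds[i] + alpha * (curve.thresholds[i + 1] - curve.thresholds[i]))
    return eer, thr


@dataclass
class MetricsReport:
    """Per-model evaluation summary across protocol sections."""

    model: str
    sections: dict = field(default_factory=dict)   # section -> per-class P/R/F1, confusion, counts
    decision_ranges: dict = field(default_factory=dict)  # section -> (min, max)
    eer: float | None = None
    eer_threshold: float | None = None

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "sections": self.sections,
            "decision_ranges": {k: [round3(v[0]), round3(v[1])]
                                for k, v in self.decision_ranges.items()},
            "eer": None if self.eer is None else round3(self.eer),
            "eer_threshold": None if self.eer_threshold is None else round3(self.eer_threshold),
        }


def _section_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict:
    out: dict = {"counts": {"genuine": int(np.sum(y_true == 1)),
                            "autowalker": int(np.sum(y_true == 0))}}
    for name, positive in (("genuine", 1), ("autowalker", 0)):
        if np.sum(y_true == positive) == 0:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, r, f1 = precision_recall_f1(y_true, y_pred, positive)
        out[name] = {"precision": round3(p), "recall": round3(r), "f1": round3(f1)}
    out["confusion"] = confusion_matrix(y_true, y_pred, classes=(0, 1)).tolist()
    return out


SECTIONS = ("seen_test", "unseen_subjects", "unseen_phones", "overtime")


def run_protocol(dataset: LabeledDataset, seed: int = 0, mode: str = "preset",
                 hyper: CnnHyper | None = None, out_dir=None,
                 model_kinds: Sequence[str] = ("hybrid", "knn", "rf", "svm"),
                 features: pd.DataFrame | None = None,
                 ) -> dict[str, MetricsReport]:
    """Train every configured model and evaluate across all protocol sections.

    Sections: held-out windows of seen subjects/phones (``seen_test``), windows
    of unseen subjects (``unseen_subjects``) and unseen phones
    (``unseen_phones``), and drifted later sessions (``overtime``).  The EER is
    computed on the pooled unseen-subject + unseen-phone windows.  Feature
    extraction can be supplied precomputed; otherwise it runs here once.
    """
    hyper = hyper or CnnHyper(seed=seed)
    train = dataset.split == "train"
    if not train.any() or not (dataset.split == "test").any():
        raise ValueError("dataset needs non-empty train and test splits")
    if features is None:
        features = feature_matrix(dataset)
    y_bin = dataset.binary_labels()

    section_masks = {
        "seen_test": dataset.split == "test",
        "unseen_subjects": dataset.section == "unseen_subject",
        "unseen_phones": dataset.section == "unseen_phone",
        "overtime": dataset.section == "overtime",
    }
    eer_mask = section_masks["unseen_subjects"] | section_masks["unseen_phones"]

    models: dict[str, HybridModel | BaselineModel] = {}
    for kind in model_kinds:
        if kind == "hybrid":
            models[kind] = train_hybrid(dataset.windows[train],
                                        dataset.multiclass_labels()[train],
                                        hyper=hyper, mode=mode, seed=seed)
        else:
            models[kind] = train_baseline(features[train], y_bin[train], kind,
                                          mode=mode if kind != "rf" else "preset",
                                          seed=seed)

    reports: dict[str, MetricsReport] = {}
    for kind, model in models.items():
        inputs_all = dataset.windows if kind == "hybrid" else features
        report = MetricsReport(model=kind)
        for section, mask in section_masks.items():
            if not mask.any():
                warnings.warn(f"section {section} is empty; skipped", stacklevel=2)
                continue
            inputs = inputs_all[mask]
            scores = decision_values(model, inputs)
            y_pred = (scores > DEFAULT_THRESHOLDS[model.family]).astype(int)
            report.sections[section] = _section_metrics(y_bin[mask], y_pred)
            report.decision_ranges[section] = (float(scores.min()), float(scores.max()))
        if eer_mask.any() and len(set(y_bin[eer_mask])) == 2:
            scores = decision_values(model, inputs_all[eer_mask])
            curve = fnr_fpr_curve(scores, y_bin[eer_mask], family=model.family)
            report.eer, report.eer_threshold = equal_error_rate(curve)
            if out_dir is not None:
                curve.to_frame().to_csv(Path(out_dir) / f"curve_{kind}.csv", index=False)
        reports[kind] = report

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        payload = {k: r.to_dict() for k, r in reports.items()}
        (out_dir / "reports.json").write_text(json.dumps(payload, indent=2))
        (out_dir / "reports.md").write_text(render_markdown(reports))
    return reports


def render_markdown(reports: Mapping[str, MetricsReport]) -> str:
    lines = ["# Evaluation report", ""]
    for kind, rep in reports.items():
        lines.append(f"## {kind}")
        if rep.eer is not None:
            lines.append(f"- EER: {round3(rep.eer)} at threshold {round3(rep.eer_threshold)}")
        for section, metrics in rep.sections.items():
            lines.append(f"### {section}")
            counts = metrics["counts"]
            lines.append(f"- windows: {counts['genuine']} genuine, "
                         f"{counts['autowalker']} auto-walker")
            for cls in ("genuine", "autowalker"):
                if cls in metrics:
                    m = metrics[cls]
                    lines.append(f"- {cls}: P={m['precision']:.3f} R={m['recall']:.3f} "
                                 f"F1={m['f1']:.3f}")
            lo, hi = rep.decision_ranges[section]
            lines.append(f"- decision values in [{lo:.3f}, {hi:.3f}]")
        lines.append("")
    return "\n".join(lines)
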