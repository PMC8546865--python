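"""Negative-control precision-recall calibration of per-model hits.

Environmental hits are treated as positives and control (gut-like) hits as
labeled false positives. For each model: a precision-recall curve over its
bit scores, a PR-AUC retention gate, a minimum-data-points gate, and a score
threshold set at the smallest distinct score whose precision reaches the
precision target. Hits in the environmental table survive only if their
model was retained, their E-value beats the cutoff, and their bit score
reaches the model's threshold.

Default gates: >= 20 data points per model, PR-AUC >= 0.75, precision target
0.9999, E-value cutoff 1e-16.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .search import HitTable

ENV = "environmental"
CONTROL = "control"


@dataclass(frozen=True)
class FilterConfig:
    precision_target: float = 0.9999
    auc_min: float = 0.75
    min_points: int = 20
    evalue_max: float = 1e-16

    def __post_init__(self) -> None:
        if not 0 < self.precision_target <= 1:
            raise ValueError("precision_target must be in (0, 1]")
        if not 0 <= self.auc_min <= 1:
            raise ValueError("auc_min must be in [0, 1]")
        if self.min_points < 0 or self.evalue_max <= 0:
            raise ValueError("invalid gate settings")


@dataclass
class LabeledScores:
    model_id: str
    scores: np.ndarray  # bit scores
    labels: np.ndarray  # True = environmental (positive), False = control

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, float)
        self.labels = np.asarray(self.labels, bool)
        if self.scores.shape != self.labels.shape:
            raise ValueError("scores and labels must align")
        if self.scores.size and not np.all(np.isfinite(self.scores)):
            raise ValueError("scores must be finite")


@dataclass
class PRCurve:
    """Points (threshold, precision, recall) at each distinct score,
    thresholds descending; tied scores share a threshold."""

    thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray


@dataclass
class CalibrationResult:
    model_id: str
    n_points: int
    n_env: int
    n_control: int
    auc: float
    score_threshold: float | None
    retained: bool
    reasons: list[str] = field(default_factory=list)


def label_scores(env: HitTable, control: HitTable) -> dict[str, LabeledScores]:
    """Per-model labeled score sets from deduplicated hit tables."""
    frames = []
    for table, is_env in ((env, True), (control, False)):
        f = table.frame[["model_id", "bit_score"]].copy()
        f["label"] = is_env
        frames.append(f)
    merged = pd.concat(frames, ignore_index=True)
    out = {}
    for model_id, grp in merged.groupby("model_id", sort=True):
        out[str(model_id)] = LabeledScores(
            str(model_id), grp["bit_score"].to_numpy(), grp["label"].to_numpy()
        )
    return out


def precision_recall_curve(s: LabeledScores) -> PRCurve:
    """PR curve with environmental as positive, control as negative."""
    n_pos = int(s.labels.sum())
    if n_pos == 0:
        raise ValueError(f"model {s.model_id}: no environmental entries")
    order = np.argsort(-s.scores, kind="mergesort")
    scores = s.scores[order]
    labels = s.labels[order]
    distinct_mask = np.r_[np.diff(scores) != 0, True]  # last index of each tie group
    tp = np.cumsum(labels)[distinct_mask].astype(float)
    n_at = (np.nonzero(distinct_mask)[0] + 1).astype(float)
    thresholds = scores[distinct_mask]
    precision = tp / n_at
    recall = tp / n_pos
    return PRCurve(thresholds, precision, recall)


def pr_auc(curve: PRCurve, method: str = "trapezoid") -> float:
    """Area under the PR curve over recall.

    ``trapezoid`` (default) anchors the curve at (recall=0, precision of the
    highest-score point) and integrates trapezoidally; ``step`` is the
    average-precision alternative (right-step sum of precision x delta
    recall).
    """
    if curve.recall.size == 0:
        raise ValueError("empty curve")
    r = np.r_[0.0, curve.recall]
    if method == "trapezoid":
        p = np.r_[curve.precision[0], curve.precision]
        return float(np.trapezoid(p, r))
    if method == "step":
        return float(np.sum(np.diff(r) * curve.precision))
    raise ValueError(f"unknown AUC method {method!r}")


def score_threshold_at_precision(curve: PRCurve, precision_target: float) -> float | None:
    """Smallest distinct score whose precision meets the target (max recall
    at the required precision); None when no threshold qualifies."""
    ok = curve.precision >= precision_target
    if not ok.any():
        return None
    return float(curve.thresholds[ok][-1])


def calibrate_model(
    s: LabeledScores,
    cfg: FilterConfig = FilterConfig(),
    env_only_points: bool = False,
    auc_method: str = "trapezoid",
) -> CalibrationResult:
    """Evaluate the retention gates for one model, in order: data points,
    PR-AUC, precision threshold."""
    n_env = int(s.labels.sum())
    n_control = int(s.labels.size - n_env)
    n_points = n_env if env_only_points else int(s.labels.size)
    reasons: list[str] = []
    if n_points < cfg.min_points:
        reasons.append("min_points")
    if n_env == 0:
        return CalibrationResult(
            s.model_id, n_points, n_env, n_control, float("nan"), None, False,
            reasons + ["auc", "precision"],
        )
    curve = precision_recall_curve(s)
    auc = pr_auc(curve, method=auc_method)
    if auc < cfg.auc_min:
        reasons.append("auc")
    threshold = score_threshold_at_precision(curve, cfg.precision_target)
    if threshold is None:
        reasons.append("precision")
    retained = not reasons and threshold is not None
    return CalibrationResult(s.model_id, n_points, n_env, n_control, auc, threshold, retained, reasons)


def calibrate_all(
    labeled: Mapping[str, LabeledScores],
    cfg: FilterConfig = FilterConfig(),
    **kwargs,
) -> dict[str, CalibrationResult]:
    return {mid: calibrate_model(ls, cfg, **kwargs) for mid, ls in sorted(labeled.items())}


def calibration_report(calibrations: Mapping[str, CalibrationResult]) -> pd.DataFrame:
    rows = [
        (
            c.model_id,
            c.n_points,
            c.n_env,
            c.n_control,
            c.auc,
            c.score_threshold if c.score_threshold is not None else np.nan,
            c.retained,
            ",".join(c.reasons),
        )
        for c in calibrations.values()
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "model_id", "n_points", "n_env", "n_control", "auc",
            "score_threshold", "retained", "reasons",
        ],
    )


def filter_hits(
    env: HitTable,
    calibrations: Mapping[str, CalibrationResult],
    cfg: FilterConfig = FilterConfig(),
) -> HitTable:
    """Final hit set: model retained AND E-value < cutoff AND score >= the
    model's threshold. A hit referencing an unknown model is an error."""
    frame = env.frame
    unknown = set(frame["model_id"]) - set(calibrations)
    if unknown:
        raise KeyError(f"hits reference uncalibrated models: {sorted(unknown)[:5]}")
    retained = frame["model_id"].map(lambda m: calibrations[m].retained)
    thresholds = frame["model_id"].map(
        lambda m: calibrations[m].score_threshold
        if calibrations[m].score_threshold is not None
        else np.inf
    )
    keep = retained & (frame["evalue"] < cfg.evalue_max) & (frame["bit_score"] >= thresholds)
    out = frame[keep].reset_index(drop=True)
    return HitTable(out, {**env.provenance, "filtered": "calibrated"})


def retained_fraction(calibrations: Mapping[str, CalibrationResult]) -> float:
    if not calibrations:
        return float("nan")
    return sum(c.retained for c in calibrations.values()) / len(calibrations)
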