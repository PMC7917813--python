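"""Evaluation: confusion counts, precision/recall/F1/accuracy and the
per-scenario report.

The drowsiness label is the instantaneous eye state: a closed-eye frame is
drowsy.  Reports list one row per recording scenario plus an unweighted
"Average" row, with the drowsy-as-positive and non-drowsy-as-positive F1
scores and per-feature-path accuracies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ParameterError
from .synth import SCENARIOS

logger = logging.getLogger(__name__)

DISPLAY_NAMES = {
    "bareface": "Bareface",
    "glasses": "Glasses",
    "sunglasses": "Sunglasses",
    "night_bareface": "Night-BareFace",
    "night_glasses": "Night-Glasses",
}

#: label treated as drowsy (positive) by default
DROWSY_LABEL = "closed"


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class Metrics:
    precision: float
    recall: float
    f1: float
    accuracy: float


@dataclass(frozen=True)
class ScenarioRow:
    scenario: str
    drowsy_f1: dict[str, float]  # per feature path
    nondrowsy_f1: dict[str, float]
    accuracy: dict[str, float]
    n: int


@dataclass(frozen=True)
class EvalReport:
    rows: list[ScenarioRow]
    average: ScenarioRow
    paths: list[str]


def confusion_counts(pred: Sequence, truth: Sequence, positive) -> ConfusionCounts:
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape or pred.size < 1:
        raise ParameterError(f"prediction/truth length mismatch: {pred.shape} vs {truth.shape}")
    p = pred == positive
    t = truth == positive
    return ConfusionCounts(
        tp=int((p & t).sum()), fp=int((p & ~t).sum()),
        tn=int((~p & ~t).sum()), fn=int((~p & t).sum()),
    )


def _safe_div(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("zero denominator computing %s; reporting 0", name)
        return 0.0
    return num / den


def metrics(c: ConfusionCounts) -> Metrics:
    """Precision, recall, F1 and accuracy; zero denominators yield 0."""
    if c.total < 1:
        raise ParameterError("confusion counts are all zero")
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    f1 = _safe_div(2.0 * precision * recall, precision + recall, "F1")
    accuracy = (c.tp + c.tn) / c.total
    return Metrics(precision, recall, f1, accuracy)


def scenario_report(
    scenarios: Sequence[str],
    truth: Sequence,
    predictions: Mapping[str, Sequence],
    positive=DROWSY_LABEL,
    negative: str = "open",
) -> EvalReport:
    """Per-scenario F1/accuracy for each feature path plus the average row.

    ``predictions`` maps feature-path names (e.g. ``"hog"``, ``"bosh"``) to
    predicted label sequences aligned with ``truth`` and ``scenarios``.
    """
    scenarios = list(scenarios)
    truth = np.asarray(truth)
    unknown = set(scenarios) - set(SCENARIOS)
    if unknown:
        raise ParameterError(f"unknown scenario tags {sorted(unknown)}")
    paths = list(predictions)
    preds = {p: np.asarray(v) for p, v in predictions.items()}
    for p, v in preds.items():
        if len(v) != len(truth):
            raise ParameterError(f"path {p!r}: {len(v)} predictions for {len(truth)} samples")

    tags = np.asarray(scenarios)
    rows = []
    for sc in (s for s in SCENARIOS if s in set(scenarios)):
        sel = tags == sc
        drowsy, nondrowsy, acc = {}, {}, {}
        for p in paths:
            c_pos = confusion_counts(preds[p][sel], truth[sel], positive)
            c_neg = confusion_counts(preds[p][sel], truth[sel], negative)
            drowsy[p] = metrics(c_pos).f1
            nondrowsy[p] = metrics(c_neg).f1
            acc[p] = metrics(c_pos).accuracy
        rows.append(ScenarioRow(sc, drowsy, nondrowsy, acc, int(sel.sum())))

    avg = ScenarioRow(
        scenario="average",
        drowsy_f1={p: float(np.mean([r.drowsy_f1[p] for r in rows])) for p in paths},
        nondrowsy_f1={p: float(np.mean([r.nondrowsy_f1[p] for r in rows])) for p in paths},
        accuracy={p: float(np.mean([r.accuracy[p] for r in rows])) for p in paths},
        n=sum(r.n for r in rows),
    )
    return EvalReport(rows=rows, average=avg, paths=paths)


def _report_cells(report: EvalReport, f1_path: str) -> list[list[str]]:
    header = ["Scenario", "Drowsiness F1-Score (%)", "Non-Drowsiness F1-Score (%)"]
    header += [f"{p} AC (%)" for p in report.paths]
    out = [header]
    for row in report.rows + [report.average]:
        name = DISPLAY_NAMES.get(row.scenario, "Average")
        cells = [name, f"{100 * row.drowsy_f1[f1_path]:.2f}", f"{100 * row.nondrowsy_f1[f1_path]:.2f}"]
        cells += [f"{100 * row.accuracy[p]:.2f}" for p in report.paths]
        out.append(cells)
    return out


def render_csv(report: EvalReport, f1_path: str | None = None) -> str:
    f1_path = f1_path or report.paths[-1]
    return "\n".join(",".join(r) for r in _report_cells(report, f1_path)) + "\n"


def render_text(report: EvalReport, f1_path: str | None = None) -> str:
    """Aligned plain-text table in the per-scenario report layout."""
    f1_path = f1_path or report.paths[-1]
    cells = _report_cells(report, f1_path)
    widths = [max(len(r[i]) for r in cells) for i in range(len(cells[0]))]
    lines = []
    for r in cells:
        lines.append("  ".join(v.ljust(w) for v, w in zip(r, widths)).rstrip())
    return "\n".join(lines) + "\n"
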