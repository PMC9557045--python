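"""Ground-truth-best determination and accuracy scoring.

Accuracy compares the size predicted from reconstructed geometry with the
"ground-truth best" size — the chart entry with the lowest metric value when
fitted to the subject's true 3D bone — exactly matched and within +/- 1
chart ordinal.  Over/underhang above 3 mm is treated as clinically
significant, so the report also tracks the percentage of subjects kept
under that threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .geometry import GeometryError, Mesh3D
from .fitting import SizePrediction, predict_sizes
from .implants import SizeChart

__all__ = [
    "OVERHANG_SIGNIFICANT_MM",
    "ReportRow",
    "EvaluationReport",
    "ground_truth_best",
    "score_predictions",
]

OVERHANG_SIGNIFICANT_MM = 3.0

_METRIC_ATTR = {"rmse": "best_by_rmse", "max_ouh": "best_by_ouh"}


def ground_truth_best(gt_mesh_or_meshes, chart: SizeChart) -> SizePrediction:
    """Best size per metric on the ground-truth geometry.

    Runs the identical fitting-engine evaluation (same metrics, same
    downsize tie-break) on the true mesh.  Accepts a single mesh (routed by
    the chart's component) or a ``{"femur": ..., "tibia": ...}`` mapping.
    """
    if isinstance(gt_mesh_or_meshes, Mesh3D):
        meshes = {chart.component: gt_mesh_or_meshes}
    else:
        meshes = dict(gt_mesh_or_meshes)
    (prediction,) = predict_sizes(
        meshes.get("femur"), meshes.get("tibia"), [chart]
    )
    return prediction


@dataclass
class ReportRow:
    """Scores for one (manufacturer, model, component) chart under one
    selection metric ("rmse" or "max_ouh")."""

    manufacturer: str
    model: str
    component: str
    metric: str
    n: int
    accuracy_pct: float
    accuracy_pm1_pct: float
    mean_gt_best_rmse: float
    mean_pred_rmse: float
    mean_gt_best_ouh: float
    mean_pred_ouh: float
    pct_under_3mm_gt: float
    pct_under_3mm_pred: float
    spearman_rho_vs_age: float
    accuracy_by_sex: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("accuracy_pct", "accuracy_pm1_pct"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise GeometryError(f"{name} must be in [0, 100]")
        if self.accuracy_pm1_pct + 1e-9 < self.accuracy_pct:
            raise GeometryError("accuracy_pm1_pct must be >= accuracy_pct")


@dataclass
class EvaluationReport:
    n_subjects: int
    rows: list

    def to_dict(self) -> dict:
        return {
            "n_subjects": self.n_subjects,
            "rows": [
                {
                    **{k: getattr(r, k) for k in (
                        "manufacturer", "model", "component", "metric", "n",
                        "accuracy_pct", "accuracy_pm1_pct",
                        "mean_gt_best_rmse", "mean_pred_rmse",
                        "mean_gt_best_ouh", "mean_pred_ouh",
                        "pct_under_3mm_gt", "pct_under_3mm_pred",
                        "spearman_rho_vs_age",
                    )},
                    "accuracy_by_sex": dict(r.accuracy_by_sex),
                }
                for r in self.rows
            ],
        }


def _subject_field(subject, name):
    if isinstance(subject, dict):
        return subject[name]
    return getattr(subject, name)


def _fit_lookup(prediction: SizePrediction) -> dict:
    return {f.size_id: f for f in prediction.all_fits}


def _spearman(correct: np.ndarray, ages: np.ndarray) -> float:
    """Spearman rank correlation with midrank ties; NaN when either input
    is constant (correlation undefined)."""
    if len(correct) < 2 or np.ptp(correct) == 0 or np.ptp(ages) == 0:
        return float("nan")
    return float(stats.spearmanr(correct, ages).statistic)


def score_predictions(
    preds: list,
    gts: list,
    charts: list,
    subjects: list,
) -> EvaluationReport:
    """Score per-subject size predictions against ground-truth bests.

    ``preds`` and ``gts`` are per-subject lists of :class:`SizePrediction`
    (``gts`` computed on ground-truth geometry); ``subjects`` provide age
    and sex.  All metric means are evaluated on the ground-truth geometry:
    the predicted size's fit values are looked up in the ground-truth fits.
    """
    if not (len(preds) == len(gts) == len(subjects)):
        raise GeometryError(
            f"subject mismatch: {len(preds)} predictions, {len(gts)} "
            f"ground truths, {len(subjects)} subjects"
        )
    if not preds:
        raise GeometryError("no subjects to score")

    ages = np.array([float(_subject_field(s, "age")) for s in subjects])
    sexes = [str(_subject_field(s, "sex")) for s in subjects]

    def key(p):
        return (p.manufacturer, p.model, p.component)

    rows = []
    for chart in charts:
        k = (chart.manufacturer, chart.model, chart.component)
        ordinals = {e.size_id: e.ordinal for e in chart.entries}
        per_subject = []
        for i, (p_list, g_list) in enumerate(zip(preds, gts)):
            p_match = [p for p in p_list if key(p) == k]
            g_match = [g for g in g_list if key(g) == k]
            if len(p_match) != 1 or len(g_match) != 1:
                raise GeometryError(
                    f"subject {i}: expected exactly one prediction and one "
                    f"ground truth for chart {k}"
                )
            per_subject.append((i, p_match[0], g_match[0]))

        for metric in ("rmse", "max_ouh"):
            attr = _METRIC_ATTR[metric]
            correct, pm1 = [], []
            pred_rmse, pred_ouh, gt_rmse, gt_ouh = [], [], [], []
            under_gt, under_pred = [], []
            sex_hits: dict = {}
            for i, p, g in per_subject:
                pred_id = getattr(p, attr)
                gt_id = getattr(g, attr)
                diff = abs(ordinals[pred_id] - ordinals[gt_id])
                correct.append(diff == 0)
                pm1.append(diff <= 1)
                sex_hits.setdefault(sexes[i], []).append(diff == 0)

                fits = _fit_lookup(g)
                gt_fit = fits[gt_id]
                gt_rmse.append(gt_fit.rmse)
                gt_ouh.append(gt_fit.max_ouh)
                under_gt.append(gt_fit.max_ouh < OVERHANG_SIGNIFICANT_MM)
                pred_fit = fits.get(pred_id)
                if pred_fit is None:
                    # predicted size failed to fit on the gt geometry: count
                    # it as exceeding the overhang threshold
                    pred_rmse.append(np.nan)
                    pred_ouh.append(np.nan)
                    under_pred.append(False)
                else:
                    pred_rmse.append(pred_fit.rmse)
                    pred_ouh.append(pred_fit.max_ouh)
                    under_pred.append(pred_fit.max_ouh < OVERHANG_SIGNIFICANT_MM)

            n = len(correct)
            rows.append(
                ReportRow(
                    manufacturer=chart.manufacturer,
                    model=chart.model,
                    component=chart.component,
                    metric=metric,
                    n=n,
                    accuracy_pct=100.0 * np.mean(correct),
                    accuracy_pm1_pct=100.0 * np.mean(pm1),
                    mean_gt_best_rmse=float(np.mean(gt_rmse)),
                    mean_pred_rmse=float(np.nanmean(pred_rmse)),
                    mean_gt_best_ouh=float(np.mean(gt_ouh)),
                    mean_pred_ouh=float(np.nanmean(pred_ouh)),
                    pct_under_3mm_gt=100.0 * np.mean(under_gt),
                    pct_under_3mm_pred=100.0 * np.mean(under_pred),
                    spearman_rho_vs_age=_spearman(
                        np.asarray(correct, dtype=float), ages
                    ),
                    accuracy_by_sex={
                        s: 100.0 * float(np.mean(h)) for s, h in sorted(sex_hits.items())
                    },
                )
            )
    if not rows:
        raise GeometryError("no charts to score")
    return EvaluationReport(n_subjects=len(subjects), rows=rows)
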