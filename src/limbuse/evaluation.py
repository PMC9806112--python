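"""Evaluation of use detectors against annotated ground truth.

Every measure emits a binary use signal at its own rate (1, 2 or 4 Hz);
evaluation aligns it to the 50 Hz consensus annotation grid by zero-order
hold and accumulates sample-wise confusion counts, from which sensitivity,
specificity and the Youden index (J = sensitivity + specificity - 1) are
derived. The module also hosts the group-level statistics (one-way ANOVA
with Bonferroni-corrected pairwise Welch t-tests), Spearman correlation of
window features against the interpretable quantities used by the
traditional measures, the sensitivity/specificity-vs-class-proportion
regression, and the task presence/absence ablation of the intra-subject
random-forest detector.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.model_selection import StratifiedKFold

from .data_model import UseSignal, ValidationError
from .ml import FEATURE_NAMES, _grid_select, _make_model

__all__ = [
    "MeasureEvaluation",
    "AblationResult",
    "confusion",
    "youden",
    "evaluate_use",
    "compare_measure_groups",
    "feature_correlates",
    "proportion_regression",
    "task_ablation",
    "ABLATION_CONDITIONS",
]

ABLATION_CONDITIONS = ("tr.te", "notr.te", "tr.note", "notr.note")


@dataclass
class MeasureEvaluation:
    """Confusion counts and derived metrics for one subject/arm/measure."""

    subject: str
    arm: str
    measure: str
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else np.nan

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass
class AblationResult:
    """Sensitivity/specificity for one task x train/test composition."""

    task: str
    condition: str  # one of ABLATION_CONDITIONS
    sensitivity: float
    specificity: float


def confusion(use: UseSignal, gt_timestamps, gt_values
              ) -> tuple[int, int, int, int]:
    """Sample-wise (tp, fp, tn, fn) of a use signal against ground truth.

    The use signal is upsampled onto the ground-truth grid by zero-order
    hold; only ground-truth samples inside the use signal's span (first
    stamp to last stamp + one period) are counted.
    """
    gt_t = np.asarray(gt_timestamps, dtype=float)
    gt_v = np.asarray(gt_values, dtype=int)
    if len(gt_t) != len(gt_v):
        raise ValidationError("ground-truth timestamps/values lengths differ")
    t0 = use.timestamps[0]
    t1 = use.timestamps[-1] + 1.0 / use.rate
    in_span = (gt_t >= t0 - 1e-9) & (gt_t < t1 - 1e-9)
    if not in_span.any():
        raise ValidationError("use signal and ground truth do not overlap")
    sel_t, sel_gt = gt_t[in_span], gt_v[in_span]
    idx = np.searchsorted(use.timestamps, sel_t + 1e-12, side="right") - 1
    idx = np.clip(idx, 0, len(use) - 1)
    pred = use.values[idx]
    tp = int(((sel_gt == 1) & (pred == 1)).sum())
    fp = int(((sel_gt == 0) & (pred == 1)).sum())
    tn = int(((sel_gt == 0) & (pred == 0)).sum())
    fn = int(((sel_gt == 1) & (pred == 0)).sum())
    return tp, fp, tn, fn


def youden(sensitivity: float, specificity: float) -> float:
    """Youden index J = sensitivity + specificity - 1.

    1 for a perfect classifier, 0 for a chance-level one, -1 when every
    decision is wrong.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValidationError("sensitivity and specificity must be in [0, 1]")
    return sensitivity + specificity - 1.0


def evaluate_use(use: UseSignal, gt_timestamps, gt_values, *,
                 subject: str = "", arm: str = "", measure: str = ""
                 ) -> MeasureEvaluation:
    """Convenience wrapper: confusion counts packed as a MeasureEvaluation."""
    tp, fp, tn, fn = confusion(use, gt_timestamps, gt_values)
    return MeasureEvaluation(subject, arm, measure, tp, fp, tn, fn)


def compare_measure_groups(groups: dict[str, np.ndarray]):
    """One-way ANOVA across measure families plus pairwise Welch t-tests.

    Returns ``(F, p, pairwise)`` where ``pairwise`` maps ``(name_a,
    name_b)`` to the Bonferroni-adjusted p-value (raw p times the number
    of pairs, clipped at 1).
    """
    cleaned = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, vals in cleaned.items():
        if len(vals) < 2:
            raise ValidationError(f"group {name!r} needs at least 2 values")
    f_stat, p = stats.f_oneway(*cleaned.values())
    pairs = list(combinations(cleaned, 2))
    pairwise = {}
    for a, b in pairs:
        _, raw = stats.ttest_ind(cleaned[a], cleaned[b], equal_var=False)
        pairwise[(a, b)] = min(1.0, float(raw) * len(pairs))
    return float(f_stat), float(p), pairwise


def feature_correlates(features: pd.DataFrame, variables: pd.DataFrame
                       ) -> pd.DataFrame:
    """Spearman rho for every (feature, variable) pair over aligned windows.

    ``variables`` carries interpretable per-window quantities (mean pitch,
    yaw range, activity counts). Pairs with a constant column get NaN.
    """
    if len(features) != len(variables):
        raise ValidationError("features and variables must have equal rows")
    out = pd.DataFrame(index=features.columns, columns=variables.columns,
                       dtype=float)
    for f in features.columns:
        for v in variables.columns:
            x, y = features[f].to_numpy(), variables[v].to_numpy()
            if np.std(x) == 0 or np.std(y) == 0:
                out.loc[f, v] = np.nan
            else:
                out.loc[f, v] = stats.spearmanr(x, y).statistic
    return out


def proportion_regression(pct_functional, sensitivities, specificities):
    """OLS of per-subject sensitivity and specificity on % functional data.

    Returns a dict with slope and slope p-value for each response.
    """
    x = np.asarray(pct_functional, dtype=float)
    if len(x) < 3:
        raise ValidationError("regression needs at least 3 subjects")
    design = sm.add_constant(x)
    out = {}
    for name, y in (("sensitivity", sensitivities),
                    ("specificity", specificities)):
        fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
        out[name] = {"slope": float(fit.params[1]),
                     "p_value": float(fit.pvalues[1])}
    return out


def task_ablation(table: pd.DataFrame, task: str, *, model: str = "rf",
                  folds: int = 5, seed: int = 0, grid=None,
                  inner_folds: int = 2) -> list[AblationResult]:
    """Effect of a task's presence/absence in train and test sets.

    For each of the four compositions (task in both, only in test, only in
    train, in neither), an intra-subject stratified CV is run where the
    task's windows are dropped from the training and/or test side of each
    fold. Windows labelled ``unknown`` (inter-task segments) are excluded
    throughout. Returns one pooled AblationResult per condition.
    """
    if "task" not in table.columns:
        raise ValidationError("table has no task column")
    work = table[table["task"] != "unknown"].reset_index(drop=True)
    is_task = (work["task"] == task).to_numpy()
    if not is_task.any():
        raise ValidationError(f"task {task!r} absent from the table")
    feats = [f for f in FEATURE_NAMES if f in work.columns]
    X = work[feats].to_numpy(dtype=float)
    y = work["label"].to_numpy(dtype=int)
    grid = grid if grid is not None else [{}]
    results = []
    for cond in ABLATION_CONDITIONS:
        keep_train = "notr" not in cond
        keep_test = "note" not in cond
        conf = np.zeros(4, dtype=int)  # tp, fp, tn, fn
        outer = StratifiedKFold(n_splits=folds, shuffle=True,
                                random_state=seed)
        for tr, te in outer.split(X, y):
            if not keep_train:
                tr = tr[~is_task[tr]]
            if not keep_test:
                te = te[~is_task[te]]
            if len(np.unique(y[tr])) < 2 or len(te) == 0:
                continue
            params, _ = _grid_select(X, y, tr, model, grid, inner_folds, seed)
            clf = _make_model(model, params, seed)
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
            conf[0] += int(((y[te] == 1) & (pred == 1)).sum())
            conf[1] += int(((y[te] == 0) & (pred == 1)).sum())
            conf[2] += int(((y[te] == 0) & (pred == 0)).sum())
            conf[3] += int(((y[te] == 1) & (pred == 0)).sum())
        tp, fp, tn, fn = conf
        sens = tp / (tp + fn) if tp + fn else np.nan
        spec = tn / (tn + fp) if tn + fp else np.nan
        results.append(AblationResult(task=task, condition=cond,
                                      sensitivity=sens, specificity=spec))
    return results
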