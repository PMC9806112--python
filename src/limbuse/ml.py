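"""Machine-learning upper-limb-use detectors.

Non-overlapping 0.25 s windows of 50 Hz triaxial acceleration are reduced
to eleven features (per-axis mean and variance, plus mean, variance,
minimum, maximum and kernel-density Shannon entropy of the per-sample
2-norm) and classified as functional / non-functional use with a random
forest, a class-weighted RBF SVM, or a two-hidden-layer MLP.

Two validation schemes mirror common practice in wearable-sensor studies:
*intra-subject* (stratified 5-fold cross-validation on one subject's
windows, repeated over shuffles) and *inter-subject* (leave-one-subject-
out). Hyper-parameters are chosen by nested cross-validation: an inner
stratified CV on the outer-training rows only. Every result records the
row indices that hyper-parameter selection touched, so leakage into the
outer test fold can be asserted rather than assumed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import NotFittedError
from sklearn.model_selection import StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .data_model import ImuRecording, ValidationError

__all__ = [
    "FEATURE_NAMES",
    "FEATURE_SUBSETS",
    "CvResult",
    "entropy_kde",
    "extract_features",
    "build_window_table",
    "train_eval_intra",
    "train_eval_inter",
    "gini_importances",
    "reduced_model_eval",
    "DEFAULT_GRIDS",
]

FEATURE_NAMES = [
    "mean_ax", "mean_ay", "mean_az",
    "var_ax", "var_ay", "var_az",
    "mean_norm", "var_norm", "min_norm", "max_norm", "entropy_norm",
]

#: Optional gyroscope features (off by default: they add no detection
#: power over the accelerometer set but widen the table).
GYRO_FEATURE_NAMES = ["mean_gx", "mean_gy", "mean_gz",
                      "var_gx", "var_gy", "var_gz"]

#: Reduced feature sets used to probe what the classifier relies on.
FEATURE_SUBSETS = {
    "mean_ax": ["mean_ax"],
    "means": ["mean_ax", "mean_ay", "mean_az"],
    "means_vars": ["mean_ax", "mean_ay", "mean_az",
                   "var_ax", "var_ay", "var_az"],
    "full": list(FEATURE_NAMES),
}

DEFAULT_GRIDS = {
    "rf": [{"n_estimators": n} for n in (10, 50, 100, 200)],
    "svm": [{"C": c, "gamma": g}
            for c in (0.1, 1.0, 10.0, 100.0)
            for g in (0.001, 0.01, 0.1, 1.0)],
    "mlp": [{}],  # fixed architecture, nothing to search
}


@dataclass
class CvResult:
    """Outcome of one outer fold (intra) or one held-out subject (inter)."""

    scheme: str
    model: str
    iteration: int
    fold: int | str
    sensitivity: float
    specificity: float
    youden: float
    params: dict
    n_test: int
    test_indices: np.ndarray = field(repr=False, default=None)
    selection_indices: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# Features

def entropy_kde(values, bandwidth: float = 0.2) -> float:
    """Shannon entropy of a Gaussian kernel-density estimate (nats).

    The density is estimated at the sample points themselves with an
    absolute bandwidth (not scaled by the sample spread):
    ``H = -(1/n) sum_i log p_hat(x_i)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValidationError("entropy needs at least 2 values")
    diff = (x[:, None] - x[None, :]) / bandwidth
    kern = np.exp(-0.5 * diff ** 2) / (np.sqrt(2.0 * np.pi) * bandwidth)
    p_hat = kern.mean(axis=1)
    return float(-np.mean(np.log(p_hat)))


def extract_features(window, bandwidth: float = 0.2) -> np.ndarray:
    """Eleven accelerometer features from one (k, 3) window in g.

    Order follows :data:`FEATURE_NAMES`. Variances are population
    variances (divide by k): the window is the population of interest,
    not a sample from one.
    """
    w = np.asarray(window, dtype=float)
    if w.ndim != 2 or w.shape[1] != 3 or w.shape[0] < 2:
        raise ValidationError("window must be (k, 3) with k >= 2")
    norms = np.linalg.norm(w, axis=1)
    return np.array([
        w[:, 0].mean(), w[:, 1].mean(), w[:, 2].mean(),
        w[:, 0].var(), w[:, 1].var(), w[:, 2].var(),
        norms.mean(), norms.var(), norms.min(), norms.max(),
        entropy_kde(norms, bandwidth),
    ])


def build_window_table(recording: ImuRecording, gt, window_s: float = 0.25,
                       *, subject: str | None = None, arm: str | None = None,
                       task_track=None, include_gyro: bool = False
                       ) -> pd.DataFrame:
    """Tile a recording into non-overlapping windows and featurize them.

    ``gt`` is the binary consensus ground truth on the recording's own
    sample grid; the window label is the ground-truth sample at the window
    centre (start + window/2, zero-order hold). A trailing partial window
    is dropped. Windows are time bins of ``window_s`` seconds, so at 50 Hz
    a 0.25 s window alternates between 12 and 13 samples.

    Returns a DataFrame with the 11 feature columns, ``label``,
    ``t_start`` and, when provided, ``subject``/``arm``/``task`` columns.
    With ``include_gyro`` the per-axis gyroscope mean/variance columns
    are appended as well.
    """
    gt = np.asarray(gt)
    n = len(recording)
    if len(gt) != n:
        raise ValidationError("ground truth must be on the recording grid")
    rate = recording.nominal_rate
    samples_per = window_s * rate
    n_win = int(np.floor(n / samples_per + 1e-9))
    if n_win == 0:
        raise ValidationError("record shorter than one feature window")
    rows = np.empty((n_win, len(FEATURE_NAMES)))
    gyro_rows = np.empty((n_win, len(GYRO_FEATURE_NAMES)))
    labels = np.empty(n_win, dtype=int)
    starts = np.empty(n_win)
    tasks = []
    for i in range(n_win):
        lo = int(np.floor(i * samples_per + 1e-9))
        hi = int(np.floor((i + 1) * samples_per + 1e-9))
        rows[i] = extract_features(recording.accel[lo:hi])
        if include_gyro:
            gw = recording.gyro[lo:hi]
            gyro_rows[i] = np.concatenate([gw.mean(axis=0), gw.var(axis=0)])
        centre = lo + int(np.floor(samples_per / 2.0))
        labels[i] = int(gt[min(centre, n - 1)])
        starts[i] = recording.timestamps[lo]
        if task_track is not None:
            tasks.append(task_track[min(centre, n - 1)])
    table = pd.DataFrame(rows, columns=FEATURE_NAMES)
    if include_gyro:
        table[GYRO_FEATURE_NAMES] = gyro_rows
    table["label"] = labels
    table["t_start"] = starts
    if subject is not None:
        table["subject"] = subject
    if arm is not None:
        table["arm"] = arm
    if task_track is not None:
        table["task"] = tasks
    return table


# ---------------------------------------------------------------------------
# Models and nested cross-validation

def _make_model(name: str, params: dict, seed: int):
    if name == "rf":
        return RandomForestClassifier(random_state=seed, n_jobs=1,
                                      **{"n_estimators": 100, **params})
    if name == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", class_weight="balanced",
                        random_state=seed, **params)),
        ])
    if name == "mlp":
        return Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(hidden_layer_sizes=(32, 16),
                                  max_iter=500, random_state=seed,
                                  **params)),
        ])
    raise ValueError(f"unknown model {name!r}")


def _confusion_metrics(y_true, y_pred) -> tuple[float, float, float]:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    tp = int(((y_true == 1) & (y_pred == 1)).sum())
    fn = int(((y_true == 1) & (y_pred == 0)).sum())
    tn = int(((y_true == 0) & (y_pred == 0)).sum())
    fp = int(((y_true == 0) & (y_pred == 1)).sum())
    sens = tp / (tp + fn) if tp + fn else np.nan
    spec = tn / (tn + fp) if tn + fp else np.nan
    return sens, spec, sens + spec - 1.0


def _grid_select(X, y, train_idx, model_name, grid, inner_folds, seed):
    """Inner nested CV over the outer-training rows only.

    Returns (best params, row indices touched during selection).
    """
    if len(grid) == 1:
        return grid[0], np.array([], dtype=int)
    y_tr = y[train_idx]
    n_splits = min(inner_folds, int(np.bincount(y_tr).min()))
    if n_splits < 2:
        return grid[0], np.array([], dtype=int)
    inner = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
    best, best_score = grid[0], -np.inf
    touched: set[int] = set()
    for params in grid:
        scores = []
        for tr, va in inner.split(X[train_idx], y_tr):
            rows_tr, rows_va = train_idx[tr], train_idx[va]
            touched.update(rows_tr.tolist())
            touched.update(rows_va.tolist())
            clf = _make_model(model_name, params, seed)
            clf.fit(X[rows_tr], y[rows_tr])
            _, _, j = _confusion_metrics(y[rows_va], clf.predict(X[rows_va]))
            scores.append(j)
        score = float(np.nanmean(scores))
        if score > best_score:
            best, best_score = params, score
    return best, np.array(sorted(touched), dtype=int)


def train_eval_intra(table: pd.DataFrame, model: str = "rf", folds: int = 5,
                     iterations: int = 10, seed: int = 0, grid=None,
                     inner_folds: int | None = None,
                     features=None) -> list[CvResult]:
    """Intra-subject protocol: repeated stratified k-fold with nested search.

    ``table`` holds one subject+arm's windows. Per iteration, an outer
    stratified split is drawn; hyper-parameters are selected by inner CV
    on each outer-training set, the model refit on it and scored on the
    outer-test fold. Returns ``iterations * folds`` results.
    """
    features = list(features) if features is not None else list(FEATURE_NAMES)
    unknown = [f for f in features if f not in table.columns]
    if unknown:
        raise ValidationError(f"unknown feature columns: {unknown}")
    X = table[features].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=int)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValidationError(
            "single-class table: both use and non-use windows are required")
    grid = grid if grid is not None else DEFAULT_GRIDS[model]
    inner_folds = inner_folds if inner_folds is not None else max(2, folds - 1)
    results = []
    for it in range(iterations):
        it_seed = seed + 1000 * it
        outer = StratifiedKFold(n_splits=folds, shuffle=True,
                                random_state=it_seed)
        for k, (tr, te) in enumerate(outer.split(X, y)):
            params, touched = _grid_select(X, y, tr, model, grid,
                                           inner_folds, it_seed)
            clf = _make_model(model, params, it_seed)
            clf.fit(X[tr], y[tr])
            sens, spec, j = _confusion_metrics(y[te], clf.predict(X[te]))
            results.append(CvResult(
                scheme="intra", model=model, iteration=it, fold=k,
                sensitivity=sens, specificity=spec, youden=j, params=params,
                n_test=len(te), test_indices=te, selection_indices=touched))
    return results


def train_eval_inter(tables: dict[str, pd.DataFrame], model: str = "rf",
                     seed: int = 0, grid=None, inner_folds: int = 4,
                     features=None) -> list[CvResult]:
    """Inter-subject protocol: leave-one-subject-out with nested search."""
    if len(tables) < 3:
        raise ValidationError("inter-subject evaluation needs >= 3 subjects")
    features = list(features) if features is not None else list(FEATURE_NAMES)
    grid = grid if grid is not None else DEFAULT_GRIDS[model]
    subjects = list(tables)
    stacked = pd.concat([tables[s].assign(_subj=s) for s in subjects],
                        ignore_index=True)
    X = stacked[features].to_numpy(dtype=float)
    y = stacked["label"].to_numpy(dtype=int)
    subj_col = stacked["_subj"].to_numpy()
    results = []
    for held_out in subjects:
        te = np.flatnonzero(subj_col == held_out)
        tr = np.flatnonzero(subj_col != held_out)
        params, touched = _grid_select(X, y, tr, model, grid, inner_folds, seed)
        clf = _make_model(model, params, seed)
        clf.fit(X[tr], y[tr])
        sens, spec, j = _confusion_metrics(y[te], clf.predict(X[te]))
        results.append(CvResult(
            scheme="inter", model=model, iteration=0, fold=held_out,
            sensitivity=sens, specificity=spec, youden=j, params=params,
            n_test=len(te), test_indices=te, selection_indices=touched))
    return results


def gini_importances(fitted_rf) -> list[tuple[str, float]]:
    """Gini (impurity-reduction) importances, descending; they sum to 1."""
    rf = fitted_rf
    try:
        check_is_fitted(rf)
    except NotFittedError as exc:
        raise ValidationError("random forest must be fitted first") from exc
    imp = rf.feature_importances_
    names = (list(rf.feature_names_in_) if hasattr(rf, "feature_names_in_")
             else FEATURE_NAMES[:len(imp)])
    order = np.argsort(imp)[::-1]
    return [(names[i], float(imp[i])) for i in order]


def reduced_model_eval(table, subsets=None, model: str = "rf",
                       scheme: str = "intra", **kwargs
                       ) -> dict[str, list[CvResult]]:
    """Run the CV protocol on reduced feature subsets.

    ``subsets`` maps subset name -> feature list; defaults to the four
    canonical subsets (1, 3, 6 and all 11 features). ``table`` is a single
    table for ``scheme='intra'`` or a subject->table dict for ``'inter'``.
    """
    subsets = subsets if subsets is not None else FEATURE_SUBSETS
    for name, feats in subsets.items():
        bad = [f for f in feats if f not in FEATURE_NAMES]
        if bad:
            raise ValidationError(f"unknown subset feature(s) in {name!r}: {bad}")
    out = {}
    for name, feats in subsets.items():
        if scheme == "intra":
            out[name] = train_eval_intra(table, model=model, features=feats,
                                         **kwargs)
        elif scheme == "inter":
            out[name] = train_eval_inter(table, model=model, features=feats,
                                         **kwargs)
        else:
            raise ValueError(f"unknown scheme {scheme!r}")
    return out
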