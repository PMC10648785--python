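"""Stratified cross-validated model comparison, metrics, ROC and DeLong.

Five classifier families are compared: logistic regression (LR), Gaussian
naive Bayes (NB), random forest (RF), support vector classification
(SVC, with calibrated probability output) and gradient-boosted trees
(XGB).  Each model is evaluated by stratified k-fold cross-validation
(default k = 5): within each fold the min-max normalizer is fitted on the
training rows only, the training rows are rebalanced (SMOTE by default),
and the untouched test rows are scored.  Threshold metrics use the 0.5
cutoff; AUC is the Mann-Whitney statistic of the scores with tie
correction.  Paired model AUCs are compared with the DeLong test for
correlated ROC curves on the pooled out-of-fold scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC
from xgboost import XGBClassifier

from .resampling import SmoteConfig, rebalance
from .tabular import DesignMatrix, MinMaxNormalizer

log = logging.getLogger(__name__)

__all__ = [
    "MODEL_NAMES",
    "ModelSpec",
    "MetricsReport",
    "RocComparison",
    "EvaluationError",
    "stratified_kfold",
    "make_classifier",
    "fit_predict",
    "confusion_metrics",
    "roc_auc",
    "compare_auc",
    "feature_importance",
    "cross_validate_model",
    "run_experiment",
    "write_report",
]

MODEL_NAMES = ("LR", "NB", "RF", "SVC", "XGB")
METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "precision", "f1", "auc")

#: The model x feature-set grid of the standard comparison report.
DEFAULT_GRID = (
    ("LR", "damico"),
    ("LR", "tnm"),
    ("LR", "clinical"),
    ("NB", "clinical"),
    ("RF", "clinical"),
    ("SVC", "clinical"),
    ("XGB", "clinical"),
    ("LR", "clinical_radiomics"),
    ("NB", "clinical_radiomics"),
    ("RF", "clinical_radiomics"),
    ("SVC", "clinical_radiomics"),
    ("XGB", "clinical_radiomics"),
)


class EvaluationError(RuntimeError):
    pass


@dataclass(frozen=True)
class ModelSpec:
    """One classifier configuration; hyperparameters override the defaults."""

    name: str
    feature_set: str = "clinical_radiomics"
    seed: int = 0
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"model name must be one of {MODEL_NAMES}")

    @property
    def label(self) -> str:
        return f"{self.name}_{self.feature_set}"


@dataclass
class MetricsReport:
    """Per-fold and aggregate metrics for one model configuration."""

    model: str
    feature_set: str
    per_fold: pd.DataFrame  # one row per fold, METRIC_NAMES columns
    pooled_confusion: dict  # tn, fp, fn, tp over concatenated test folds
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray

    def aggregate(self) -> dict:
        out = {}
        for m in METRIC_NAMES:
            vals = self.per_fold[m]
            out[m] = {
                "mean": float(vals.mean()),
                "min": float(vals.min()),
                "max": float(vals.max()),
            }
        return out

    def formatted(self) -> dict:
        return {
            m: f"{v['mean']:.2f} ({v['min']:.2f}–{v['max']:.2f})"
            for m, v in self.aggregate().items()
        }


@dataclass
class RocComparison:
    model_a: str
    model_b: str
    auc_a: float
    auc_b: float
    p_value: float


def stratified_kfold(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Assign each row to one of k folds, preserving class proportions.

    Per-fold class counts differ from an exact proportional split by at
    most one. Deterministic under ``seed``.
    """
    labels = np.asarray(labels)
    if k < 2:
        raise EvaluationError("k must be >= 2 (a held-out set is required)")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise EvaluationError(f"every class needs at least k={k} members")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of = np.empty(len(labels), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(labels)), labels)):
        fold_of[test_idx] = f
    return fold_of


def make_classifier(spec: ModelSpec):
    """Instantiate the named model family with frozen default settings."""
    hp = spec.hyperparameters
    if spec.name == "LR":
        return LogisticRegression(max_iter=5000, random_state=spec.seed, **hp)
    if spec.name == "NB":
        return GaussianNB(**hp)
    if spec.name == "RF":
        return RandomForestClassifier(
            n_estimators=100, random_state=spec.seed, n_jobs=1, **hp
        )
    if spec.name == "SVC":
        # Platt-calibrated scores so the SVC emits probabilities like the
        # other models.
        return CalibratedClassifierCV(
            SVC(random_state=spec.seed, **hp), ensemble=False, cv=3
        )
    if spec.name == "XGB":
        return XGBClassifier(
            n_estimators=100,
            max_depth=4,
            tree_method="hist",
            random_state=spec.seed,
            n_jobs=1,
            eval_metric="logloss",
            verbosity=0,
            **hp,
        )
    raise ValueError(spec.name)  # pragma: no cover


def fit_predict(
    spec: ModelSpec,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
):
    """Fit one model and return recurrence scores in [0, 1] for the test rows."""
    for name, arr in (("train", X_train), ("test", X_test)):
        if not np.all(np.isfinite(arr)):
            raise EvaluationError(f"non-finite features in the {name} matrix")
    clf = make_classifier(spec)
    clf.fit(X_train, y_train)
    return clf.predict_proba(X_test)[:, 1], clf


def confusion_metrics(tn: int, fp: int, fn: int, tp: int) -> dict:
    """Threshold metrics from a 2x2 confusion matrix.

    Ratios with a zero denominator are reported as 0 and listed under
    ``undefined``.
    """
    total = tn + fp + fn + tp
    if total == 0:
        raise EvaluationError("all-zero confusion matrix")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    sens = ratio(tp, tp + fn, "sensitivity")
    spec_ = ratio(tn, tn + fp, "specificity")
    prec = ratio(tp, tp + fp, "precision")
    f1 = ratio(2 * prec * sens, prec + sens, "f1")
    return {
        "accuracy": (tp + tn) / total,
        "sensitivity": sens,
        "specificity": spec_,
        "precision": prec,
        "f1": f1,
        "undefined": undefined,
    }


def roc_auc(scores, labels) -> float:
    """AUC as the tie-corrected Mann-Whitney statistic (ties count 1/2)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("roc_auc needs both classes present")
    ranks = stats.rankdata(scores)
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_components(pos: np.ndarray, neg: np.ndarray):
    """Structural components V10 (per positive) and V01 (per negative)."""
    m, n = len(pos), len(neg)
    all_scores = np.concatenate([pos, neg])
    r_all = stats.rankdata(all_scores)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    v10 = (r_all[:m] - r_pos) / n
    v01 = 1.0 - (r_all[m:] - r_neg) / m
    return v10, v01


def compare_auc(scores_a, scores_b, labels) -> RocComparison:
    """DeLong test for two correlated ROC curves on the same rows."""
    scores_a = np.asarray(scores_a, dtype=np.float64)
    scores_b = np.asarray(scores_b, dtype=np.float64)
    labels = np.asarray(labels, dtype=int)
    if not (len(scores_a) == len(scores_b) == len(labels)):
        raise EvaluationError("score vectors and labels must align row-for-row")
    pos_mask = labels == 1
    aucs = []
    v10s, v01s = [], []
    for s in (scores_a, scores_b):
        v10, v01 = _delong_components(s[pos_mask], s[~pos_mask])
        v10s.append(v10)
        v01s.append(v01)
        aucs.append(float(np.mean(v10)))
    m, n = int(pos_mask.sum()), int((~pos_mask).sum())
    s10 = np.cov(np.vstack(v10s))
    s01 = np.cov(np.vstack(v01s))
    var_diff = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    )
    delta = aucs[0] - aucs[1]
    if var_diff <= 0:
        p = 1.0 if delta == 0 else 0.0
    else:
        z = delta / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    return RocComparison("a", "b", aucs[0], aucs[1], p)


def feature_importance(model, names, top: int = 10) -> pd.DataFrame:
    """Top-ranked mean impurity-decrease importances of a tree ensemble.

    Importances are normalized to sum to 1; each feature is tagged as
    clinical or radiomics (the ``front_`` / ``back_`` prefixes mark
    radiomics columns).
    """
    if not hasattr(model, "feature_importances_"):
        raise EvaluationError("feature_importance requires a fitted tree ensemble")
    imp = np.asarray(model.feature_importances_, dtype=np.float64)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    df = pd.DataFrame(
        {
            "feature": list(names),
            "importance": imp,
            "class": [
                "radiomics" if str(n).startswith(("front_", "back_")) else "clinical"
                for n in names
            ],
        }
    )
    return df.sort_values("importance", ascending=False, kind="stable").head(top).reset_index(
        drop=True
    )


def cross_validate_model(
    design: DesignMatrix,
    spec: ModelSpec,
    k: int = 5,
    seed: int = 0,
    smote: SmoteConfig | None = None,
    fold_of: np.ndarray | None = None,
) -> MetricsReport:
    """Stratified k-fold evaluation of one model on one design matrix.

    Per fold: fit the min-max normalizer on training rows, rebalance the
    training rows, fit, score the untouched test rows.  Pooled scores are
    the concatenated out-of-fold scores, so the pooled confusion matrix
    totals the cohort size.
    """
    X_df, y = design.X, design.y
    if fold_of is None:
        fold_of = stratified_kfold(y, k=k, seed=seed)
    smote = smote or SmoteConfig(seed=seed)
    pooled_scores = np.empty(len(y), dtype=np.float64)
    rows = []
    cm_total = {"tn": 0, "fp": 0, "fn": 0, "tp": 0}
    for f in range(fold_of.max() + 1):
        test = fold_of == f
        train = ~test
        norm = MinMaxNormalizer(design.normalize_columns).fit(X_df[train])
        X_train = norm.transform(X_df[train]).to_numpy(dtype=np.float64)
        X_test = norm.transform(X_df[test]).to_numpy(dtype=np.float64)
        Xr, yr, _ = rebalance(X_train, y[train], smote)
        scores, _ = fit_predict(spec, Xr, yr, X_test)
        pooled_scores[test] = scores
        pred = scores >= 0.5
        yt = y[test].astype(bool)
        tn = int(np.sum(~pred & ~yt))
        fp = int(np.sum(pred & ~yt))
        fn = int(np.sum(~pred & yt))
        tp = int(np.sum(pred & yt))
        for key, val in zip(("tn", "fp", "fn", "tp"), (tn, fp, fn, tp)):
            cm_total[key] += val
        metrics = confusion_metrics(tn, fp, fn, tp)
        metrics.pop("undefined")
        metrics["auc"] = roc_auc(scores, y[test])
        rows.append(metrics)
    return MetricsReport(
        model=spec.name,
        feature_set=spec.feature_set,
        per_fold=pd.DataFrame(rows, columns=list(METRIC_NAMES)),
        pooled_confusion=cm_total,
        pooled_scores=pooled_scores,
        pooled_labels=y.copy(),
    )


@dataclass
class ExperimentReport:
    """Bundle of everything the standard comparison run produces."""

    reports: dict  # label -> MetricsReport
    metrics_table: pd.DataFrame  # Table-2-shaped
    best_label: str
    confusion_table: pd.DataFrame  # Table-3-shaped (pooled, best model)
    roc_table: pd.DataFrame  # Table-4-shaped (DeLong vs best)
    importance: pd.DataFrame | None  # top-10 RF importances


def run_experiment(
    designs: dict[str, DesignMatrix],
    k: int = 5,
    seed: int = 0,
    smote: SmoteConfig | None = None,
    grid=DEFAULT_GRID,
) -> ExperimentReport:
    """Run the full model x feature-set comparison.

    ``designs`` maps feature-set name to its design matrix (all variants
    share patients and labels).  All models share one fold assignment, so
    their pooled out-of-fold scores are paired row-for-row and can be
    compared with the DeLong test.  The best model is the one with the
    highest mean cross-validated AUC.
    """
    labels0 = next(iter(designs.values())).y
    for d in designs.values():
        if not np.array_equal(d.y, labels0):
            raise EvaluationError("all design variants must share labels")
    fold_of = stratified_kfold(labels0, k=k, seed=seed)

    reports: dict[str, MetricsReport] = {}
    table_rows = []
    for name, feature_set in grid:
        if feature_set not in designs:
            continue
        spec = ModelSpec(name=name, feature_set=feature_set, seed=seed)
        rep = cross_validate_model(
            designs[feature_set], spec, k=k, seed=seed, smote=smote, fold_of=fold_of
        )
        reports[spec.label] = rep
        row = {"model": name, "feature_set": feature_set}
        agg = rep.aggregate()
        fmt = rep.formatted()
        for m in METRIC_NAMES:
            row[m] = fmt[m]
            row[f"{m}_mean"] = agg[m]["mean"]
        table_rows.append(row)
        log.info("evaluated %-24s mean AUC %.3f", spec.label, agg["auc"]["mean"])
    metrics_table = pd.DataFrame(table_rows)

    best_label = max(reports, key=lambda lb: reports[lb].per_fold["auc"].mean())
    best = reports[best_label]
    cm = best.pooled_confusion
    confusion_table = pd.DataFrame(
        [[cm["tn"], cm["fp"]], [cm["fn"], cm["tp"]]],
        index=pd.Index(["true_no", "true_yes"]),
        columns=["pred_no", "pred_yes"],
    )

    roc_rows = []
    for lb, rep in reports.items():
        if lb == best_label:
            continue
        cmp_res = compare_auc(best.pooled_scores, rep.pooled_scores, labels0)
        roc_rows.append(
            {
                "best_model": best_label,
                "other_model": lb,
                "auc_best": cmp_res.auc_a,
                "auc_other": cmp_res.auc_b,
                "p_value": cmp_res.p_value,
            }
        )
    roc_table = pd.DataFrame(roc_rows)

    importance = None
    rf_label = "RF_clinical_radiomics"
    if rf_label in reports:
        design = designs["clinical_radiomics"]
        norm = MinMaxNormalizer(design.normalize_columns).fit(design.X)
        Xn = norm.transform(design.X).to_numpy(dtype=np.float64)
        Xr, yr, _ = rebalance(Xn, design.y, smote or SmoteConfig(seed=seed))
        rf = make_classifier(ModelSpec("RF", "clinical_radiomics", seed=seed))
        rf.fit(Xr, yr)
        importance = feature_importance(rf, design.X.columns, top=10)

    return ExperimentReport(
        reports=reports,
        metrics_table=metrics_table,
        best_label=best_label,
        confusion_table=confusion_table,
        roc_table=roc_table,
        importance=importance,
    )


def write_report(report: ExperimentReport, out_dir) -> list[str]:
    """Write table2/table3/table4 CSVs, the importance table and a ROC plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path
    from sklearn.metrics import roc_curve

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []

    report.metrics_table.to_csv(out_dir / "table2.csv", index=False)
    report.confusion_table.to_csv(out_dir / "table3.csv")
    report.roc_table.to_csv(out_dir / "table4.csv", index=False)
    written += ["table2.csv", "table3.csv", "table4.csv"]
    if report.importance is not None:
        report.importance.to_csv(out_dir / "importance.csv", index=False)
        written.append("importance.csv")

    fig, ax = plt.subplots(figsize=(6, 5))
    for lb, rep in report.reports.items():
        fpr, tpr, _ = roc_curve(rep.pooled_labels, rep.pooled_scores)
        auc = rep.per_fold["auc"].mean()
        ax.plot(fpr, tpr, label=f"{lb} (AUC {auc:.2f})", lw=1.2)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.legend(fontsize=6, loc="lower right")
    fig.tight_layout()
    fig.savefig(out_dir / "roc.svg")
    plt.close(fig)
    written.append("roc.svg")
    return written
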