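"""Diagnostic metrics, multi-run model comparison, ablation and attribution.

Metrics follow the usual multi-class conventions: per-class precision,
recall and F1 derive from the confusion matrix, F1 being the harmonic mean
2PR/(P+R); macro averages weight every disease class equally so that rare
diagnoses count as much as common ones.  AUC-ROC and AUC-PR are one-vs-rest
per class (midrank tie handling for ROC, conservative step-curve for PR) and
macro-averaged.  Model comparison across repeated seeded runs reports
mean accuracy ± a t-based 95% CI and two-sided paired t-tests against a
reference model.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from . import model as _model
from .model import ModelState, VARIANTS, build_variant
from .preprocess import FeatureMatrix
from .training import Hyperparams, initialize, train

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "ComparisonReport",
    "AblationReport",
    "AttributionReport",
    "confusion_matrix",
    "precision_recall_f1",
    "auc_roc",
    "auc_pr",
    "evaluate",
    "multi_run_compare",
    "run_ablation",
    "permutation_importance",
    "make_baseline",
    "BASELINES",
]


# ---------------------------------------------------------------------------
# confusion matrix and derived metrics
# ---------------------------------------------------------------------------

def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K×K counts, entry (i, j) = samples of true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred length mismatch")
    if y_true.size and (
        min(y_true.min(), y_pred.min()) < 0
        or max(y_true.max(), y_pred.max()) >= n_classes
    ):
        raise ValueError("labels out of range [0, K)")
    cm = np.zeros((n_classes, n_classes), dtype=int)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def precision_recall_f1(
    cm: np.ndarray, averaging: str = "macro"
) -> dict[str, np.ndarray | float]:
    """Precision, recall and F1 (percent) from a confusion matrix.

    Per-class precision = TP/(TP+FP), recall = TP/(TP+FN),
    F1 = 2·P·R/(P+R); a class never predicted contributes precision 0.
    ``averaging`` is macro (unweighted class mean), weighted (by class
    support) or per_class.
    """
    cm = np.asarray(cm)
    if cm.size == 0 or cm.shape[0] != cm.shape[1]:
        raise ValueError("confusion matrix must be square and non-empty")
    tp = np.diag(cm).astype(float)
    fp = cm.sum(axis=0) - tp
    fn = cm.sum(axis=1) - tp
    pred_pos = tp + fp
    if (pred_pos == 0).any():
        logger.info(
            "%d class(es) never predicted; precision reported as 0",
            int((pred_pos == 0).sum()),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = np.where(pred_pos > 0, tp / np.where(pred_pos > 0, pred_pos, 1), 0.0)
        rec = np.where(tp + fn > 0, tp / np.where(tp + fn > 0, tp + fn, 1), 0.0)
        f1 = np.where(prec + rec > 0, 2 * prec * rec / np.where(prec + rec > 0, prec + rec, 1), 0.0)
    prec, rec, f1 = 100 * prec, 100 * rec, 100 * f1
    if averaging == "per_class":
        return {"precision": prec, "recall": rec, "f1": f1}
    if averaging == "macro":
        w = np.full(cm.shape[0], 1.0 / cm.shape[0])
    elif averaging == "weighted":
        support = cm.sum(axis=1).astype(float)
        if support.sum() == 0:
            raise ValueError("empty confusion matrix")
        w = support / support.sum()
    else:
        raise ValueError(f"unknown averaging {averaging!r}")
    return {
        "precision": float(prec @ w),
        "recall": float(rec @ w),
        "f1": float(f1 @ w),
    }


def f1_score_pct(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall on the percent scale."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


# ---------------------------------------------------------------------------
# threshold-free metrics
# ---------------------------------------------------------------------------

def _ovr_macro(scores, y_true, per_class_fn) -> float:
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    y_true = np.asarray(y_true, dtype=int)
    if np.unique(y_true).size < 2:
        raise ValueError("need at least two classes present")
    vals = []
    for k in range(scores.shape[1]):
        pos = y_true == k
        v = per_class_fn(pos, scores[:, k])
        if v is None:
            continue
        vals.append(v)
    if not vals:
        raise ValueError("no class was evaluable")
    return float(np.mean(vals))


def auc_roc(scores, y_true) -> float:
    """One-vs-rest macro AUC-ROC with midrank tie handling.

    Classes lacking either a positive or a negative sample are skipped with
    a warning.
    """

    def per_class(pos, s):
        if pos.sum() == 0 or (~pos).sum() == 0:
            warnings.warn("class without both positives and negatives skipped in AUC-ROC")
            return None
        return roc_auc_score(pos, s)

    return _ovr_macro(scores, y_true, per_class)


def auc_pr(scores, y_true) -> float:
    """One-vs-rest macro area under the precision-recall step curve
    (Σ ΔRecall × precision; no linear interpolation between points)."""

    def per_class(pos, s):
        if pos.sum() == 0:
            warnings.warn("class without positives skipped in AUC-PR")
            return None
        return average_precision_score(pos, s)

    return _ovr_macro(scores, y_true, per_class)


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MetricsReport:
    """Full held-out evaluation of one fitted classifier."""

    accuracy: float                 # percent
    precision: float                # macro, percent
    recall: float
    f1: float
    auc_roc: float | None
    auc_pr: float | None
    per_class: pd.DataFrame         # class, precision, recall, f1, support
    confusion: np.ndarray

    def to_dict(self) -> dict:
        return {
            "accuracy": round(self.accuracy, 1),
            "precision": round(self.precision, 1),
            "recall": round(self.recall, 1),
            "f1": round(self.f1, 1),
            "auc_roc": None if self.auc_roc is None else round(self.auc_roc, 4),
            "auc_pr": None if self.auc_pr is None else round(self.auc_pr, 4),
            "per_class": self.per_class.round(1).to_dict(orient="records"),
            "confusion": self.confusion.tolist(),
        }


def evaluate(
    classifier, data: FeatureMatrix, averaging: str = "macro"
) -> MetricsReport:
    """Score a classifier on labeled data.

    ``classifier`` may be a ModelState, anything with predict/predict_proba
    (sklearn-style), or a bare ``predict`` callable (then AUCs are omitted).
    """
    scores = None
    if isinstance(classifier, ModelState):
        scores = _model.predict_proba(classifier, data.X)
        y_pred = scores.argmax(axis=1)
    elif hasattr(classifier, "predict"):
        y_pred = np.asarray(classifier.predict(data.X))
        if hasattr(classifier, "predict_proba"):
            scores = np.asarray(classifier.predict_proba(data.X))
        elif hasattr(classifier, "decision_function"):
            scores = np.asarray(classifier.decision_function(data.X))
    else:
        y_pred = np.asarray(classifier(data.X))

    K = len(data.class_names)
    cm = confusion_matrix(data.y, y_pred, K)
    macro = precision_recall_f1(cm, averaging=averaging)
    per = precision_recall_f1(cm, averaging="per_class")
    per_class = pd.DataFrame(
        {
            "class": data.class_names,
            "precision": per["precision"],
            "recall": per["recall"],
            "f1": per["f1"],
            "support": cm.sum(axis=1),
        }
    )
    roc = pr = None
    if scores is not None and scores.ndim == 2 and scores.shape[1] == K:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                roc = auc_roc(scores, data.y)
                pr = auc_pr(scores, data.y)
            except ValueError:
                pass
    return MetricsReport(
        accuracy=100.0 * float(np.mean(np.asarray(data.y) == y_pred)),
        precision=macro["precision"],
        recall=macro["recall"],
        f1=macro["f1"],
        auc_roc=roc,
        auc_pr=pr,
        per_class=per_class,
        confusion=cm,
    )


# ---------------------------------------------------------------------------
# multi-run statistical comparison
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class ComparisonReport:
    table: pd.DataFrame             # model, mean_accuracy, ci95, ..., p_value
    reference: str
    n_runs: int
    alpha: float

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "n_runs": self.n_runs,
            "alpha": self.alpha,
            "rows": self.table.to_dict(orient="records"),
        }


def _ci95_halfwidth(x: np.ndarray) -> float:
    if x.size < 2:
        return 0.0
    sd = np.std(x, ddof=1)
    if sd == 0:
        return 0.0
    return float(stats.t.ppf(0.975, x.size - 1) * sd / np.sqrt(x.size))


def multi_run_compare(
    accuracy: Mapping[str, Sequence[float]],
    reference: str,
    alpha: float = 0.05,
    extra_metrics: Mapping[str, Mapping[str, Sequence[float]]] | None = None,
) -> ComparisonReport:
    """Mean ± 95% CI per model and paired t-tests against the reference.

    Every model must have the same number of paired runs (same seeds/splits
    per position).  Zero-variance run differences use the degenerate
    conventions: p = 1.0 for an identically-zero difference, p = 0.0 (flagged
    degenerate) for a constant nonzero difference.
    """
    if reference not in accuracy:
        raise ValueError(f"reference model {reference!r} not among results")
    runs = {m: np.asarray(v, dtype=float) for m, v in accuracy.items()}
    R = len(runs[reference])
    if R < 2:
        raise ValueError("need at least 2 paired runs")
    if any(v.size != R for v in runs.values()):
        raise ValueError("all models must have the same number of runs")
    rows = []
    for name, acc in runs.items():
        row = {
            "model": name,
            "mean_accuracy": float(np.mean(acc)),
            "ci95": _ci95_halfwidth(acc),
        }
        if extra_metrics and name in extra_metrics:
            for mname, vals in extra_metrics[name].items():
                row[f"mean_{mname}"] = float(np.mean(vals))
        if name == reference:
            row.update(p_value=None, significant=None, degenerate=False)
        else:
            diff = runs[reference] - acc
            if np.allclose(np.std(diff, ddof=1), 0.0):
                if np.allclose(diff.mean(), 0.0):
                    p, degenerate = 1.0, False
                else:
                    p, degenerate = 0.0, True
            else:
                p = float(stats.ttest_rel(runs[reference], acc).pvalue)
                degenerate = False
            row.update(p_value=p, significant=p < alpha, degenerate=degenerate)
        rows.append(row)
    return ComparisonReport(
        table=pd.DataFrame(rows), reference=reference, n_runs=R, alpha=alpha
    )


# ---------------------------------------------------------------------------
# ablation harness
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AblationReport:
    table: pd.DataFrame             # variant, accuracy, precision, recall, f1, auc_roc
    per_seed: pd.DataFrame          # variant, seed, accuracy
    failures: dict[str, str]

    def to_dict(self) -> dict:
        return {
            "rows": self.table.round(4).to_dict(orient="records"),
            "per_seed": self.per_seed.round(4).to_dict(orient="records"),
            "failures": self.failures,
        }


def run_ablation(
    data: tuple[FeatureMatrix, FeatureMatrix, FeatureMatrix],
    hp: Hyperparams,
    seeds: Sequence[int],
    variants: Sequence[str] = tuple(VARIANTS),
    **config_overrides,
) -> AblationReport:
    """Train and score every architecture variant over shared seeds.

    All variants see identical data splits and hyperparameters; each seed
    controls both initialization and mini-batch shuffling, paired across
    variants.  A variant whose training fails is recorded in ``failures``
    and excluded from the table.
    """
    tr, va, te = data
    K = len(tr.class_names)
    F = tr.X.shape[1]
    rows, per_seed, failures = [], [], {}
    for name in variants:
        metrics: list[MetricsReport] = []
        try:
            for seed in seeds:
                cfg = build_variant(name, F, K, seed=int(seed), **config_overrides)
                ts = train(cfg, initialize(cfg, int(seed)), (tr, va),
                           dataclasses.replace(hp, seed=int(seed)))
                rep = evaluate(ts.model, te)
                metrics.append(rep)
                per_seed.append(
                    {"variant": name, "seed": int(seed), "accuracy": rep.accuracy}
                )
        except Exception as exc:  # noqa: BLE001 — partial report by contract
            failures[name] = f"{type(exc).__name__}: {exc}"
            logger.warning("variant %s failed: %s", name, failures[name])
            continue
        mp = float(np.mean([m.precision for m in metrics]))
        mr = float(np.mean([m.recall for m in metrics]))
        rows.append(
            {
                "variant": name,
                "accuracy": np.mean([m.accuracy for m in metrics]),
                "precision": mp,
                "recall": mr,
                # table convention: the F1 cell is the harmonic mean of the
                # row's printed precision and recall
                "f1": f1_score_pct(mp, mr),
                "auc_roc": np.mean(
                    [m.auc_roc for m in metrics if m.auc_roc is not None]
                ),
            }
        )
    return AblationReport(
        table=pd.DataFrame(rows),
        per_seed=pd.DataFrame(per_seed),
        failures=failures,
    )


# ---------------------------------------------------------------------------
# permutation feature attribution
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class AttributionReport:
    table: pd.DataFrame             # feature, importance, std — ranked descending
    baseline_accuracy: float
    n_repeats: int

    def to_dict(self) -> dict:
        return {
            "baseline_accuracy": round(self.baseline_accuracy, 4),
            "n_repeats": self.n_repeats,
            "rows": self.table.round(6).to_dict(orient="records"),
        }


def permutation_importance(
    classifier,
    data: FeatureMatrix,
    n_repeats: int = 5,
    seed: int = 0,
    attribution_hook: Callable | None = None,
) -> AttributionReport:
    """Model-agnostic attribution: drop in accuracy when one source feature's
    columns are permuted (one-hot blocks are permuted jointly, preserving the
    block structure).

    ``attribution_hook``, if given, is called as hook(predict_fn, data) and
    its result attached — the extension point for SHAP/LIME-style explainers.
    """
    if data.X.shape[0] < 2:
        raise ValueError("need at least 2 rows to permute")
    if isinstance(classifier, ModelState):
        predict_fn = lambda X: _model.predict(classifier, X)  # noqa: E731
    elif hasattr(classifier, "predict"):
        predict_fn = classifier.predict
    else:
        predict_fn = classifier
    rng = np.random.default_rng(seed)
    y = np.asarray(data.y)
    base = float(np.mean(predict_fn(data.X) == y))
    rows = []
    for feat, sl in data.groups.items():
        drops = []
        for _ in range(n_repeats):
            Xp = data.X.copy()
            perm = rng.permutation(Xp.shape[0])
            Xp[:, sl] = Xp[perm, sl]
            drops.append(base - float(np.mean(predict_fn(Xp) == y)))
        rows.append(
            {"feature": feat, "importance": float(np.mean(drops)),
             "std": float(np.std(drops))}
        )
    table = (
        pd.DataFrame(rows)
        .sort_values("importance", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    report = AttributionReport(
        table=table, baseline_accuracy=base, n_repeats=n_repeats
    )
    if attribution_hook is not None:
        report.hook_result = attribution_hook(predict_fn, data)  # type: ignore[attr-defined]
    return report


# ---------------------------------------------------------------------------
# baseline comparators (delegated to scikit-learn behind one adapter)
# ---------------------------------------------------------------------------

BASELINES = ("svm", "rf", "knn", "lr", "mlp")


def make_baseline(name: str, seed: int = 0):
    """A scikit-learn comparator with a uniform fit/predict surface."""
    if name == "svm":
        return SVC(kernel="rbf", C=1.0, random_state=seed)
    if name == "rf":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=5)
    if name == "lr":
        return LogisticRegression(max_iter=2000, random_state=seed)
    if name == "mlp":
        return MLPClassifier(
            hidden_layer_sizes=(64, 32), max_iter=300, random_state=seed
        )
    raise ValueError(f"unknown baseline {name!r}; choose from {BASELINES}")
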