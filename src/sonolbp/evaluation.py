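"""Linear-SVM classification with nested stratified cross-validation.

Protocol: stratified 5-fold outer cross-validation; within each outer
training fold the features are standardized, the top ANOVA percentile is
retained, and the soft-margin cost C is chosen by an inner stratified
grid search on accuracy; the refit model is then scored on the held-out
fold.  Moderate-severe pain is the positive class.  Confusion counts are
pooled over the outer folds; AUC is the Mann-Whitney rank statistic of the
pooled decision scores, P(score+ > score-) + 0.5 P(tie).

Feature importance is the mean absolute standardized SVM weight across the
outer folds (a feature not selected in a fold contributes 0 there).
Attribution tables tally a retained feature set by family, muscle,
vertebral level, side and position against the 800-name universe.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import protocol
from .cohort import MODERATE_SEVERE
from .protocol import FeatureName, ROIKey, parse_feature_name, roi_feature_names
from .selection import SelectionConfig, fit_selection, standardize_apply

logger = logging.getLogger(__name__)

POSITIVE_CLASS = MODERATE_SEVERE


@dataclass(frozen=True)
class SVMConfig:
    c_grid: tuple[float, ...] = (0.01, 0.1, 1.0, 10.0, 100.0)
    inner_folds: int = 5
    outer_folds: int = 5
    seed: int = 0

    def validate(self) -> list[str]:
        problems = []
        if not self.c_grid or any(c <= 0 for c in self.c_grid):
            problems.append("SVMConfig.c_grid: must be non-empty with positive entries")
        if self.outer_folds != 5:
            problems.append("SVMConfig.outer_folds: fixed at 5")
        if self.inner_folds < 2:
            problems.append("SVMConfig.inner_folds: must be >= 2")
        return problems


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass(frozen=True)
class MetricPanel:
    accuracy: float
    sensitivity: float
    specificity: float
    auc: float
    precision: float
    npv: float

    def to_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy, "sensitivity": self.sensitivity,
            "specificity": self.specificity, "auc": self.auc,
            "precision": self.precision, "npv": self.npv,
        }


@dataclass
class EvalReport:
    fold_panels: list[MetricPanel]
    fold_counts: list[ConfusionCounts]
    pooled_counts: ConfusionCounts
    pooled: MetricPanel
    best_c: list[float]
    ranking: pd.DataFrame  # serialized name, mean_weight, mean_abs_weight
    fold_retained: list[list[str]]
    retained: list[str]  # consensus retained set (selection fit on all rows)
    attribution: dict[str, pd.DataFrame]
    mode: str = "fold-fit"  # or "fit-on-all"


def split_feature_table(table: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Split a cohort feature table into (features, binary labels);
    1 = moderate-severe (positive class)."""
    y = (table["group"].to_numpy() == POSITIVE_CLASS).astype(int)
    X = table.drop(columns=[c for c in ("vas", "group") if c in table.columns])
    return X, y


def train_linear_svm(X: np.ndarray, y: np.ndarray, c: float) -> tuple[np.ndarray, float]:
    """Fit the linear-kernel soft-margin SVM; returns (weights, bias)."""
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    model = SVC(kernel="linear", C=c)
    model.fit(X, y)
    return model.coef_[0].copy(), float(model.intercept_[0])


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score+ > score-) + 0.5 P(tie)."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    n_neg = int(labels.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.debug("%s undefined (zero denominator); reported as NaN", name)
        return float("nan")
    return num / den


def metric_panel(
    counts: ConfusionCounts,
    scores: np.ndarray | None = None,
    labels: np.ndarray | None = None,
) -> MetricPanel:
    auc = rank_auc(scores, labels) if scores is not None and labels is not None else float("nan")
    return MetricPanel(
        accuracy=_ratio(counts.tp + counts.tn, counts.n, "accuracy"),
        sensitivity=_ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        specificity=_ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        auc=auc,
        precision=_ratio(counts.tp, counts.tp + counts.fp, "precision"),
        npv=_ratio(counts.tn, counts.tn + counts.fn, "npv"),
    )


def _confusion(preds: np.ndarray, y: np.ndarray) -> ConfusionCounts:
    preds = np.asarray(preds).astype(int)
    y = np.asarray(y).astype(int)
    return ConfusionCounts(
        tp=int(((preds == 1) & (y == 1)).sum()),
        fp=int(((preds == 1) & (y == 0)).sum()),
        tn=int(((preds == 0) & (y == 0)).sum()),
        fn=int(((preds == 0) & (y == 1)).sum()),
    )


def _grid_search_c(
    X: np.ndarray, y: np.ndarray, sel_cfg: SelectionConfig, svm_cfg: SVMConfig,
    fixed_selection=None,
) -> float:
    """Inner stratified grid search over C by accuracy; ties take the smaller C."""
    inner = StratifiedKFold(n_splits=svm_cfg.inner_folds, shuffle=True,
                            random_state=svm_cfg.seed + 1)
    accs = np.zeros(len(svm_cfg.c_grid))
    for tr, va in inner.split(X, y):
        if fixed_selection is None:
            sel = fit_selection(X[tr], y[tr], sel_cfg)
        else:
            sel = fixed_selection
        ztr = standardize_apply(X[tr], sel.params)[:, sel.retained]
        zva = standardize_apply(X[va], sel.params)[:, sel.retained]
        for i, c in enumerate(svm_cfg.c_grid):
            w, b = train_linear_svm(ztr, y[tr], c)
            preds = (zva @ w + b >= 0).astype(int)
            accs[i] += (preds == y[va]).mean()
    return float(svm_cfg.c_grid[int(np.argmax(accs))])


def cross_validate(
    X: pd.DataFrame,
    y: np.ndarray,
    sel_cfg: SelectionConfig | None = None,
    svm_cfg: SVMConfig | None = None,
    fit_on_all: bool = False,
    attribution: bool = True,
) -> EvalReport:
    """Full nested-CV evaluation of the standardize -> select -> SVM pipeline.

    ``fit_on_all=True`` mirrors the compatibility mode in which
    standardization and selection are fit once on the whole matrix before
    cross-validating the classifier (optimistic; the default refits both
    inside every training fold).
    """
    sel_cfg = sel_cfg or SelectionConfig()
    svm_cfg = svm_cfg or SVMConfig()
    for cfg in (sel_cfg, svm_cfg):
        problems = cfg.validate()
        if problems:
            raise ValueError("; ".join(problems))
    columns = list(X.columns)
    Xv = X.to_numpy(dtype=np.float64)
    y = np.asarray(y).astype(int)
    class_counts = np.bincount(y, minlength=2)
    if class_counts.min() < svm_cfg.outer_folds:
        raise ValueError(
            f"stratified {svm_cfg.outer_folds}-fold CV needs >= {svm_cfg.outer_folds} "
            f"samples per class, got {class_counts.tolist()}"
        )

    global_sel = fit_selection(Xv, y, sel_cfg)
    outer = StratifiedKFold(n_splits=svm_cfg.outer_folds, shuffle=True,
                            random_state=svm_cfg.seed)
    fold_panels, fold_counts, best_cs, fold_retained = [], [], [], []
    abs_weights = np.zeros((svm_cfg.outer_folds, Xv.shape[1]))
    signed_weights = np.zeros_like(abs_weights)
    pooled_scores = np.zeros(len(y))
    pooled_preds = np.zeros(len(y), dtype=int)

    for k, (tr, te) in enumerate(outer.split(Xv, y)):
        sel = global_sel if fit_on_all else fit_selection(Xv[tr], y[tr], sel_cfg)
        best_c = _grid_search_c(Xv[tr], y[tr], sel_cfg, svm_cfg,
                                fixed_selection=global_sel if fit_on_all else None)
        ztr = standardize_apply(Xv[tr], sel.params)[:, sel.retained]
        zte = standardize_apply(Xv[te], sel.params)[:, sel.retained]
        w, b = train_linear_svm(ztr, y[tr], best_c)
        scores = zte @ w + b
        preds = (scores >= 0).astype(int)

        counts = _confusion(preds, y[te])
        fold_counts.append(counts)
        fold_panels.append(metric_panel(counts, scores, y[te]))
        best_cs.append(best_c)
        fold_retained.append([columns[i] for i in sel.retained])
        abs_weights[k, sel.retained] = np.abs(w)
        signed_weights[k, sel.retained] = w
        pooled_scores[te] = scores
        pooled_preds[te] = preds

    pooled_counts = ConfusionCounts()
    for c in fold_counts:
        pooled_counts = pooled_counts + c
    pooled = metric_panel(pooled_counts, pooled_scores, y)

    ranking = pd.DataFrame({
        "feature": columns,
        "mean_weight": signed_weights.mean(axis=0),
        "mean_abs_weight": abs_weights.mean(axis=0),
    }).sort_values("mean_abs_weight", ascending=False, kind="stable").reset_index(drop=True)

    retained = [columns[i] for i in global_sel.retained]
    attr = attribution_tables(retained, columns) if attribution else {}
    return EvalReport(
        fold_panels=fold_panels, fold_counts=fold_counts,
        pooled_counts=pooled_counts, pooled=pooled, best_c=best_cs,
        ranking=ranking, fold_retained=fold_retained, retained=retained,
        attribution=attr, mode="fit-on-all" if fit_on_all else "fold-fit",
    )


def importance_ranking(report: EvalReport, top: int | None = None) -> pd.DataFrame:
    """Features by descending mean absolute weight, in the conventional
    serialized naming style."""
    ranking = report.ranking.copy()
    ranking["rank"] = np.arange(1, len(ranking) + 1)
    return ranking.head(top) if top is not None else ranking


# ---------------------------------------------------------------------------
# Attribution bookkeeping

_PARTITIONS = {
    "family": lambda n: n.family,
    "muscle": lambda n: n.muscle,
    "level": lambda n: n.level,
    "side": lambda n: n.side,
    "position": lambda n: n.position,
}


def attribution_tables(
    retained: list[str | FeatureName], universe: list[str | FeatureName] | None = None
) -> dict[str, pd.DataFrame]:
    """Tally retained features by family/muscle/level/side/position, with
    denominators from the full feature universe."""
    def as_names(items) -> list[FeatureName]:
        return [parse_feature_name(x) if isinstance(x, str) else x for x in items]

    retained_names = as_names(retained)
    universe_names = as_names(universe) if universe is not None else list(protocol.feature_universe())
    tables = {}
    for part, keyfn in _PARTITIONS.items():
        cats = list(dict.fromkeys(keyfn(n) for n in universe_names))
        sel = pd.Series([keyfn(n) for n in retained_names]).value_counts()
        tot = pd.Series([keyfn(n) for n in universe_names]).value_counts()
        tables[part] = pd.DataFrame({
            "selected": [int(sel.get(c, 0)) for c in cats],
            "total": [int(tot.get(c, 0)) for c in cats],
        }, index=pd.Index(cats, name=part))
    return tables


# ---------------------------------------------------------------------------
# Single-site (SIFS) vs multi-site (MIFS) comparison

def site_columns(site: ROIKey, columns: list[str]) -> list[str]:
    wanted = {n.serialize() for n in roi_feature_names(site)}
    return [c for c in columns if c in wanted]


def sifs_run(
    X: pd.DataFrame, y: np.ndarray, site: ROIKey,
    sel_cfg: SelectionConfig | None = None, svm_cfg: SVMConfig | None = None,
) -> MetricPanel:
    """Evaluate the pipeline restricted to one ROI's 57 features."""
    cols = site_columns(site, list(X.columns))
    if not cols:
        raise ValueError(f"no feature columns for site {site.site_label()}")
    report = cross_validate(X[cols], y, sel_cfg, svm_cfg, attribution=False)
    return report.pooled


def sifs_table(
    X: pd.DataFrame, y: np.ndarray,
    sel_cfg: SelectionConfig | None = None, svm_cfg: SVMConfig | None = None,
) -> pd.DataFrame:
    """14 single-site panels plus the all-site (multi-site fusion) Total row."""
    rows = {}
    for site in protocol.PROTOCOL_KEYS:
        rows[site.site_label()] = sifs_run(X, y, site, sel_cfg, svm_cfg).to_dict()
    rows["Total"] = cross_validate(X, y, sel_cfg, svm_cfg, attribution=False).pooled.to_dict()
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# Group-difference reporting for top features

def mann_whitney_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Mann-Whitney p (exact when sample sizes permit)."""
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="auto").pvalue)


def students_t_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided pooled-variance Student's t p-value."""
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def _significance_flag(p: float) -> str:
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def group_difference_tests(
    X: pd.DataFrame, y: np.ndarray, feature_names: list[str] | None = None
) -> pd.DataFrame:
    """Per-feature two-group test: Student's t when both groups pass a
    Shapiro-Wilk normality check at alpha 0.05, Mann-Whitney otherwise."""
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("both classes must be present")
    names = feature_names if feature_names is not None else list(X.columns)
    rows = []
    for name in names:
        a = X[name].to_numpy(dtype=np.float64)[y == 1]
        b = X[name].to_numpy(dtype=np.float64)[y == 0]
        if np.ptp(np.concatenate([a, b])) == 0:
            logger.debug("feature %s is constant; p=1 by convention", name)
            rows.append((name, "degenerate", 1.0, ""))
            continue
        normal = (
            len(a) >= 3 and len(b) >= 3
            and np.ptp(a) > 0 and np.ptp(b) > 0
            and stats.shapiro(a).pvalue > 0.05 and stats.shapiro(b).pvalue > 0.05
        )
        if normal:
            p = students_t_p(a, b)
            test = "t-test"
        else:
            p = mann_whitney_p(a, b)
            test = "mann-whitney"
        rows.append((name, test, p, _significance_flag(p)))
    return pd.DataFrame(rows, columns=["feature", "test", "p_value", "flag"])
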