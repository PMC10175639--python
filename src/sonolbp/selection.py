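"""Feature standardization and ANOVA-percentile selection.

Features are z-scored, y = (x - mu) / sigma, with population moments
estimated on the training rows; each feature is then scored by the one-way
ANOVA F statistic between the two pain groups and the top percentile
(default 6%, i.e. 48 of 800 features) is retained.

The F score is invariant under any affine rescaling of a feature, so
standardization does not change the ranking; it matters for the margin-based
classifier downstream.  Ties are broken by the canonical feature order so
the retained set is deterministic.  A feature with zero within-group
variance but distinct group means gets an infinite score and ranks above
every finite one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_PERCENTILE = 6


@dataclass(frozen=True)
class StandardizationParams:
    mean: np.ndarray
    std: np.ndarray  # population std; zero marks a constant column

    @property
    def constant_columns(self) -> np.ndarray:
        return self.std == 0


@dataclass(frozen=True)
class SelectionConfig:
    percentile: int = DEFAULT_PERCENTILE
    tie_break: str = "canonical"  # ties in F broken by column order

    def validate(self) -> list[str]:
        problems = []
        if not (1 <= self.percentile <= 100):
            problems.append("SelectionConfig.percentile: must be an integer in [1, 100]")
        if self.tie_break != "canonical":
            problems.append("SelectionConfig.tie_break: only 'canonical' is implemented")
        return problems


@dataclass(frozen=True)
class SelectionResult:
    f_scores: np.ndarray
    retained: np.ndarray  # column indices, best score first
    params: StandardizationParams


def standardize_fit(matrix: np.ndarray) -> StandardizationParams:
    """Per-column population mean and standard deviation."""
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("standardization needs a 2-D matrix with >= 2 rows")
    mean = x.mean(axis=0)
    std = x.std(axis=0)  # ddof=0
    n_const = int((std == 0).sum())
    if n_const:
        logger.debug("%d constant columns (sigma=0) map to 0 after standardization", n_const)
    return StandardizationParams(mean=mean, std=std)


def standardize_apply(matrix: np.ndarray, params: StandardizationParams) -> np.ndarray:
    x = np.asarray(matrix, dtype=np.float64)
    if x.shape[-1] != params.mean.shape[0]:
        raise ValueError(
            f"matrix has {x.shape[-1]} columns but params were fit on {params.mean.shape[0]}"
        )
    safe = np.where(params.std > 0, params.std, 1.0)
    return np.where(params.std > 0, (x - params.mean) / safe, 0.0)


def anova_f(matrix: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """One-way two-group ANOVA F per column: (SSB/(g-1)) / (SSW/(n-g)).

    Columns with zero within-group variance score +inf when the group means
    differ and 0 when they coincide.
    """
    x = np.atleast_2d(np.asarray(matrix, dtype=np.float64))
    if x.ndim == 2 and x.shape[0] == 1:
        x = x.T
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"exactly two classes required, got {classes.size}")
    if min(int((y == c).sum()) for c in classes) < 2:
        raise ValueError("each class needs at least 2 samples")
    n = x.shape[0]
    grand = x.mean(axis=0)
    ssb = np.zeros(x.shape[1])
    ssw = np.zeros(x.shape[1])
    for c in classes:
        xc = x[y == c]
        mc = xc.mean(axis=0)
        ssb += xc.shape[0] * (mc - grand) ** 2
        ssw += ((xc - mc) ** 2).sum(axis=0)
    msb = ssb  # g - 1 == 1
    msw = ssw / (n - 2)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f = np.where(msw > 0, f, np.where(msb > 0, np.inf, 0.0))
    return f


def select_top_percentile(f_scores: np.ndarray, config: SelectionConfig) -> np.ndarray:
    """Indices of the top-percentile scores, best first; k = floor(n*pct/100).

    Ties (including between infinities) are broken by column order.
    """
    problems = config.validate()
    if problems:
        raise ValueError("; ".join(problems))
    f = np.asarray(f_scores, dtype=np.float64)
    n = f.shape[0]
    k = (n * config.percentile) // 100
    if k < 1:
        raise ValueError(
            f"percentile {config.percentile} of {n} features retains no feature"
        )
    # Stable sort on -F keeps earlier (canonical-order) columns first on ties;
    # NaN-free: infinities sort ahead of all finite scores.
    order = np.argsort(-f, kind="stable")
    return order[:k]


def fit_selection(
    matrix: np.ndarray, labels: np.ndarray, config: SelectionConfig
) -> SelectionResult:
    """Standardize, score and select on one training matrix."""
    params = standardize_fit(matrix)
    z = standardize_apply(matrix, params)
    f = anova_f(z, labels)
    retained = select_top_percentile(f, config)
    return SelectionResult(f_scores=f, retained=retained, params=params)


def percentile_sweep(matrix, labels, percentiles, eval_fn) -> list[tuple[int, float]]:
    """Evaluate ``eval_fn(matrix, labels, percentile)`` over a percentile grid.

    Returns [(percentile, metric), ...] in the requested order; the caller
    reads the argmax off the curve.
    """
    curve = []
    for pct in percentiles:
        curve.append((int(pct), float(eval_fn(matrix, labels, int(pct)))))
    return curve
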