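"""The analysis battery for cohort data.

Covers the full pipeline used to evaluate the instrument against the SWAN
inattention subscale:

* Pearson correlations (two-sided t-based p) of each predictor with the
  SWAN total, overall and per IS class — a 3 x 4 grid.
* Single/multiple OLS regressions over the 7 nonempty predictor subsets
  of {median, IQR, omissions}, exposing their collinearity.
* Block-wise correlations of the per-block median distance with SWAN,
  one per block, tagged with IS class.
* One-way ANOVA on those correlations with IS class as factor, plus
  Bonferroni pairwise comparisons (per-test alpha = family alpha / 3).
* Repeated hold-out validation: many random 75/25 splits, a 3-predictor
  linear model (per-IS-class median distances) fit on train, scored as the
  Pearson r between predicted and observed SWAN on test, averaged raw
  across repetitions.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm

from .cohort_sim import Cohort
from .errors import ConfigurationError, DegenerateDataError, SingularDesignError
from .metrics import Scope
from .schedule import ISClass, is_class

__all__ = [
    "CorrelationResult",
    "RegressionResult",
    "RegressionTerm",
    "AnovaResult",
    "PairwiseComparison",
    "ValidationResult",
    "pearson",
    "correlation_table",
    "ols_fit",
    "collinearity_table",
    "per_block_correlations",
    "anova_on_correlations",
    "bonferroni_pairwise",
    "validation_predictors",
    "repeated_validation",
    "PREDICTORS",
    "MODEL_SUBSETS",
]

logger = logging.getLogger(__name__)

#: Predictor columns of the metrics table, in reporting order.
PREDICTORS = ("median", "iqr", "omissions")

#: The 7 nonempty predictor subsets, in the conventional reporting order.
MODEL_SUBSETS: tuple[tuple[str, ...], ...] = (
    ("median",),
    ("iqr",),
    ("omissions",),
    ("median", "iqr"),
    ("median", "omissions"),
    ("iqr", "omissions"),
    ("median", "iqr", "omissions"),
)


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    n: int
    label: str = ""


@dataclass(frozen=True)
class RegressionTerm:
    name: str
    coef: float
    se: float
    t: float
    p: float


@dataclass(frozen=True)
class RegressionResult:
    terms: tuple[RegressionTerm, ...]
    n: int
    model_label: str
    r_squared: float

    def term(self, name: str) -> RegressionTerm:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)


@dataclass(frozen=True)
class AnovaResult:
    F: float
    p: float
    group_means: dict[str, float]
    df_between: int
    df_within: int


@dataclass(frozen=True)
class PairwiseComparison:
    pair: tuple[str, str]
    mean_difference: float
    p: float
    per_test_alpha: float
    significant: bool


@dataclass(frozen=True)
class ValidationResult:
    mean_r: float
    per_rep_r: tuple[float, ...]
    reps: int
    train_fraction: float
    train_n: int
    test_n: int
    n_excluded: int = 0


# -- elementary procedures ----------------------------------------------


def _as_clean_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ConfigurationError(f"{name} must be one-dimensional")
    return arr


def pearson(x, y, label: str = "") -> CorrelationResult:
    """Product-moment correlation with a two-sided t-based p-value."""
    xv = _as_clean_vector(x, "x")
    yv = _as_clean_vector(y, "y")
    if xv.size != yv.size:
        raise ConfigurationError(f"length mismatch: {xv.size} vs {yv.size}")
    if xv.size < 3:
        raise DegenerateDataError("pearson requires n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise DegenerateDataError("correlation undefined for constant input")
    res = sps.pearsonr(xv, yv)
    return CorrelationResult(r=float(res.statistic), p=float(res.pvalue),
                             n=int(xv.size), label=label)


def correlation_table(
    metrics: pd.DataFrame, swan: dict[str, float]
) -> dict[tuple[str, str], CorrelationResult]:
    """3 predictors x 4 scopes grid of correlations against SWAN totals.

    Keys are ``(predictor, scope)`` with predictor in ``PREDICTORS`` and
    scope in ``("ALL", "SHORT", "MEDIUM", "LONG")``.  Participants with a
    missing value for a cell (e.g. no voluntary jumps in that scope) are
    dropped pairwise, with the count logged.
    """
    out: dict[tuple[str, str], CorrelationResult] = {}
    for scope in Scope:
        sub = metrics[metrics["scope"] == scope.value]
        sw = sub["participant_id"].map(swan).to_numpy(dtype=float)
        for pred in PREDICTORS:
            vals = sub[pred].to_numpy(dtype=float)
            ok = ~(np.isnan(vals) | np.isnan(sw))
            n_dropped = int((~ok).sum())
            if n_dropped:
                logger.info(
                    "correlation_table: dropped %d participants for %s/%s",
                    n_dropped, pred, scope.value,
                )
            out[(pred, scope.value)] = pearson(
                vals[ok], sw[ok], label=f"{pred}:{scope.value}"
            )
    return out


def ols_fit(response, predictors: dict[str, np.ndarray] | pd.DataFrame) -> RegressionResult:
    """Ordinary least squares with intercept; per-term SE, t and two-sided p."""
    X = pd.DataFrame(predictors)
    y = _as_clean_vector(response, "response")
    if len(X) != y.size:
        raise ConfigurationError("response and predictors have different lengths")
    k = X.shape[1]
    if y.size <= k + 1:
        raise DegenerateDataError("need n > number of predictors + 1")
    design = sm.add_constant(X.to_numpy(dtype=float), has_constant="add")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise SingularDesignError(
            f"design matrix with predictors {list(X.columns)} is rank deficient"
        )
    fit = sm.OLS(y, design).fit()
    names = ["const", *map(str, X.columns)]
    terms = tuple(
        RegressionTerm(
            name=nm,
            coef=float(fit.params[i]),
            se=float(fit.bse[i]),
            t=float(fit.tvalues[i]),
            p=float(fit.pvalues[i]),
        )
        for i, nm in enumerate(names)
    )
    return RegressionResult(
        terms=terms,
        n=int(y.size),
        model_label="+".join(map(str, X.columns)),
        r_squared=float(fit.rsquared),
    )


def collinearity_table(
    metrics_all: pd.DataFrame, swan: dict[str, float]
) -> list[RegressionResult]:
    """Fit the 7 predictor-subset regressions of SWAN on ALL-scope metrics.

    ``metrics_all`` is the ALL-scope slice of the metrics table (or the
    full table, from which the ALL rows are taken).  The returned list
    follows ``MODEL_SUBSETS`` order: the three simple regressions, the
    three two-predictor models, then the full model.
    """
    sub = metrics_all
    if "scope" in metrics_all.columns:
        sub = metrics_all[metrics_all["scope"] == Scope.ALL.value]
    y = sub["participant_id"].map(swan).to_numpy(dtype=float)
    results = []
    for subset in MODEL_SUBSETS:
        X = sub[list(subset)]
        mask = ~(X.isna().any(axis=1).to_numpy() | np.isnan(y))
        results.append(ols_fit(y[mask], X.loc[mask]))
    return results


def per_block_correlations(cohort: Cohort) -> list[tuple[str, ISClass, CorrelationResult]]:
    """Correlation of each block's median jump distance with SWAN, B1..B18.

    Participants with no voluntary jump in a block are dropped pairwise for
    that block (count logged); every block needs at least 3 remaining.
    """
    if not cohort.logs:
        raise DegenerateDataError("empty cohort")
    swan = cohort.swan_totals()
    schedule_blocks = {}
    per_block: dict[str, dict[str, float]] = {}
    for log in cohort.logs:
        by_block: dict[str, list[float]] = {}
        for r in log.records:
            if r.voluntary:
                by_block.setdefault(r.block_id, []).append(r.distance)
        for bid, ds in by_block.items():
            per_block.setdefault(bid, {})[log.participant_id] = float(np.median(ds))
    # preserve schedule order from the first log
    order = list(dict.fromkeys(r.block_id for r in cohort.logs[0].records))
    for r in cohort.logs[0].records:
        schedule_blocks.setdefault(r.block_id, r.is_nominal)
    out = []
    for bid in order:
        medians = per_block.get(bid, {})
        pids = [pid for pid in cohort.participant_ids if pid in medians]
        n_dropped = len(cohort) - len(pids)
        if n_dropped:
            logger.info("per_block_correlations: block %s dropped %d participants",
                        bid, n_dropped)
        if len(pids) < 3:
            raise DegenerateDataError(
                f"block {bid}: fewer than 3 participants with voluntary jumps"
            )
        res = pearson(
            [medians[p] for p in pids], [swan[p] for p in pids], label=f"block:{bid}"
        )
        out.append((bid, schedule_blocks[bid], res))
    return out


def anova_on_correlations(rs, classes) -> AnovaResult:
    """One-way fixed-effects ANOVA of correlation values grouped by IS class."""
    rs = _as_clean_vector(rs, "rs")
    classes = [str(c.value) if isinstance(c, ISClass) else str(c) for c in classes]
    if len(classes) != rs.size:
        raise ConfigurationError("rs and classes must have equal length")
    groups: dict[str, list[float]] = {}
    for v, c in zip(rs, classes):
        groups.setdefault(c, []).append(float(v))
    if len(groups) < 2:
        raise DegenerateDataError("ANOVA needs at least 2 groups")
    for name, vals in groups.items():
        if len(vals) < 2:
            raise DegenerateDataError(f"group {name} has fewer than 2 values")
    arrays = [np.asarray(v) for v in groups.values()]
    F, p = sps.f_oneway(*arrays)
    return AnovaResult(
        F=float(F),
        p=float(p),
        group_means={name: float(np.mean(v)) for name, v in groups.items()},
        df_between=len(groups) - 1,
        df_within=int(rs.size - len(groups)),
    )


def bonferroni_pairwise(rs, classes, family_alpha: float = 0.05) -> list[PairwiseComparison]:
    """All pairwise two-sample t comparisons at per-test alpha = family / n_pairs."""
    rs = _as_clean_vector(rs, "rs")
    classes = [str(c.value) if isinstance(c, ISClass) else str(c) for c in classes]
    groups: dict[str, list[float]] = {}
    for v, c in zip(rs, classes):
        groups.setdefault(c, []).append(float(v))
    for name, vals in groups.items():
        if len(vals) < 2:
            raise DegenerateDataError(f"group {name} has fewer than 2 values")
    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    alpha = family_alpha / len(pairs)
    out = []
    for a, b in pairs:
        t, p = sps.ttest_ind(groups[a], groups[b], equal_var=True)
        out.append(
            PairwiseComparison(
                pair=(a, b),
                mean_difference=float(np.mean(groups[a]) - np.mean(groups[b])),
                p=float(p),
                per_test_alpha=alpha,
                significant=bool(p < alpha),
            )
        )
    return out


# -- repeated hold-out validation ---------------------------------------


def validation_predictors(metrics: pd.DataFrame) -> pd.DataFrame:
    """Per-participant median distances in SHORT/MEDIUM/LONG scopes.

    The three-predictor design used by the hold-out validation.  Indexed by
    participant id; participants missing any class median are dropped with
    the count logged.
    """
    sub = metrics[metrics["scope"].isin(["SHORT", "MEDIUM", "LONG"])]
    wide = sub.pivot(index="participant_id", columns="scope", values="median")
    wide = wide[["SHORT", "MEDIUM", "LONG"]]
    n_dropped = int(wide.isna().any(axis=1).sum())
    if n_dropped:
        logger.info("validation_predictors: dropped %d participants with a "
                    "missing class median", n_dropped)
    return wide.dropna()


def repeated_validation(
    predictors: pd.DataFrame,
    swan: dict[str, float],
    train_fraction: float = 0.75,
    reps: int = 10_000,
    seed: int | np.random.SeedSequence = 0,
) -> ValidationResult:
    """Repeated random hold-out evaluation of the 3-predictor linear model.

    Each repetition splits the cohort into disjoint train/test sets
    (``train_n = round(train_fraction * n)``), fits OLS with intercept on
    the training rows and correlates the model's test-set predictions with
    the observed SWAN totals; the raw Pearson r values are averaged across
    repetitions.  Repetitions whose test responses or predictions are
    constant are excluded, with the count reported.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ConfigurationError("train_fraction must be in (0, 1)")
    if reps < 1:
        raise ConfigurationError("reps must be >= 1")
    X = predictors.to_numpy(dtype=float)
    y = np.asarray([swan[p] for p in predictors.index], dtype=float)
    n = X.shape[0]
    if n < 8:
        raise DegenerateDataError("repeated validation needs a cohort of >= 8")
    train_n = round(train_fraction * n)
    test_n = n - train_n
    if train_n <= X.shape[1] + 1 or test_n < 3:
        raise DegenerateDataError("split leaves too few rows to fit or score")
    design = np.column_stack([np.ones(n), X])
    rng = np.random.default_rng(seed)
    rs: list[float] = []
    n_excluded = 0
    for _ in range(reps):
        perm = rng.permutation(n)
        tr, te = perm[:train_n], perm[train_n:]
        beta, *_ = np.linalg.lstsq(design[tr], y[tr], rcond=None)
        pred = design[te] @ beta
        if np.ptp(y[te]) == 0 or np.ptp(pred) == 0:
            n_excluded += 1
            continue
        rs.append(float(np.corrcoef(pred, y[te])[0, 1]))
    if n_excluded:
        logger.info("repeated_validation: excluded %d degenerate repetitions",
                    n_excluded)
    if not rs:
        raise DegenerateDataError("all repetitions were degenerate")
    return ValidationResult(
        mean_r=float(np.mean(rs)),
        per_rep_r=tuple(rs),
        reps=reps,
        train_fraction=train_fraction,
        train_n=train_n,
        test_n=test_n,
        n_excluded=n_excluded,
    )


def fisher_z_mean(rs) -> float:
    """Fisher-z averaged correlation (optional alternative to the raw mean)."""
    arr = np.clip(np.asarray(rs, dtype=float), -1 + 1e-15, 1 - 1e-15)
    return float(np.tanh(np.mean(np.arctanh(arr))))
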