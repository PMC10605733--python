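"""Cohort statistics: linear fits, repeated-split logistic ROC/AUC, sweeps.

Univariate and two-predictor ordinary-least-squares fits of blob
features to the ordinal grade report signed Pearson correlations,
per-coefficient p-values (from the joint fit, when multivariate), the
multiple correlation R12 = sqrt(R^2) and the overall F-test
probability.  Classification of clinically significant disease uses
unpenalised logistic regression evaluated over repeated random
train/test splits (70/30 by default, 1000 repetitions), summarised by
the mean AUC and the 2.5/97.5 percentile confidence interval of the
AUC distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve

FEATURE_COLUMNS = ("max_blob_vol_ml", "ave_blob_vol_ml", "max_blob_ecc")


class StatsError(ValueError):
    pass


@dataclass
class FitResult:
    """Linear-fit summary shared by the uni- and multivariate paths.

    ``r`` maps each predictor name to its *signed univariate* Pearson
    correlation with the response; ``p_values`` are the coefficient
    t-test p-values from the fitted model (the joint model, when more
    than one predictor is present).
    """

    coefficients: dict[str, float]
    conf_ints: dict[str, tuple[float, float]]
    r: dict[str, float]
    p_values: dict[str, float]
    r_multiple: float
    f_pvalue: float
    n: int

    def __post_init__(self) -> None:
        for name, val in self.r.items():
            if abs(val) > 1 + 1e-9:
                raise StatsError(f"|R| > 1 for {name}")
        if not -1e-9 <= self.r_multiple <= 1 + 1e-9:
            raise StatsError("multiple correlation outside [0, 1]")


@dataclass
class RocResult:
    """AUC distribution over repeated splits with a percentile CI."""

    aucs: np.ndarray
    mean_auc: float
    ci_95: tuple[float, float]
    reps: int
    seed: int | None
    n_redrawn: int = 0

    @classmethod
    def from_aucs(cls, aucs: np.ndarray, seed: int | None,
                  n_redrawn: int = 0) -> "RocResult":
        aucs = np.asarray(aucs, dtype=float)
        lo, hi = np.percentile(aucs, [2.5, 97.5])
        return cls(aucs=aucs, mean_auc=float(aucs.mean()),
                   ci_95=(float(lo), float(hi)), reps=len(aucs),
                   seed=seed, n_redrawn=n_redrawn)


# ---------------------------------------------------------------------------
# linear fits
# ---------------------------------------------------------------------------

def _as_1d(name: str, x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise StatsError(f"{name} contains non-finite values")
    return x


def fit_univariate(x, y, name: str = "x") -> FitResult:
    """OLS fit of ``y`` on ``x`` with signed Pearson R and slope t-test p."""
    x, y = _as_1d(name, x), _as_1d("y", y)
    if len(x) != len(y):
        raise StatsError("x and y must have equal length")
    if len(x) < 3:
        raise StatsError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise StatsError(f"predictor {name!r} is constant")
    model = sm.OLS(y, sm.add_constant(x)).fit()
    ci = model.conf_int(alpha=0.05)
    r = float(sps.pearsonr(x, y).statistic) if np.ptp(y) > 0 else 0.0
    return FitResult(
        coefficients={"intercept": float(model.params[0]), name: float(model.params[1])},
        conf_ints={"intercept": tuple(ci[0]), name: tuple(ci[1])},
        r={name: r},
        p_values={name: float(model.pvalues[1])},
        r_multiple=float(np.sqrt(max(model.rsquared, 0.0))),
        f_pvalue=float(model.f_pvalue),
        n=len(x),
    )


def fit_multivariate(x1, x2, y, names: tuple[str, str] = ("x1", "x2")) -> FitResult:
    """Joint OLS on two predictors.

    R1/R2 are the signed univariate Pearson correlations of each
    predictor with ``y``; their p-values come from the joint fit's
    coefficient t-tests; R12 is the multiple correlation of the joint
    fit and ``f_pvalue`` its overall F-test probability.
    """
    x1, x2, y = _as_1d(names[0], x1), _as_1d(names[1], x2), _as_1d("y", y)
    n = len(y)
    if not (len(x1) == len(x2) == n):
        raise StatsError("predictors and response must have equal length")
    if n < 4:
        raise StatsError("need at least 4 observations")
    design = sm.add_constant(np.column_stack([x1, x2]))
    if np.linalg.matrix_rank(design) < 3:
        raise StatsError("collinear predictors: design matrix is rank deficient")
    model = sm.OLS(y, design).fit()
    ci = model.conf_int(alpha=0.05)
    if np.ptp(y) > 0:
        r1 = float(sps.pearsonr(x1, y).statistic)
        r2 = float(sps.pearsonr(x2, y).statistic)
    else:
        r1 = r2 = 0.0
    return FitResult(
        coefficients={
            "intercept": float(model.params[0]),
            names[0]: float(model.params[1]),
            names[1]: float(model.params[2]),
        },
        conf_ints={
            "intercept": tuple(ci[0]),
            names[0]: tuple(ci[1]),
            names[1]: tuple(ci[2]),
        },
        r={names[0]: r1, names[1]: r2},
        p_values={
            names[0]: float(model.pvalues[1]),
            names[1]: float(model.pvalues[2]),
        },
        r_multiple=float(np.sqrt(max(model.rsquared, 0.0))),
        f_pvalue=float(model.f_pvalue),
        n=n,
    )


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------

def roc_auc(scores, labels) -> float:
    """Area under the ROC curve (ties contribute one half)."""
    scores = _as_1d("scores", scores)
    labels = np.asarray(labels).astype(bool).ravel()
    if labels.all() or not labels.any():
        raise StatsError("ROC needs both classes present")
    return float(roc_auc_score(labels, scores))


def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """(false positive rate, true positive rate) points of the ROC curve."""
    fpr, tpr, _ = roc_curve(np.asarray(labels).astype(int), _as_1d("scores", scores))
    return fpr, tpr


def logistic_split_auc(features, labels, train_frac: float = 0.7,
                       reps: int = 1000, seed: int | None = None,
                       max_redraws: int = 1000) -> RocResult:
    """Repeated random-split logistic classification, AUC per repetition.

    Each repetition draws a train/test split, fits an unpenalised
    logistic model on the training part and scores the AUC on the test
    part.  Splits whose train or test portion lacks one of the classes
    are redrawn (counted in ``n_redrawn``).  The same seed reproduces
    the whole AUC distribution.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(labels).astype(bool).ravel()
    n = len(y)
    if X.shape[0] != n:
        raise StatsError("features and labels must have equal length")
    if y.all() or not y.any():
        raise StatsError("need both classes in the cohort")
    if reps < 1:
        raise StatsError("reps must be >= 1")
    n_train = int(round(train_frac * n))
    if not 0 < n_train < n:
        raise StatsError(f"train fraction {train_frac} leaves an empty set")

    rng = np.random.default_rng(seed)
    aucs = np.empty(reps)
    redrawn = 0
    for rep in range(reps):
        for _ in range(max_redraws):
            perm = rng.permutation(n)
            tr, te = perm[:n_train], perm[n_train:]
            if 0 < y[tr].sum() < len(tr) and 0 < y[te].sum() < len(te):
                break
            redrawn += 1
        else:
            raise StatsError("could not draw a split with both classes in both sets")
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=1000)
        with warnings.catch_warnings():
            # separable training data: lbfgs stops at max_iter with
            # large-but-finite coefficients, which is the intended cap
            warnings.simplefilter("ignore", ConvergenceWarning)
            clf.fit(X[tr], y[tr])
        aucs[rep] = roc_auc(clf.decision_function(X[te]), y[te])
    return RocResult.from_aucs(aucs, seed=seed, n_redrawn=redrawn)


# ---------------------------------------------------------------------------
# sweeps and summaries
# ---------------------------------------------------------------------------

def threshold_sweep(features: pd.DataFrame, cohort: pd.DataFrame,
                    auc_reps: int = 1000, train_frac: float = 0.7,
                    seed: int | None = None) -> pd.DataFrame:
    """Univariate R/p and split-AUC for every (threshold, feature) pair.

    ``features`` needs columns ``patient_id``, ``threshold`` and the
    three blob features; ``cohort`` needs ``patient_id``, ``isup_grade``
    and ``cspca``.  Returns one row per (threshold, feature).
    """
    merged = features.merge(cohort, on="patient_id", validate="many_to_one")
    rows = []
    rng = np.random.default_rng(seed)
    for thr in sorted(merged["threshold"].unique()):
        sub = merged[merged["threshold"] == thr]
        for feat in FEATURE_COLUMNS:
            x = sub[feat].to_numpy(dtype=float)
            y = sub["isup_grade"].to_numpy(dtype=float)
            labels = sub["cspca"].to_numpy(dtype=bool)
            row = {"threshold": thr, "feature": feat, "n": len(sub)}
            try:
                fit = fit_univariate(x, y, name=feat)
                row["r"] = fit.r[feat]
                row["p_value"] = fit.p_values[feat]
                row["slope"] = fit.coefficients[feat]
            except StatsError:
                row.update(r=np.nan, p_value=np.nan, slope=np.nan)
            try:
                roc = logistic_split_auc(
                    x, labels, train_frac=train_frac, reps=auc_reps,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                row["auc"] = roc.mean_auc
                row["auc_ci_low"], row["auc_ci_high"] = roc.ci_95
            except StatsError:
                row.update(auc=np.nan, auc_ci_low=np.nan, auc_ci_high=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def optimal_threshold(sweep: pd.DataFrame, feature: str) -> float:
    """Threshold with the highest correlation coefficient for a feature."""
    sub = sweep[sweep["feature"] == feature].dropna(subset=["r"])
    if sub.empty:
        raise StatsError(f"no usable sweep rows for feature {feature!r}")
    return float(sub.loc[sub["r"].idxmax(), "threshold"])


def grade_distribution_summary(distribution: pd.DataFrame) -> dict[str, float]:
    """Patient-count-weighted summary of an ISUP grade distribution.

    ``distribution`` has columns ``isup_grade`` and ``patients``.
    Returns the total patient count and the count-weighted mean grade.
    """
    grades = distribution["isup_grade"].to_numpy(dtype=float)
    counts = distribution["patients"].to_numpy(dtype=float)
    if np.any(counts < 0) or counts.sum() <= 0:
        raise StatsError("invalid patient counts")
    total = counts.sum()
    return {
        "total_patients": float(total),
        "mean_grade": float((grades * counts).sum() / total),
    }


def load_example_grade_distribution() -> pd.DataFrame:
    """Bundled per-grade patient counts of a published 42-patient cohort."""
    with resources.files("bpspect.data").joinpath(
        "example_isup_distribution.csv"
    ).open() as fh:
        return pd.read_csv(fh)
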