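"""Feature-selection routes: univariate screening, penalized-coefficient
thresholding, recursive feature elimination, and forest importances.

Each route returns a :class:`SelectionResult` with ordered feature names and
per-feature scores, so downstream modeling can consume any of them
interchangeably.  Penalized fits standardize features first — an absolute
coefficient cut at 0.5 is only meaningful on a common scale.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFE, RFECV
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import StandardScaler

from .features import FeatureMatrix


@dataclass(frozen=True)
class SelectionConfig:
    screen_alpha: float = 0.05
    coef_threshold: float = 0.5
    rfe_target: int | str = "auto"
    method: str = "ridge"  # route feeding the modeling stage
    # Inverse regularization per penalized route.  L2 spreads weight across
    # correlated features and shrinks every coefficient, so a fixed |coef|
    # cut needs a weaker ridge penalty to stay comparably selective; the L1
    # route is kept strongly sparse.
    ridge_C: float = 10.0
    lasso_C: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.screen_alpha < 1:
            raise ValueError("screen_alpha must lie in (0, 1)")
        if self.coef_threshold < 0:
            raise ValueError("coef_threshold must be >= 0")

    def hash(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class SelectionResult:
    method: str
    features: list[str]
    scores: pd.Series  # per selected feature: p-value, |coef|, rank or importance
    extra: dict = field(default_factory=dict)
    config_hash: str = ""

    def __len__(self) -> int:
        return len(self.features)


def _xy(fm: FeatureMatrix | tuple) -> tuple[pd.DataFrame, np.ndarray]:
    if isinstance(fm, FeatureMatrix):
        return fm.X, fm.y.to_numpy(dtype=int)
    X, y = fm
    return X, np.asarray(y, dtype=int)


def _require_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2 or min(np.bincount(y)) < 2:
        raise ValueError("both classes with >= 2 rows are required")


def univariate_screen(fm: FeatureMatrix, alpha: float = 0.05) -> SelectionResult:
    """Two-sample screening of every feature against the case/control label.

    Both the independent-sample t-test and the Mann-Whitney U p-values are
    computed; the t-test drives the selection gate at ``alpha``.  Zero-
    variance features are excluded and flagged as undefined.  No multiple-
    testing correction is applied.
    """
    X, y = _xy(fm)
    _require_two_classes(y)
    a, b = X[y == 1].to_numpy(), X[y == 0].to_numpy()

    with warnings.catch_warnings():
        # constant columns trip precision warnings; they are flagged below
        warnings.simplefilter("ignore", RuntimeWarning)
        t_stat, t_p = stats.ttest_ind(a, b, axis=0)
    undefined = [
        c for c, v in zip(X.columns, np.nanstd(X.to_numpy(), axis=0)) if v == 0
    ]
    u_p = np.full(X.shape[1], np.nan)
    for j in range(X.shape[1]):
        if X.columns[j] in undefined:
            continue
        try:
            u_p[j] = stats.mannwhitneyu(a[:, j], b[:, j]).pvalue
        except ValueError:
            u_p[j] = np.nan

    table = pd.DataFrame(
        {"t_p": t_p, "mwu_p": u_p}, index=X.columns
    )
    mask = (table["t_p"] < alpha) & ~table.index.isin(undefined)
    selected = table[mask].sort_values("t_p")
    return SelectionResult(
        method="t_screen",
        features=list(selected.index),
        scores=selected["t_p"],
        extra={"table": table, "undefined": undefined, "alpha": alpha},
    )


def _penalized_logistic(penalty: str, C: float, seed: int) -> LogisticRegression:
    """L2 (ridge) or L1 (lasso) logistic classifier, across sklearn's old
    (penalty=) and new (l1_ratio=) parameterizations."""
    kw = dict(C=C, solver="liblinear", random_state=seed, max_iter=2000)
    if penalty == "ridge":
        return LogisticRegression(**kw)  # L2 is the default penalty
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        return LogisticRegression(penalty="l1", **kw)


def penalized_selection(
    fm: FeatureMatrix,
    penalty: str = "ridge",
    threshold: float = 0.5,
    C: float | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Features whose standardized |coefficient| clears the threshold.

    A logistic classifier with an L2 (ridge) or L1 (lasso) penalty is fitted
    on standardized features; selected features are ordered by decreasing
    absolute coefficient.
    """
    if penalty not in ("ridge", "lasso"):
        raise ValueError(f"penalty must be 'ridge' or 'lasso', got {penalty!r}")
    if C is None:
        C = SelectionConfig.ridge_C if penalty == "ridge" else SelectionConfig.lasso_C
    X, y = _xy(fm)
    sd = X.to_numpy().std(axis=0)
    if np.all(sd == 0):
        raise ValueError("all features are constant")
    keep = X.columns[sd > 0]
    Z = StandardScaler().fit_transform(X[keep])
    clf = _penalized_logistic(penalty, C, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        warnings.simplefilter("ignore", UserWarning)
        clf.fit(Z, y)
    coefs = pd.Series(np.abs(clf.coef_[0]), index=keep)
    selected = coefs[coefs >= threshold].sort_values(ascending=False)
    return SelectionResult(
        method=penalty,
        features=list(selected.index),
        scores=selected,
        extra={"coefficients": coefs, "threshold": threshold},
    )


def rfe_selection(
    fm: FeatureMatrix,
    target: int | str = "auto",
    estimator=None,
    seed: int = 0,
) -> SelectionResult:
    """Recursive feature elimination down to ``target`` features.

    The default estimator is the ridge-penalized logistic classifier, one
    feature dropped per step; ``target="auto"`` picks the count by
    cross-validated score (RFECV).
    """
    X, y = _xy(fm)
    if isinstance(target, int):
        if target < 1:
            raise ValueError("target must be >= 1")
        if target > X.shape[1]:
            raise ValueError("target exceeds the number of features")
    est = estimator or _penalized_logistic("ridge", 1.0, seed)
    Z = pd.DataFrame(
        StandardScaler().fit_transform(X), columns=X.columns, index=X.index
    )
    if target == "auto":
        sel = RFECV(est, step=1, cv=5, scoring="roc_auc").fit(Z, y)
    else:
        sel = RFE(est, n_features_to_select=target, step=1).fit(Z, y)
    ranks = pd.Series(sel.ranking_, index=X.columns)
    chosen = ranks[ranks == 1].index
    # order the survivors by |coefficient| of a final fit
    final = est.fit(Z[chosen], y)
    order = pd.Series(np.abs(final.coef_[0]), index=chosen).sort_values(
        ascending=False
    )
    return SelectionResult(
        method="rfe",
        features=list(order.index),
        scores=ranks[order.index],
        extra={"ranking": ranks},
    )


def forest_importance(fm: FeatureMatrix, seed: int = 0, n_estimators: int = 200) -> SelectionResult:
    """Random-forest variable importances under two split criteria.

    Returns Gini-impurity and information-gain (entropy) importance
    rankings, each normalized to sum to 1; the Gini ranking orders the
    result's feature list.
    """
    X, y = _xy(fm)
    _require_two_classes(y)
    rankings = {}
    for criterion in ("gini", "entropy"):
        rf = RandomForestClassifier(
            n_estimators=n_estimators, criterion=criterion, random_state=seed, n_jobs=1
        ).fit(X, y)
        imp = pd.Series(rf.feature_importances_, index=X.columns)
        total = imp.sum()
        rankings[criterion] = (imp / total if total > 0 else imp).sort_values(
            ascending=False
        )
    gini = rankings["gini"]
    return SelectionResult(
        method="forest",
        features=list(gini.index),
        scores=gini,
        extra={"gini": rankings["gini"], "entropy": rankings["entropy"]},
    )


def select_features(
    fm: FeatureMatrix, cfg: SelectionConfig
) -> dict[str, SelectionResult]:
    """Run every route; the ``cfg.method`` entry feeds modeling."""
    cfg.validate()
    results = {
        "t_screen": univariate_screen(fm, cfg.screen_alpha),
        "ridge": penalized_selection(
            fm, "ridge", cfg.coef_threshold, C=cfg.ridge_C, seed=cfg.seed
        ),
        "lasso": penalized_selection(
            fm, "lasso", cfg.coef_threshold, C=cfg.lasso_C, seed=cfg.seed
        ),
        "forest": forest_importance(fm, seed=cfg.seed),
    }
    rfe_target = cfg.rfe_target
    if isinstance(rfe_target, int):
        rfe_target = min(rfe_target, fm.X.shape[1])
    results["rfe"] = rfe_selection(fm, target=rfe_target, seed=cfg.seed)
    for r in results.values():
        r.config_hash = cfg.hash()
    return results
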