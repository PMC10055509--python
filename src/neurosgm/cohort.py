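"""Cohort-level statistics, classification and parameter ablation.

Group comparison of fitted parameters uses a fixed-effects linear model with
age as a covariate (outcome ~ group + age); adjusted (least-squares) means
are evaluated at the pooled mean age and the group contrast is tested with
an unpaired t-test on the group coefficient, Bonferroni-corrected over the
seven-parameter family.  Cognition regressions are ordinary least squares on
patient rows.  Classification is a random forest under nested stratified
cross-validation (outer 5-fold repeated, inner 5-fold tuning max depth
only).  The ablation experiment re-fits subjects while freeing parameters
one at a time in classifier-importance order, the rest clamped to the
cohort mean of the fitted values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import (
    accuracy_score,
    confusion_matrix,
    f1_score,
    precision_score,
    recall_score,
    roc_auc_score,
)
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .connectome import ConnectomeGraph
from .fitting import FitConfig, _subject_seed, fit_subject
from .sgm import PARAM_NAMES, RegionalSpectrum, SGMParameters

logger = logging.getLogger(__name__)

__all__ = [
    "PARAM_REPORT_COLUMNS",
    "GroupComparisonRow",
    "ClassifyConfig",
    "ClassificationReport",
    "AblationResult",
    "adjusted_group_compare",
    "cohens_d",
    "ks_group_test",
    "regress_cognition",
    "classify_groups",
    "parameter_ablation",
]

#: reporting-unit column names of the seven optimized parameters
PARAM_REPORT_COLUMNS = (
    "tau_G_ms", "tau_e_ms", "tau_i_ms", "g_ei", "g_ii", "alpha", "speed",
)

_REPORT_TO_NATURAL = {
    "tau_G_ms": ("tau_G", 1e-3), "tau_e_ms": ("tau_e", 1e-3),
    "tau_i_ms": ("tau_i", 1e-3), "g_ei": ("g_ei", 1.0),
    "g_ii": ("g_ii", 1.0), "alpha": ("alpha", 1.0), "speed": ("speed", 1.0),
}


def cohens_d(x, y) -> float:
    """Effect size (mean x - mean y) / pooled SD (n-1 denominators)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    pooled_var = (
        (x.size - 1) * x.var(ddof=1) + (y.size - 1) * y.var(ddof=1)
    ) / (x.size + y.size - 2)
    if pooled_var == 0:
        warnings.warn("zero pooled SD; Cohen's d undefined", RuntimeWarning)
        return float("nan")
    return float((x.mean() - y.mean()) / np.sqrt(pooled_var))


def ks_group_test(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 5 or y.size < 5:
        raise ValueError("each sample needs at least 5 values")
    res = scipy.stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


@dataclass
class GroupComparisonRow:
    """Covariate-adjusted comparison of one parameter between groups."""

    parameter: str
    mean_control: float
    ci_control: tuple[float, float]
    mean_ad: float
    ci_ad: tuple[float, float]
    t_stat: float
    p_raw: float
    p_adjusted: float
    cohens_d: float
    age_adjusted: bool = True

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d["ci_control"] = list(self.ci_control)
        d["ci_ad"] = list(self.ci_ad)
        return d


def adjusted_group_compare(
    table: pd.DataFrame,
    parameter: str,
    m_tests: int = 7,
    group_col: str = "group",
    ad_label: str = "AD",
    ci_level: float = 0.95,
) -> GroupComparisonRow:
    """Linear model ``parameter ~ group + age`` with least-squares means.

    Adjusted group means (and their CIs) are evaluated at the pooled mean
    age; the group difference is tested by an unpaired t-test on the group
    coefficient and Bonferroni-corrected over ``m_tests`` parameters.
    Cohen's d is computed on the raw group values.  Falls back to an
    unadjusted comparison with a warning when age is constant.
    """
    df = table.dropna(subset=[parameter, "age"])
    is_ad = (df[group_col] == ad_label).to_numpy(dtype=float)
    if is_ad.sum() == 0 or is_ad.sum() == len(df):
        raise ValueError("both groups must be non-empty")
    y = df[parameter].to_numpy(dtype=float)
    age = df["age"].to_numpy(dtype=float)

    age_adjusted = age.std() > 0
    if not age_adjusted:
        warnings.warn("age is constant; falling back to unadjusted comparison",
                      RuntimeWarning)
        X = np.column_stack([np.ones_like(y), is_ad])
    else:
        X = np.column_stack([np.ones_like(y), is_ad, age])
    fit = sm.OLS(y, X).fit()
    t_stat = float(fit.tvalues[1])
    p_raw = float(fit.pvalues[1])

    age_bar = age.mean()
    rows = []
    for grp in (0.0, 1.0):
        c = np.array([1.0, grp] if not age_adjusted else [1.0, grp, age_bar])
        mean = float(c @ fit.params)
        se = float(np.sqrt(c @ fit.cov_params() @ c))
        tcrit = scipy.stats.t.ppf(0.5 + ci_level / 2, df=fit.df_resid)
        rows.append((mean, (mean - tcrit * se, mean + tcrit * se)))

    d = cohens_d(y[is_ad == 0], y[is_ad == 1])
    return GroupComparisonRow(
        parameter=parameter,
        mean_control=rows[0][0], ci_control=rows[0][1],
        mean_ad=rows[1][0], ci_ad=rows[1][1],
        t_stat=t_stat, p_raw=p_raw,
        p_adjusted=min(1.0, p_raw * m_tests),
        cohens_d=d, age_adjusted=age_adjusted,
    )


def regress_cognition(
    table: pd.DataFrame,
    outcome: str,
    predictors: list[str],
    include_age: bool = False,
    group_col: str = "group",
    ad_label: str = "AD",
) -> dict:
    """OLS regression of a cognition score on fitted parameters (patients).

    Reports per-predictor slopes with raw and Bonferroni-adjusted p-values
    (m = number of parameters tested), plus model r, adjusted r-squared and
    the F statistic.
    """
    df = table[table[group_col] == ad_label].dropna(
        subset=[outcome] + predictors + (["age"] if include_age else [])
    )
    cols = list(predictors) + (["age"] if include_age else [])
    if len(df) < len(cols) + 2:
        raise ValueError(
            f"{len(df)} rows cannot support {len(cols)} predictors"
        )
    X = sm.add_constant(df[cols].to_numpy(dtype=float))
    y = df[outcome].to_numpy(dtype=float)
    fit = sm.OLS(y, X).fit()
    m = len(predictors)
    coef = {}
    for i, name in enumerate(cols, start=1):
        p = float(fit.pvalues[i])
        coef[name] = {
            "slope": float(fit.params[i]),
            "p_raw": p,
            "p_adjusted": min(1.0, p * m) if name in predictors else p,
        }
    return {
        "outcome": outcome,
        "n": int(len(df)),
        "coefficients": coef,
        "model_r": float(np.sqrt(max(fit.rsquared, 0.0))),
        "adjusted_r2": float(fit.rsquared_adj),
        "f_stat": float(fit.fvalue),
        "f_pvalue": float(fit.f_pvalue),
    }


@dataclass
class ClassifyConfig:
    """Nested-CV random-forest settings."""

    n_folds: int = 5
    repeats: int = 100
    max_depth_grid: tuple = (None, 2, 3, 4)
    n_estimators: int = 100
    seed: int = 0


@dataclass
class ClassificationReport:
    auroc_mean: float
    auroc_sd: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    feature_importances: dict[str, float]
    confusion: np.ndarray
    config: ClassifyConfig
    features: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auroc_mean": self.auroc_mean, "auroc_sd": self.auroc_sd,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
            "feature_importances": self.feature_importances,
            "confusion": self.confusion.tolist(),
            "features": self.features,
            "config": {
                "n_folds": self.config.n_folds,
                "repeats": self.config.repeats,
                "max_depth_grid": list(self.config.max_depth_grid),
                "n_estimators": self.config.n_estimators,
                "seed": self.config.seed,
            },
        }

    def importance_order(self) -> list[str]:
        """Feature names sorted by decreasing averaged importance."""
        return sorted(self.feature_importances,
                      key=self.feature_importances.get, reverse=True)


def classify_groups(
    table: pd.DataFrame,
    features: list[str],
    config: ClassifyConfig | None = None,
    group_col: str = "group",
    ad_label: str = "AD",
) -> ClassificationReport:
    """Random-forest classification of the two groups under nested CV.

    Outer 5-fold stratified CV repeated ``config.repeats`` times; within
    each training split an inner 5-fold grid search tunes only the maximum
    tree depth.  Tuning never sees the held-out fold.  AUROC is computed per
    repeat on the pooled outer-fold scores; feature importances are averaged
    over all tuned forests and renormalized to sum to 1.
    """
    config = config or ClassifyConfig()
    df = table.dropna(subset=features)
    X = df[features].to_numpy(dtype=float)
    y = (df[group_col] == ad_label).to_numpy(dtype=int)
    if len(np.unique(y)) != 2:
        raise ValueError("need both groups present")

    aurocs, accs, precs, recs, f1s = [], [], [], [], []
    importances = np.zeros(len(features))
    n_fits = 0
    pooled_confusion = np.zeros((2, 2), dtype=int)
    for rep in range(config.repeats):
        rep_seed = (config.seed + rep) % (2 ** 31)
        outer = StratifiedKFold(config.n_folds, shuffle=True,
                                random_state=rep_seed)
        scores = np.empty_like(y, dtype=float)
        preds = np.empty_like(y)
        for train, test in outer.split(X, y):
            # inner folds cannot exceed the smallest class in the training
            # split; only relevant for very small cohorts
            n_inner = int(min(config.n_folds, np.bincount(y[train]).min()))
            inner = StratifiedKFold(max(n_inner, 2), shuffle=True,
                                    random_state=rep_seed)
            search = GridSearchCV(
                RandomForestClassifier(
                    n_estimators=config.n_estimators, random_state=rep_seed
                ),
                {"max_depth": list(config.max_depth_grid)},
                cv=inner, scoring="roc_auc",
            )
            search.fit(X[train], y[train])
            model = search.best_estimator_
            scores[test] = model.predict_proba(X[test])[:, 1]
            preds[test] = model.predict(X[test])
            importances += model.feature_importances_
            n_fits += 1
        aurocs.append(roc_auc_score(y, scores))
        accs.append(accuracy_score(y, preds))
        precs.append(precision_score(y, preds, zero_division=0))
        recs.append(recall_score(y, preds, zero_division=0))
        f1s.append(f1_score(y, preds, zero_division=0))
        pooled_confusion += confusion_matrix(y, preds, labels=[0, 1])

    importances /= n_fits
    total = importances.sum()
    if total > 0:
        importances = importances / total
    return ClassificationReport(
        auroc_mean=float(np.mean(aurocs)), auroc_sd=float(np.std(aurocs)),
        accuracy=float(np.mean(accs)), precision=float(np.mean(precs)),
        recall=float(np.mean(recs)), f1=float(np.mean(f1s)),
        feature_importances=dict(zip(features, importances.tolist())),
        confusion=pooled_confusion, config=config, features=list(features),
    )


@dataclass
class AblationResult:
    """Mean fit quality as parameters are freed in importance order.

    ``stages`` is an ordered list of (freed-parameter tuple, mean
    spectral_r, mean spatial_r) starting from the all-clamped stage and
    ending with all seven parameters free.
    """

    stages: list[tuple[tuple[str, ...], float, float]]
    per_subject: pd.DataFrame | None = None

    def spectral_gains(self) -> list[tuple[str, float]]:
        """Per-step increase in mean spectral correlation."""
        out = []
        for prev, cur in zip(self.stages, self.stages[1:]):
            out.append((cur[0][-1], cur[1] - prev[1]))
        return out


def cohort_mean_parameters(fits: pd.DataFrame) -> SGMParameters:
    """Pooled (both groups together) mean of fitted parameters."""
    kwargs = {}
    for col, (name, scale) in _REPORT_TO_NATURAL.items():
        kwargs[name] = float(fits[col].mean() * scale)
    return SGMParameters(**kwargs)


def parameter_ablation(
    subjects: dict[str, RegionalSpectrum],
    graph: ConnectomeGraph,
    cohort_mean_params: SGMParameters,
    importance_order: list[str],
    config: FitConfig | None = None,
) -> AblationResult:
    """Re-fit subjects while freeing parameters in importance order.

    Stage 0 frees nothing (all parameters clamped to the cohort mean);
    stage k frees the first k entries of ``importance_order``.  Per-subject
    seeds match ``fit_cohort``, so the final all-free stage coincides with
    independent full fits run under the same configuration.
    """
    config = config or FitConfig()
    order = [n for n in importance_order if n in PARAM_NAMES]
    if sorted(order) != sorted(PARAM_NAMES):
        raise ValueError(
            "importance_order must cover the seven optimized parameters"
        )
    stages: list[tuple[tuple[str, ...], float, float]] = []
    rows = []
    for k in range(len(order) + 1):
        free = tuple(order[:k])
        spec_rs, spat_rs = [], []
        for sid in sorted(subjects):
            sub_config = FitConfig(
                initial_guesses=config.initial_guesses,
                maxiter=config.maxiter, w=config.w,
                seed=_subject_seed(config.seed, sid), K=config.K,
                n_stages=config.n_stages, denom_tol=config.denom_tol,
                alpha_band=config.alpha_band,
            )
            try:
                res = fit_subject(subjects[sid], graph, sub_config,
                                  free=free, base=cohort_mean_params)
            except Exception as exc:  # noqa: BLE001 — record, don't abort
                logger.error("ablation fit failed for %s at stage %d: %s",
                             sid, k, exc)
                rows.append({"id": sid, "n_free": k, "error": str(exc)})
                continue
            spec_rs.append(res.spectral_r)
            spat_rs.append(res.spatial_r)
            rows.append({"id": sid, "n_free": k,
                         "free": ",".join(free) if free else "None",
                         "spectral_r": res.spectral_r,
                         "spatial_r": res.spatial_r,
                         "objective": res.objective})
        stages.append((free, float(np.nanmean(spec_rs)),
                       float(np.nanmean(spat_rs))))
    return AblationResult(stages=stages, per_subject=pd.DataFrame(rows))
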