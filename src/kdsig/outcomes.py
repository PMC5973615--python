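"""Outcome prediction: ROC/Youden thresholding, correlations, and logistic
regression for IVIG non-response.

The MDTH score is evaluated as a biomarker via the ROC curve (rank-based AUC
with half-credit for ties, DeLong asymptotic confidence interval) and an
optimal cutpoint chosen by Youden's J = sensitivity + specificity - 1.
Univariate/multivariable logistic regression quantifies independent
prediction of non-response, reporting odds ratios on a declared covariate
scale (e.g. MDTH per 1,000 units) with Wald 95% intervals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "RocResult",
    "LogisticFit",
    "SeparationError",
    "roc_auc",
    "youden_threshold",
    "spearman_corr",
    "logistic_regression",
]


@dataclass(frozen=True)
class RocPoint:
    threshold: float
    sensitivity: float
    specificity: float


@dataclass(frozen=True)
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    curve: tuple[RocPoint, ...]
    youden_threshold: float
    J: float


@dataclass(frozen=True)
class CovariateEffect:
    name: str
    odds_ratio: float
    ci_95: tuple[float, float]
    p: float


@dataclass(frozen=True)
class LogisticFit:
    effects: tuple[CovariateEffect, ...]
    n: int
    n_dropped: int
    outcome: str
    scaling: Mapping[str, float]

    def effect(self, name: str) -> CovariateEffect:
        for e in self.effects:
            if e.name == name:
                return e
        raise KeyError(name)


class SeparationError(RuntimeError):
    """Perfect separation: the MLE diverges; use exact or penalized logistic
    regression instead."""


def _delong_variance(pos: np.ndarray, neg: np.ndarray) -> float:
    """DeLong asymptotic variance of the rank AUC (midrank construction)."""
    m, n = len(pos), len(neg)
    all_v = np.concatenate([pos, neg])
    rx = stats.rankdata(all_v)
    r_pos = stats.rankdata(pos)
    r_neg = stats.rankdata(neg)
    # structural components
    v10 = (rx[:m] - r_pos) / n
    v01 = 1.0 - (rx[m:] - r_neg) / m
    s10 = np.var(v10, ddof=1) if m > 1 else 0.0
    s01 = np.var(v01, ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> RocResult:
    """ROC analysis with the positive class defined as label 1 (higher scores
    indicating the positive class).

    AUC uses the Mann-Whitney rank formulation with 0.5 credit for ties,
    which equals trapezoidal integration of the enumerated curve.  The curve
    enumerates every distinct score as a "predict positive when score >=
    threshold" rule, bracketed by the degenerate all/none rules.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if s.shape != y.shape:
        raise ValueError("scores and labels must align")
    if set(np.unique(y)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")
    pos, neg = s[y == 1], s[y == 0]
    ranks = stats.rankdata(s)
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    var = _delong_variance(pos, neg)
    half = 1.959963984540054 * math.sqrt(max(var, 0.0))
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    thresholds = np.concatenate([[np.inf], np.unique(s)[::-1]])
    curve = []
    for t in thresholds:
        pred = s >= t
        sens = float(np.sum(pred & (y == 1)) / n_pos)
        spec = float(np.sum(~pred & (y == 0)) / n_neg)
        curve.append(RocPoint(float(t), sens, spec))
    j_vals = [p.sensitivity + p.specificity - 1.0 for p in curve]
    j_max = max(j_vals)
    # ties broken toward higher specificity
    best = max(
        (p for p, j in zip(curve, j_vals) if j == j_max),
        key=lambda p: p.specificity,
    )
    return RocResult(
        auc=float(auc),
        auc_ci=ci,
        curve=tuple(curve),
        youden_threshold=best.threshold,
        J=float(j_max),
    )


def youden_threshold(roc: RocResult) -> tuple[float, float, float]:
    """(threshold, sensitivity, specificity) at the maximum of Youden's J."""
    for p in roc.curve:
        if p.threshold == roc.youden_threshold:
            return p.threshold, p.sensitivity, p.specificity
    raise ValueError("threshold not on curve")


def spearman_corr(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Midrank Spearman correlation with large-sample p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired data, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("rho undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def logistic_regression(
    outcome: Sequence[int] | pd.Series,
    covariates: pd.DataFrame,
    scaling: Mapping[str, float] | None = None,
    outcome_name: str = "outcome",
) -> LogisticFit:
    """Maximum-likelihood logistic fit with Wald 95% CIs on odds ratios.

    ``scaling`` divides each named covariate before fitting, so the reported
    odds ratio applies per that many original units (e.g. ``{"mdth": 1000}``
    reports the OR per 1,000 score units).  Rows with any missing covariate
    or outcome are dropped and counted.
    """
    y = pd.Series(np.asarray(outcome, dtype=float), index=covariates.index)
    df = covariates.copy().astype(float)
    scaling = dict(scaling or {})
    for name, div in scaling.items():
        if name not in df.columns:
            raise KeyError(f"scaling names unknown covariate {name!r}")
        df[name] = df[name] / div
    mask = df.notna().all(axis=1) & y.notna()
    n_dropped = int((~mask).sum())
    df, y = df[mask], y[mask]
    if set(np.unique(y)) - {0.0, 1.0} or len(np.unique(y)) < 2:
        raise ValueError("outcome must contain both binary classes")
    X = sm.add_constant(df, has_constant="add")
    with warnings.catch_warnings():
        warnings.simplefilter("error", category=RuntimeWarning)
        warnings.simplefilter("ignore", category=UserWarning)
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception as exc:  # PerfectSeparationError or overflow
            raise SeparationError(
                "logistic MLE failed to converge (possible complete separation); "
                "consider exact or penalized logistic regression"
            ) from exc
    if not fit.mle_retvals.get("converged", False) or np.any(
        np.abs(fit.params.drop("const")) > 50
    ):
        raise SeparationError(
            "logistic MLE failed to converge (possible complete separation); "
            "consider exact or penalized logistic regression"
        )
    conf = fit.conf_int()
    effects = []
    for name in df.columns:
        lo, hi = conf.loc[name]
        effects.append(
            CovariateEffect(
                name=name,
                odds_ratio=float(np.exp(fit.params[name])),
                ci_95=(float(np.exp(lo)), float(np.exp(hi))),
                p=float(fit.pvalues[name]),
            )
        )
    return LogisticFit(
        effects=tuple(effects),
        n=int(mask.sum()),
        n_dropped=n_dropped,
        outcome=outcome_name,
        scaling=scaling,
    )
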