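"""Diagnostic-accuracy statistics for comparing gas-exchange scores.

Univariable and multivariable logistic regression with Wald inference
(SPSS-style B / S.E. / Wald / df / Sig. / Exp(B) / 95% CI columns),
Box-Tidwell linearity-of-the-logit checks with a Bonferroni threshold,
ROC curves with Mann-Whitney AUROC and DeLong confidence intervals, and
Youden-index operating points with back-conversion of ODFlip thresholds
to the oxygen-deficit scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .physiology import od_from_odflip

__all__ = [
    "TermStats",
    "LogisticFit",
    "RocResult",
    "SeparationWarning",
    "fit_logistic",
    "odds_ratio_report",
    "wald_term_stats",
    "box_tidwell",
    "roc_curve",
    "youden_point",
    "od_threshold_report",
    "delong_paired_test",
    "compare_predictors",
]

_Z95 = 1.959963984540054  # two-sided 95% normal quantile
_MAX_ITER = 100
_COEF_TOL = 1e-8


class SeparationWarning(UserWarning):
    """Raised-as-flag marker; complete separation is reported, never hidden."""


@dataclass
class TermStats:
    """One model term in the B / S.E. / Wald / df / Sig. / Exp(B) layout."""

    name: str
    B: float
    SE: float
    wald: float
    df: int
    p: float
    exp_b: float
    ci95: tuple[float, float]
    t_value: float  # B / SE, the alternative software convention


@dataclass
class LogisticFit:
    """Maximum-likelihood logistic fit with per-term Wald inference."""

    terms: list[TermStats]
    model: str
    converged: bool
    n_obs: int
    deviance: float
    n_iter: int
    message: str = ""

    def term(self, name: str) -> TermStats:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(f"unknown term {name!r}; have {[t.name for t in self.terms]}")


@dataclass
class RocResult:
    """ROC curve, AUROC with DeLong CI, and the Youden operating point."""

    thresholds: np.ndarray  # original score scale, sorted
    sensitivity: np.ndarray
    one_minus_specificity: np.ndarray
    auroc: float
    auroc_ci95: tuple[float, float]
    youden_j: float
    optimal_threshold: float
    optimal_sensitivity: float
    optimal_one_minus_specificity: float
    direction: str = "higher"


def wald_term_stats(name: str, b: float, se: float, df: int = 1) -> TermStats:
    """Assemble the Wald-inference row for one coefficient.

    Exp(B) = exp(B); 95% CI = exp(B +/- 1.96*SE); Wald = (B/SE)^2 with a
    chi-square(df) p-value.
    """
    t = b / se if se > 0 else math.inf * np.sign(b)
    wald = t * t
    p = float(stats.chi2.sf(wald, df)) if np.isfinite(wald) else 0.0

    def _exp(x: float) -> float:
        try:
            return math.exp(x)
        except OverflowError:
            return math.inf

    return TermStats(
        name=name,
        B=b,
        SE=se,
        wald=wald,
        df=df,
        p=p,
        exp_b=_exp(b),
        ci95=(_exp(b - _Z95 * se), _exp(b + _Z95 * se)),
        t_value=t,
    )


def _validate_outcome(y: np.ndarray) -> None:
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome has a single class; both classes required")
    if not np.isin(classes, [0, 1]).all():
        raise ValueError("outcome must be binary 0/1")


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, float, int, bool, str]:
    """IRLS with step-halving; deviance is guaranteed non-increasing."""

    def deviance(beta: np.ndarray) -> float:
        eta = X @ beta
        # log-likelihood in the numerically stable logaddexp form
        ll = y * eta - np.logaddexp(0.0, eta)
        return -2.0 * float(np.sum(ll))

    n, k = X.shape
    beta = np.zeros(k)
    dev = deviance(beta)
    converged = False
    message = ""
    it = 0
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        w = np.maximum(w, 1e-12)
        XtW = X.T * w
        try:
            step = np.linalg.solve(XtW @ X, X.T @ (y - mu))
        except np.linalg.LinAlgError:
            message = "singular information matrix"
            break
        # halve the step until the deviance does not increase
        scale = 1.0
        new_dev = deviance(beta + step)
        while new_dev > dev + 1e-10 and scale > 1e-8:
            scale *= 0.5
            new_dev = deviance(beta + scale * step)
        beta = beta + scale * step
        dev = new_dev
        if np.max(np.abs(scale * step)) < _COEF_TOL:
            converged = True
            break

    mu = 1.0 / (1.0 + np.exp(-(X @ beta)))
    if not converged:
        if np.min(np.abs(mu - 0.5)) > 0.5 - 1e-6 or np.max(np.abs(beta)) > 25.0:
            message = message or "possible complete separation; fit not converged"
        else:
            message = message or f"no convergence in {_MAX_ITER} iterations"

    w = np.maximum(mu * (1.0 - mu), 1e-12)
    info = (X.T * w) @ X
    cov = np.linalg.pinv(info)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    return beta, se, dev, it, converged, message


def fit_logistic(
    table: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "needs_supplemental_o2",
) -> LogisticFit:
    """Fit outcome ~ intercept + predictors by maximum likelihood (IRLS).

    Convergence when the largest coefficient update falls below 1e-8 (at most
    100 iterations).  Complete separation is flagged through
    ``converged=False`` and a diagnostic message, never silently corrected.
    """
    predictors = list(predictors)
    y = table[outcome].to_numpy(dtype=float)
    _validate_outcome(y)
    n = len(table)
    if n <= len(predictors) + 1:
        raise ValueError("need more observations than model terms")
    X = np.column_stack(
        [np.ones(n)] + [table[p].to_numpy(dtype=float) for p in predictors]
    )
    beta, se, dev, n_iter, converged, message = _irls(X, y)
    names = ["Constant"] + predictors
    terms = [wald_term_stats(nm, float(b), float(s)) for nm, b, s in zip(names, beta, se)]
    formula = f"{outcome}~{'+'.join(predictors)}"
    return LogisticFit(
        terms=terms,
        model=formula,
        converged=converged,
        n_obs=n,
        deviance=dev,
        n_iter=n_iter,
        message=message,
    )


def odds_ratio_report(fit: LogisticFit, term: str) -> tuple[float, tuple[float, float]]:
    """Exp(B) with its 95% CI for one term; raises ``KeyError`` if unknown."""
    t = fit.term(term)
    return t.exp_b, t.ci95


def box_tidwell(
    table: pd.DataFrame,
    predictors: Sequence[str],
    outcome: str = "needs_supplemental_o2",
    shift: dict[str, float] | None = None,
) -> dict:
    """Linearity-of-the-logit check via x*ln(x) augmentation terms.

    Each continuous predictor must be strictly positive (apply ``shift`` to
    move it there, else an error is raised).  The model gains one x*ln(x)
    term per predictor; linearity is accepted when every augmentation term's
    Wald p-value is at least 0.05/k, where k counts all model terms
    (intercept + predictors + augmentation terms — k = 5 and threshold 0.01
    for the two-predictor model).
    """
    predictors = list(predictors)
    shift = shift or {}
    aug = table.copy()
    aug_names = []
    for p in predictors:
        x = aug[p].to_numpy(dtype=float) + shift.get(p, 0.0)
        if (x <= 0).any():
            raise ValueError(
                f"predictor {p!r} must be strictly positive for x*ln(x); "
                "provide a shift"
            )
        name = f"{p}_xlnx"
        aug[name] = x * np.log(x)
        aug[p] = x
        aug_names.append(name)

    fit = fit_logistic(aug, predictors + aug_names, outcome)
    k = 1 + len(predictors) + len(aug_names)
    threshold = 0.05 / k
    aug_p = {name: fit.term(name).p for name in aug_names}
    return {
        "augmentation_p": aug_p,
        "n_terms": k,
        "bonferroni_threshold": threshold,
        "linear_ok": all(p >= threshold for p in aug_p.values()),
        "fit": fit,
    }


def _delong_components(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    neg_sorted = np.sort(neg)
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / neg.size  # P(neg below pos), ties half
    pos_sorted = np.sort(pos)
    lo2 = np.searchsorted(pos_sorted, neg, side="left")
    hi2 = np.searchsorted(pos_sorted, neg, side="right")
    above = pos.size - hi2
    v01 = (above + 0.5 * (hi2 - lo2)) / pos.size  # P(pos above neg), ties half
    auc = float(np.mean(v10))
    return auc, v10, v01


def roc_curve(
    scores: Sequence[float],
    outcomes: Sequence[int],
    direction: str = "higher",
) -> RocResult:
    """ROC analysis of a continuous score against a binary outcome.

    ``direction='higher'`` means larger scores indicate the positive class
    ('lower' negates internally, thresholds stay on the original scale).
    AUROC is the Mann-Whitney concordance with half credit for ties (equal to
    the trapezoidal area under the empirical curve); its 95% CI uses DeLong's
    method.  The Youden operating point is attached.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    _validate_outcome(y)
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    s = scores if direction == "higher" else -scores

    auc, v10, v01 = _delong_components(s, y)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    var = 0.0
    if n_pos > 1:
        var += float(np.var(v10, ddof=1)) / n_pos
    if n_neg > 1:
        var += float(np.var(v01, ddof=1)) / n_neg
    half = _Z95 * math.sqrt(var)
    ci = (max(0.0, auc - half), min(1.0, auc + half))

    # operating points at each unique score value: predict positive when the
    # (oriented) score is >= threshold
    uniq = np.unique(s)
    sens = np.array([np.mean(s[y == 1] >= u) for u in uniq])
    fpr = np.array([np.mean(s[y == 0] >= u) for u in uniq])
    thresholds = uniq if direction == "higher" else -uniq

    order = np.argsort(thresholds)
    result = RocResult(
        thresholds=thresholds[order],
        sensitivity=sens[order],
        one_minus_specificity=fpr[order],
        auroc=auc,
        auroc_ci95=ci,
        youden_j=math.nan,
        optimal_threshold=math.nan,
        optimal_sensitivity=math.nan,
        optimal_one_minus_specificity=math.nan,
        direction=direction,
    )
    thr, j, se_opt, fpr_opt = youden_point(result)
    result.youden_j = j
    result.optimal_threshold = thr
    result.optimal_sensitivity = se_opt
    result.optimal_one_minus_specificity = fpr_opt
    return result


def youden_point(roc: RocResult) -> tuple[float, float, float, float]:
    """Maximize J = sensitivity - (1 - specificity) over the curve.

    Ties are broken toward the point with the higher sensitivity, then the
    lower threshold.  Returns (threshold, J, sensitivity, 1-specificity).
    """
    if roc.thresholds.size == 0:
        raise ValueError("empty ROC curve")
    j = roc.sensitivity - roc.one_minus_specificity
    best = 0
    for i in range(1, j.size):
        if j[i] > j[best] + 1e-12:
            best = i
        elif abs(j[i] - j[best]) <= 1e-12:
            if roc.sensitivity[i] > roc.sensitivity[best] + 1e-12:
                best = i
            elif (
                abs(roc.sensitivity[i] - roc.sensitivity[best]) <= 1e-12
                and roc.thresholds[i] < roc.thresholds[best]
            ):
                best = i
    return (
        float(roc.thresholds[best]),
        float(j[best]),
        float(roc.sensitivity[best]),
        float(roc.one_minus_specificity[best]),
    )


def od_threshold_report(roc: RocResult) -> float:
    """Convert an ODFlip-scale operating threshold back to the OD scale."""
    return od_from_odflip(roc.optimal_threshold)


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[int],
    direction_a: str = "higher",
    direction_b: str = "higher",
) -> dict:
    """DeLong test of AUROC(a) vs AUROC(b) on the same cases."""
    y = np.asarray(outcomes, dtype=float)
    _validate_outcome(y)
    sa = np.asarray(scores_a, dtype=float) * (1.0 if direction_a == "higher" else -1.0)
    sb = np.asarray(scores_b, dtype=float) * (1.0 if direction_b == "higher" else -1.0)
    auc_a, v10a, v01a = _delong_components(sa, y)
    auc_b, v10b, v01b = _delong_components(sb, y)
    n_pos = v10a.size
    n_neg = v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    cov = s10 / n_pos + s01 / n_neg
    var_diff = cov[0, 0] + cov[1, 1] - 2.0 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = math.inf if diff != 0 else 0.0
    else:
        z = diff / math.sqrt(var_diff)
    p = 2.0 * float(stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    return {"auroc_a": auc_a, "auroc_b": auc_b, "difference": diff, "z": z, "p": p}


def _term_dict(t: TermStats) -> dict:
    return {
        "B": t.B,
        "SE": t.SE,
        "Wald": t.wald,
        "df": t.df,
        "p": t.p,
        "ExpB": t.exp_b,
        "ci95": list(t.ci95),
        "t": t.t_value,
    }


def _fit_dict(fit: LogisticFit) -> dict:
    return {
        "model": fit.model,
        "converged": fit.converged,
        "n_obs": fit.n_obs,
        "deviance": fit.deviance,
        "message": fit.message,
        "terms": {t.name: _term_dict(t) for t in fit.terms},
    }


def _roc_dict(roc: RocResult) -> dict:
    return {
        "auroc": roc.auroc,
        "auroc_ci95": list(roc.auroc_ci95),
        "youden_j": roc.youden_j,
        "optimal_threshold": roc.optimal_threshold,
        "optimal_sensitivity": roc.optimal_sensitivity,
        "optimal_one_minus_specificity": roc.optimal_one_minus_specificity,
        "direction": roc.direction,
    }


def compare_predictors(table: pd.DataFrame, outcome: str = "needs_supplemental_o2") -> dict:
    """Run the full accuracy recipe per cohort label and pooled.

    For each of the positive-label, negative-label, and pooled cohorts with
    both outcome classes present: three univariable fits (od, odflip, spo2),
    the two-predictor multivariable fit (odflip + spo2), ROC analyses of
    ODFlip and SpO2 (lower score indicates the positive class for both), the
    ODFlip Youden threshold back-converted to the OD scale, and a DeLong
    paired comparison of the two AUROCs.
    """
    report: dict = {"schema_version": 1, "cohorts": {}}
    subsets = {
        "positive": table[table["cohort_label"] == "positive"],
        "negative": table[table["cohort_label"] == "negative"],
        "pooled": table,
    }
    for label, sub in subsets.items():
        if len(sub) == 0 or sub[outcome].nunique() < 2:
            report["cohorts"][label] = {"skipped": "needs both outcome classes"}
            continue
        entry: dict = {"n": int(len(sub))}
        entry["univariable"] = {
            p: _fit_dict(fit_logistic(sub, [p], outcome))
            for p in ("od", "odflip", "spo2")
        }
        entry["multivariable"] = _fit_dict(fit_logistic(sub, ["odflip", "spo2"], outcome))
        y = sub[outcome].astype(int).to_numpy()
        roc_flip = roc_curve(sub["odflip"].to_numpy(), y, direction="lower")
        roc_spo2 = roc_curve(sub["spo2"].to_numpy(), y, direction="lower")
        entry["roc"] = {
            "odflip": _roc_dict(roc_flip),
            "spo2": _roc_dict(roc_spo2),
        }
        entry["roc"]["odflip"]["od_threshold"] = od_threshold_report(roc_flip)
        entry["delong_odflip_vs_spo2"] = delong_paired_test(
            sub["odflip"].to_numpy(),
            sub["spo2"].to_numpy(),
            y,
            direction_a="lower",
            direction_b="lower",
        )
        report["cohorts"][label] = entry
    return report
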