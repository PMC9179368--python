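"""Diagnostic-accuracy statistics with confidence intervals, plus ROC/AUC.

Given true and predicted IDH labels ("mut" is the positive class
throughout), this module computes the full diagnostic panel —
sensitivity, specificity, accuracy, predictive values, likelihood
ratios, disease prevalence — each with a 95% confidence interval, and
the area under the ROC curve from continuous decision scores.

Interval methods
----------------
* sensitivity / specificity / accuracy / prevalence: exact
  Clopper–Pearson intervals (beta-quantile formulation);
* likelihood ratios: the log method,
  exp(ln LR ± z·SE) with SE(ln LR+) = √(1/tp − 1/n₁ + 1/fp − 1/n₂) and
  SE(ln LR−) = √(1/fn − 1/n₁ + 1/tn − 1/n₂);
* PPV / NPV: the standard logit (Wald-on-log-odds) interval.  The method
  used for these two intervals in the source clinical literature is not
  uniquely identifiable, so they are tagged with their method name.

Statistics with zero denominators are flagged undefined rather than
raising, so a partial report is always available.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

POSITIVE_LABEL = "mut"
NEGATIVE_LABEL = "wt"


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 table with "mut" as the positive class."""

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fn", "fp", "tn"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v}")
            object.__setattr__(self, name, int(v))

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def n_positive(self) -> int:
        """Number of truly diseased (IDH-mutant) cases."""
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.fp + self.tn


def confusion(y_true, y_pred) -> ConfusionMatrix:
    """Cross-tabulate true against predicted labels."""
    y_true, y_pred = list(y_true), list(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted labels"
        )
    counts = {"tp": 0, "fn": 0, "fp": 0, "tn": 0}
    for t, p in zip(y_true, y_pred):
        for name, v in (("true", t), ("predicted", p)):
            if v not in (POSITIVE_LABEL, NEGATIVE_LABEL):
                raise ValueError(f"unknown {name} label {v!r}")
        if t == POSITIVE_LABEL:
            counts["tp" if p == POSITIVE_LABEL else "fn"] += 1
        else:
            counts["fp" if p == POSITIVE_LABEL else "tn"] += 1
    return ConfusionMatrix(**counts)


@dataclass(frozen=True)
class Estimate:
    """A point estimate with a two-sided confidence interval.

    ``undefined`` marks statistics whose denominator was zero; their
    numeric fields are NaN.
    """

    value: float
    lower: float
    upper: float
    method: str = ""
    undefined: bool = False

    def as_percent(self) -> tuple:
        return (100 * self.value, 100 * self.lower, 100 * self.upper)


def _undefined(method: str) -> Estimate:
    return Estimate(math.nan, math.nan, math.nan, method=method, undefined=True)


def clopper_pearson(count: int, nobs: int, ci_level: float = 0.95) -> Estimate:
    """Exact binomial (Clopper–Pearson) interval for count/nobs."""
    if nobs == 0:
        return _undefined("clopper-pearson")
    lower, upper = proportion_confint(count, nobs, alpha=1 - ci_level, method="beta")
    return Estimate(count / nobs, float(lower), float(upper), method="clopper-pearson")


def _logit_interval(count: int, nobs: int, ci_level: float) -> Estimate:
    method = "logit (method differs from source publication)"
    if nobs == 0:
        return _undefined(method)
    p = count / nobs
    if count == 0 or count == nobs:
        # logit SE undefined at the boundary; fall back to the exact interval
        exact = clopper_pearson(count, nobs, ci_level)
        return Estimate(p, exact.lower, exact.upper, method=method)
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    se = math.sqrt(1.0 / count + 1.0 / (nobs - count))
    lo = math.log(p / (1 - p)) - z * se
    hi = math.log(p / (1 - p)) + z * se
    expit = lambda x: 1.0 / (1.0 + math.exp(-x))  # noqa: E731
    return Estimate(p, expit(lo), expit(hi), method=method)


def _lr_interval(value: float, se_terms, z: float, method: str) -> Estimate:
    if not math.isfinite(value) or value <= 0:
        return Estimate(value, math.nan, math.nan, method=method, undefined=True)
    if any(t is None for t in se_terms):
        return Estimate(value, math.nan, math.nan, method=method, undefined=True)
    se_sq = sum(se_terms)
    if se_sq < 0:
        se_sq = 0.0
    se = math.sqrt(se_sq)
    return Estimate(
        value,
        math.exp(math.log(value) - z * se),
        math.exp(math.log(value) + z * se),
        method=method,
    )


@dataclass
class DiagnosticReport:
    """All Table-style diagnostic statistics for one confusion matrix."""

    cm: ConfusionMatrix
    sensitivity: Estimate
    specificity: Estimate
    accuracy: Estimate
    ppv: Estimate
    npv: Estimate
    prevalence: Estimate
    lr_pos: Estimate
    lr_neg: Estimate
    auc: float | None = None
    ci_level: float = 0.95
    extras: dict = field(default_factory=dict)


def report(cm: ConfusionMatrix, ci_level: float = 0.95) -> DiagnosticReport:
    """Compute the full diagnostic panel from a confusion matrix."""
    n1, n2, n = cm.n_positive, cm.n_negative, cm.n
    if n == 0:
        raise ValueError("empty confusion matrix")
    z = float(stats.norm.ppf(0.5 + ci_level / 2.0))

    sens = clopper_pearson(cm.tp, n1, ci_level) if n1 else _undefined("clopper-pearson")
    spec = clopper_pearson(cm.tn, n2, ci_level) if n2 else _undefined("clopper-pearson")
    acc = clopper_pearson(cm.tp + cm.tn, n, ci_level)
    prev = clopper_pearson(n1, n, ci_level)
    ppv = (
        _logit_interval(cm.tp, cm.tp + cm.fp, ci_level)
        if cm.tp + cm.fp
        else _undefined("logit")
    )
    npv = (
        _logit_interval(cm.tn, cm.tn + cm.fn, ci_level)
        if cm.tn + cm.fn
        else _undefined("logit")
    )

    lr_method = "log method"
    if n1 and n2 and cm.tn < n2:
        lr_pos_val = (cm.tp / n1) / (1 - cm.tn / n2)
        terms = (
            [1 / cm.tp - 1 / n1, 1 / cm.fp - 1 / n2]
            if cm.tp > 0 and cm.fp > 0
            else [None]
        )
        lr_pos = _lr_interval(lr_pos_val, terms, z, lr_method)
    else:
        lr_pos = _undefined(lr_method)
    if n1 and n2 and cm.tn > 0:
        lr_neg_val = (1 - cm.tp / n1) / (cm.tn / n2)
        terms = (
            [1 / cm.fn - 1 / n1, 1 / cm.tn - 1 / n2]
            if cm.fn > 0 and cm.tn > 0
            else [None]
        )
        lr_neg = _lr_interval(lr_neg_val, terms, z, lr_method)
    else:
        lr_neg = _undefined(lr_method)

    return DiagnosticReport(
        cm=cm,
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        ppv=ppv,
        npv=npv,
        prevalence=prev,
        lr_pos=lr_pos,
        lr_neg=lr_neg,
        ci_level=ci_level,
    )


def roc_auc(scores, y_true) -> tuple:
    """AUC (Mann–Whitney; ties count ½) plus the ROC curve.

    Returns ``(auc, fpr, tpr, thresholds)`` with one ROC point per
    distinct threshold.  The trapezoidal area under the empirical ROC
    curve equals the Mann–Whitney pair-counting statistic.
    """
    scores = np.asarray(scores, dtype=float)
    yb = np.asarray([1 if t == POSITIVE_LABEL else 0 for t in y_true])
    for t in y_true:
        if t not in (POSITIVE_LABEL, NEGATIVE_LABEL):
            raise ValueError(f"unknown label {t!r}")
    if yb.sum() == 0 or yb.sum() == len(yb):
        raise ValueError("ROC needs both classes present")
    fpr, tpr, thresholds = roc_curve(yb, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr, thresholds


# ---------------------------------------------------------------------------
# Report rendering and serialization.
# ---------------------------------------------------------------------------

REPORT_SCHEMA_VERSION = 1

_PERCENT_ROWS = (
    ("Accuracy (%)", "accuracy"),
    ("Sensitivity (%)", "sensitivity"),
    ("Specificity (%)", "specificity"),
    ("Positive likelihood ratio", "lr_pos"),
    ("Negative likelihood ratio", "lr_neg"),
    ("Positive predictive value (%)", "ppv"),
    ("Negative predictive value (%)", "npv"),
    ("Disease prevalence (%)", "prevalence"),
)


def format_report(rep: DiagnosticReport, title: str = "") -> str:
    """Render the report as a plain-text table (percentages, 2 decimals)."""
    lines = []
    if title:
        lines.append(title)
    lines.append(f"{'Statistic':<32}{'Value (95% CI)':<28}")
    for row_name, attr in _PERCENT_ROWS:
        est: Estimate = getattr(rep, attr)
        if est.undefined:
            lines.append(f"{row_name:<32}undefined")
            continue
        if "(%)" in row_name:
            v, lo, hi = est.as_percent()
        else:
            v, lo, hi = est.value, est.lower, est.upper
        lines.append(f"{row_name:<32}{v:.2f} ({lo:.2f}–{hi:.2f})")
    if rep.auc is not None:
        lines.append(f"{'AUC':<32}{rep.auc:.2f}")
    return "\n".join(lines)


def report_to_dict(rep: DiagnosticReport) -> dict:
    def enc(est: Estimate) -> dict:
        return {
            "value": None if est.undefined else est.value,
            "lower": None if est.undefined else est.lower,
            "upper": None if est.undefined else est.upper,
            "method": est.method,
            "undefined": est.undefined,
        }

    return {
        "format": "mrsidh-report",
        "schema_version": REPORT_SCHEMA_VERSION,
        "confusion_matrix": {
            "tp": rep.cm.tp,
            "fn": rep.cm.fn,
            "fp": rep.cm.fp,
            "tn": rep.cm.tn,
        },
        "ci_level": rep.ci_level,
        "statistics": {
            attr: enc(getattr(rep, attr))
            for attr in (
                "sensitivity",
                "specificity",
                "accuracy",
                "ppv",
                "npv",
                "prevalence",
                "lr_pos",
                "lr_neg",
            )
        },
        "auc": rep.auc,
        "extras": rep.extras,
    }


def write_report(rep: DiagnosticReport, path) -> None:
    Path(path).write_text(
        json.dumps(report_to_dict(rep), indent=2) + "\n", encoding="utf-8"
    )
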