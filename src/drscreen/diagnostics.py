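"""Diagnostic accuracy of a binary test against a reference grader.

Ordinal grades are dichotomised at a clinical threshold (any retinopathy,
grade >= 1, or referable disease, grade >= 2), cross-classified into a
2x2 confusion table with the manual grader as reference standard, and
summarised as prevalence, sensitivity, specificity and accuracy, each with
a binomial confidence interval.

Three interval methods are provided:

* ``wald`` — normal approximation p +/- z * sqrt(p(1-p)/n), clipped to [0,1];
* ``clopper_pearson`` — exact beta-quantile bounds, guaranteeing
  at-least-nominal coverage (lower bound 0 when x = 0, upper bound 1 when
  x = n; for x = n the lower bound has the closed form (alpha/2)^(1/n));
* ``wilson`` — score interval, always inside [0, 1] without clipping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .cohort import ICDRGrade

__all__ = [
    "Confusion2x2",
    "MetricEstimate",
    "DiagnosticMetrics",
    "binarize",
    "confusion_2x2",
    "metrics",
    "binomial_ci",
    "CI_METHODS",
]

CI_METHODS = ("wald", "clopper_pearson", "wilson")

#: Interval methods reproducing the conventional report layout: the exact
#: method for proportions near the boundary (sensitivity/specificity/
#: accuracy, rare-outcome prevalence) and the normal approximation for the
#: headline disease prevalence.
DEFAULT_CI_METHODS = {
    "prevalence": "wald",
    "sensitivity": "clopper_pearson",
    "specificity": "clopper_pearson",
    "accuracy": "clopper_pearson",
}


@dataclass(frozen=True)
class Confusion2x2:
    """2x2 confusion counts; reference = manual grader, test = automated."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise InputError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricEstimate:
    """One proportion with its confidence interval."""

    value: float
    ci_low: float
    ci_high: float
    ci_method: str
    numerator: int
    denominator: int

    def to_dict(self) -> dict:
        return {
            "value": self.value,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_method": self.ci_method,
            "numerator": self.numerator,
            "denominator": self.denominator,
        }


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Prevalence, sensitivity, specificity and accuracy with CIs.

    A metric whose denominator is zero (e.g. sensitivity with no reference
    positives) is ``None`` rather than silently 0.
    """

    prevalence: MetricEstimate | None
    sensitivity: MetricEstimate | None
    specificity: MetricEstimate | None
    accuracy: MetricEstimate | None
    ci_level: float
    counts: Confusion2x2

    def to_dict(self) -> dict:
        d: dict = {
            "counts": {"tp": self.counts.tp, "fp": self.counts.fp,
                       "fn": self.counts.fn, "tn": self.counts.tn,
                       "n": self.counts.n},
            "ci_level": self.ci_level,
        }
        for name in ("prevalence", "sensitivity", "specificity", "accuracy"):
            est: MetricEstimate | None = getattr(self, name)
            d[name] = est.to_dict() if est is not None else None
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def binarize(grades: Sequence[int | ICDRGrade], threshold: int) -> np.ndarray:
    """Dichotomise ordinal grades: positive iff grade >= threshold.

    ``threshold`` is 1 for "any DR" or 2 for "referable DR".  Ungradable
    sentinels are rejected: filter the cohort first.
    """
    if threshold not in (1, 2):
        raise InputError(f"threshold must be 1 (any DR) or 2 (referable), got {threshold}")
    codes = []
    for g in grades:
        if isinstance(g, ICDRGrade):
            if not g.gradable:
                raise InputError(
                    "ungradable grade in binarize input; apply filter_gradable first"
                )
            codes.append(g.value)
        else:
            codes.append(int(g))
    arr = np.asarray(codes, dtype=np.int64)
    if arr.size and (arr.min() < 0 or arr.max() > 3):
        raise InputError("grade codes must lie in 0..3")
    return arr >= threshold


def confusion_2x2(reference: Sequence[bool], test: Sequence[bool]) -> Confusion2x2:
    """Cross-classify paired boolean calls into a 2x2 confusion table."""
    ref = np.asarray(reference, dtype=bool)
    tst = np.asarray(test, dtype=bool)
    if ref.shape != tst.shape or ref.ndim != 1:
        raise InputError(
            f"reference and test must be 1-D and equal length (got {ref.shape} vs {tst.shape})"
        )
    return Confusion2x2(
        tp=int(np.sum(ref & tst)),
        fp=int(np.sum(~ref & tst)),
        fn=int(np.sum(ref & ~tst)),
        tn=int(np.sum(~ref & ~tst)),
    )


def binomial_ci(
    x: int, n: int, method: str = "clopper_pearson", level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval for a binomial proportion x/n."""
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise InputError("x and n must be integers")
    if n < 1 or not (0 <= x <= n):
        raise InputError(f"require 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not (0.0 < level < 1.0):
        raise InputError(f"confidence level must lie in (0, 1), got {level}")
    alpha = 1.0 - level
    p = x / n
    if method == "wald":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        half = z * math.sqrt(p * (1.0 - p) / n)
        return max(0.0, p - half), min(1.0, p + half)
    if method == "clopper_pearson":
        low = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2.0, x, n - x + 1))
        high = 1.0 if x == n else float(stats.beta.ppf(1.0 - alpha / 2.0, x + 1, n - x))
        return low, high
    if method == "wilson":
        z = stats.norm.ppf(1.0 - alpha / 2.0)
        z2 = z * z
        centre = (p + z2 / (2.0 * n)) / (1.0 + z2 / n)
        half = (z / (1.0 + z2 / n)) * math.sqrt(p * (1.0 - p) / n + z2 / (4.0 * n * n))
        # at x=0 / x=n the score bounds are exactly 0 / 1; avoid cancellation
        low = 0.0 if x == 0 else centre - half
        high = 1.0 if x == n else centre + half
        return low, high
    raise InputError(f"unknown CI method {method!r}; expected one of {CI_METHODS}")


def _estimate(x: int, n: int, method: str, level: float) -> MetricEstimate | None:
    if n == 0:
        return None
    low, high = binomial_ci(x, n, method, level)
    return MetricEstimate(x / n, low, high, method, x, n)


def metrics(
    c: Confusion2x2,
    ci_method: str | dict[str, str] | None = None,
    ci_level: float = 0.95,
) -> DiagnosticMetrics:
    """Diagnostic metrics with per-metric confidence intervals.

    ``ci_method`` may be a single method name applied to every metric, a
    per-metric mapping, or ``None`` for the defaults (Wald for prevalence,
    exact Clopper-Pearson elsewhere).
    """
    if c.n == 0:
        raise InputError("confusion table is empty")
    if ci_method is None:
        methods = dict(DEFAULT_CI_METHODS)
    elif isinstance(ci_method, str):
        methods = {m: ci_method for m in DEFAULT_CI_METHODS}
    else:
        methods = {**DEFAULT_CI_METHODS, **ci_method}
    for m in methods.values():
        if m not in CI_METHODS:
            raise InputError(f"unknown CI method {m!r}; expected one of {CI_METHODS}")
    pos = c.tp + c.fn
    neg = c.tn + c.fp
    return DiagnosticMetrics(
        prevalence=_estimate(pos, c.n, methods["prevalence"], ci_level),
        sensitivity=_estimate(c.tp, pos, methods["sensitivity"], ci_level),
        specificity=_estimate(c.tn, neg, methods["specificity"], ci_level),
        accuracy=_estimate(c.tp + c.tn, c.n, methods["accuracy"], ci_level),
        ci_level=ci_level,
        counts=c,
    )
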