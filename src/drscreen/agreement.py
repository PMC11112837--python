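"""Ordinal inter-grader agreement: Cohen's and weighted kappa, Spearman rho.

Two graders assigning the same ordinal scale to the same eyes are compared
through a k x k contingency table.  Cohen's kappa corrects the observed
agreement for the agreement expected under marginal independence; the
weighted variant credits partial agreement between nearby ordinal
categories through an agreement-weight matrix w_ij in [0, 1] with w_ii = 1:

    kappa_w = (Po_w - Pe_w) / (1 - Pe_w),
    Po_w = sum_ij w_ij p_ij,   Pe_w = sum_ij w_ij r_i c_j,

with cell proportions p_ij and marginals r, c.  The identity weight matrix
recovers the unweighted statistic.  Standard errors follow the asymptotic
(large-sample) variance of weighted kappa of Fleiss, Cohen & Everitt; the
p-value is a two-sided z-test of kappa = 0 using the null-hypothesis
variance.  Verbal interpretation uses the Landis-Koch bands.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import InputError, UndefinedStatisticError

__all__ = [
    "ContingencyTable",
    "WeightScheme",
    "AgreementResult",
    "contingency_table",
    "cohen_kappa",
    "weighted_kappa",
    "spearman_rho",
    "landis_koch_band",
]


@dataclass(frozen=True)
class ContingencyTable:
    """k x k cross-tabulation of two graders' categories.

    Rows index grader A (the reference), columns grader B.  Unused
    categories keep their (empty) rows and columns so that ordinal weights
    remain defined over the full scale.
    """

    counts: np.ndarray
    category_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise InputError("contingency table must be square")
        if (counts < 0).any():
            raise InputError("contingency table entries must be non-negative")
        if len(self.category_labels) != counts.shape[0]:
            raise InputError("category_labels length must match table size")
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "category_labels", tuple(self.category_labels))

    @property
    def k(self) -> int:
        return self.counts.shape[0]

    @property
    def n(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class WeightScheme:
    """Agreement weights over a k-level ordinal scale.

    ``identity`` scores only exact agreement; ``linear`` discounts
    disagreement in proportion to the category distance, ``quadratic`` to
    its square.  A ``custom`` scheme supplies its own matrix (w_ii = 1,
    entries in [0, 1]).
    """

    name: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise InputError("weight matrix must be square")
        if (w < 0).any() or (w > 1).any():
            raise InputError("weights must lie in [0, 1]")
        if not np.allclose(np.diag(w), 1.0):
            raise InputError("diagonal weights must equal 1")
        object.__setattr__(self, "weights", w)

    @classmethod
    def identity(cls, k: int) -> "WeightScheme":
        return cls("identity", np.eye(k))

    @classmethod
    def linear(cls, k: int) -> "WeightScheme":
        d = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        return cls("linear", 1.0 - d / (k - 1))

    @classmethod
    def quadratic(cls, k: int) -> "WeightScheme":
        d = np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        return cls("quadratic", 1.0 - (d / (k - 1)) ** 2)

    @classmethod
    def from_name(cls, name: str, k: int) -> "WeightScheme":
        try:
            return {"identity": cls.identity, "linear": cls.linear, "quadratic": cls.quadratic}[name](k)
        except KeyError as exc:
            raise InputError(f"unknown weight scheme {name!r}") from exc


@dataclass(frozen=True)
class AgreementResult:
    """A kappa statistic with its agreement components and interpretation.

    ``standard_error`` is the large-sample SE of the estimate;
    ``p_value`` tests kappa = 0 with the null-variance z statistic
    (recorded in ``metadata`` alongside the weighting scheme).
    """

    kappa: float
    observed_agreement: float
    expected_agreement: float
    standard_error: float
    p_value: float
    band: str
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.metadata.get("statistic", "kappa"),
            "scheme": self.metadata.get("scheme"),
            "kappa": self.kappa,
            "po": self.observed_agreement,
            "pe": self.expected_agreement,
            "se": self.standard_error,
            "p_value": self.p_value,
            "band": self.band,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


def contingency_table(
    grades_a: Sequence[int],
    grades_b: Sequence[int],
    k: int,
    labels: Sequence[str] | None = None,
) -> ContingencyTable:
    """Cross-tabulate two equal-length ordinal code vectors over 0..k-1."""
    a = np.asarray(grades_a, dtype=np.int64)
    b = np.asarray(grades_b, dtype=np.int64)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError(
            f"grade vectors must be 1-D and equal length (got {a.shape} vs {b.shape})"
        )
    for name, v in (("grades_a", a), ("grades_b", b)):
        if v.size and (v.min() < 0 or v.max() >= k):
            raise InputError(f"{name} contains codes outside 0..{k - 1}")
    counts = np.zeros((k, k), dtype=np.int64)
    np.add.at(counts, (a, b), 1)
    if labels is None:
        labels = tuple(str(i) for i in range(k))
    return ContingencyTable(counts, tuple(labels))


def weighted_kappa(table: ContingencyTable, scheme: WeightScheme) -> AgreementResult:
    """Weighted Cohen's kappa with asymptotic SE and z-test p-value."""
    if table.n == 0:
        raise InputError("contingency table is empty")
    w = scheme.weights
    if w.shape[0] != table.k:
        raise InputError(
            f"weight scheme is {w.shape[0]}x{w.shape[0]} but table is {table.k}x{table.k}"
        )
    n = table.n
    p = table.counts / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    po = float((w * p).sum())
    pe = float((w * np.outer(r, c)).sum())
    if 1.0 - pe <= 1e-15:
        raise UndefinedStatisticError(
            "expected agreement is 1; kappa is undefined for this table"
        )
    kappa = (po - pe) / (1.0 - pe)

    # Fleiss-Cohen-Everitt asymptotic variances.  w_row[i] / w_col[j] are the
    # marginal-weighted average weights entering both the null and the
    # estimate variance.
    w_row = w @ c          # wbar_i. = sum_j c_j w_ij
    w_col = r @ w          # wbar_.j = sum_i r_i w_ij
    cross = np.add.outer(w_row, w_col)
    var = (
        float((p * (w * (1.0 - pe) - cross * (1.0 - po)) ** 2).sum())
        - (po * pe - 2.0 * pe + po) ** 2
    ) / (n * (1.0 - pe) ** 4)
    var0 = (
        float((np.outer(r, c) * (w - cross) ** 2).sum()) - pe**2
    ) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    se0 = math.sqrt(max(var0, 0.0))
    if se0 > 0:
        p_value = float(2.0 * stats.norm.sf(abs(kappa) / se0))
    else:
        p_value = 1.0
    return AgreementResult(
        kappa=float(kappa),
        observed_agreement=po,
        expected_agreement=pe,
        standard_error=se,
        p_value=min(p_value, 1.0) if p_value > 0 else np.nextafter(0, 1),
        band=landis_koch_band(float(np.clip(kappa, -1.0, 1.0))),
        metadata={
            "statistic": "weighted_kappa" if scheme.name != "identity" else "cohen_kappa",
            "scheme": scheme.name,
            "n": n,
            "se_method": "Fleiss-Cohen-Everitt asymptotic",
            "p_value_method": "two-sided z-test, null variance",
        },
    )


def cohen_kappa(table: ContingencyTable) -> AgreementResult:
    """Unweighted Cohen's kappa (identity weights)."""
    return weighted_kappa(table, WeightScheme.identity(table.k))


def spearman_rho(grades_a: Sequence[int], grades_b: Sequence[int]) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with p-value."""
    a = np.asarray(grades_a, dtype=float)
    b = np.asarray(grades_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise InputError("grade vectors must be 1-D and equal length")
    if a.size < 3:
        raise InputError("need at least 3 paired grades for a rank correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise UndefinedStatisticError(
            "rank correlation undefined: a grade vector has zero variance"
        )
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)


#: Upper-inclusive Landis-Koch interpretation bands.
_LANDIS_KOCH = (
    (0.20, "poor"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "good"),
    (1.00, "very good"),
)


def landis_koch_band(kappa: float) -> str:
    """Verbal Landis-Koch interpretation of a kappa value in [-1, 1]."""
    if not (-1.0 <= kappa <= 1.0) or math.isnan(kappa):
        raise InputError(f"kappa must lie in [-1, 1], got {kappa}")
    for upper, label in _LANDIS_KOCH:
        if kappa <= upper:
            return label
    return "very good"  # pragma: no cover - unreachable
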