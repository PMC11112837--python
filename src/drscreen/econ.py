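"""Cost-minimization model for screening strategies.

Strategies assumed equally effective are ranked purely by cost.  The total
cost per patient of a strategy adds, per visit, the screening fee (a DRG
reimbursement weight), the round-trip transport cost, and the patient's
time valued at an hourly rate:

    total = visits * (screening + transport * transport_multiplier
                      + hours * hourly_rate)

Grader labour is excluded (assumed equal across strategies).  The packaged
baselines compare conventional ophthalmologist screening (fee $164, 1.5 h
of patient time) with automated AI-based screening (fee $33, 1 h); both
share a $73 round-trip transport cost and a $24/h time cost, giving
per-patient totals of $273 vs $130 and a $143 saving per patient.

All arithmetic is double precision without intermediate rounding; currency
rounding (half-up, whole dollars) happens only at report time through
:func:`round_money`.
"""

from __future__ import annotations

import decimal
import json
from dataclasses import dataclass, field, replace
from typing import Mapping

from .errors import ParameterError

__all__ = [
    "ScreeningStrategy",
    "CostResult",
    "ExchangeRate",
    "per_patient_cost",
    "cost_difference",
    "cohort_cost",
    "mixed_strategy_cost",
    "nok_to_usd",
    "round_money",
    "manual_baseline",
    "ai_baseline",
    "DEFAULT_COHORT_SIZE",
]

#: Number of patients screened on the baseline screening day.
DEFAULT_COHORT_SIZE = 33


@dataclass(frozen=True)
class ScreeningStrategy:
    """Cost parameters of one screening modality (all money in USD).

    ``transport_multiplier`` scales the transport term; the packaged
    default of 1 treats ``transport_cost_round_trip`` as already covering
    the full round trip.  Set it to 2 to explore pricing each leg
    separately.
    """

    name: str
    screening_cost: float
    transport_cost_round_trip: float
    patient_time_hours: float
    time_cost_per_hour: float
    visits: int = 1
    transport_multiplier: float = 1.0

    def __post_init__(self) -> None:
        for fname in (
            "screening_cost",
            "transport_cost_round_trip",
            "patient_time_hours",
            "time_cost_per_hour",
            "transport_multiplier",
        ):
            v = getattr(self, fname)
            if not isinstance(v, (int, float)) or v < 0 or v != v:
                raise ParameterError(f"{self.name or 'strategy'}.{fname} must be >= 0, got {v!r}")
        if not isinstance(self.visits, int) or self.visits < 1:
            raise ParameterError(f"{self.name or 'strategy'}.visits must be an integer >= 1")

    def with_value(self, parameter: str, value: float) -> "ScreeningStrategy":
        """Copy of this strategy with one numeric parameter replaced."""
        if parameter not in (
            "screening_cost",
            "transport_cost_round_trip",
            "patient_time_hours",
            "time_cost_per_hour",
            "visits",
            "transport_multiplier",
        ):
            raise ParameterError(f"unknown strategy parameter {parameter!r}")
        if parameter == "visits":
            value = int(value)
        return replace(self, **{parameter: value})


@dataclass(frozen=True)
class CostResult:
    """Itemised cost of one strategy."""

    strategy: str
    per_patient_total: float
    components: Mapping[str, float]
    cohort_total: float | None = None

    def to_dict(self) -> dict:
        d = {
            "strategy": self.strategy,
            "per_patient_total": self.per_patient_total,
            "components": dict(self.components),
        }
        if self.cohort_total is not None:
            d["cohort_total"] = self.cohort_total
        return d

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)


@dataclass(frozen=True)
class ExchangeRate:
    """NOK per USD conversion rate."""

    nok_per_usd: float = 9.89

    def __post_init__(self) -> None:
        if not (self.nok_per_usd > 0):
            raise ParameterError(f"nok_per_usd must be positive, got {self.nok_per_usd}")


def manual_baseline() -> ScreeningStrategy:
    """Conventional ophthalmologist screening at baseline parameters."""
    return ScreeningStrategy(
        name="manual",
        screening_cost=164.0,
        transport_cost_round_trip=73.0,
        patient_time_hours=1.5,
        time_cost_per_hour=24.0,
    )


def ai_baseline() -> ScreeningStrategy:
    """Automated AI-based screening at baseline parameters."""
    return ScreeningStrategy(
        name="ai",
        screening_cost=33.0,
        transport_cost_round_trip=73.0,
        patient_time_hours=1.0,
        time_cost_per_hour=24.0,
    )


def per_patient_cost(s: ScreeningStrategy) -> CostResult:
    """Total cost per patient, itemised into screening/transport/time."""
    screening = s.visits * s.screening_cost
    transport = s.visits * s.transport_cost_round_trip * s.transport_multiplier
    time = s.visits * s.patient_time_hours * s.time_cost_per_hour
    return CostResult(
        strategy=s.name,
        per_patient_total=screening + transport + time,
        components={"screening": screening, "transport": transport, "time": time},
    )


def cost_difference(a: ScreeningStrategy, b: ScreeningStrategy) -> float:
    """Per-patient cost of a minus b; positive means b is cost-saving."""
    return per_patient_cost(a).per_patient_total - per_patient_cost(b).per_patient_total


def cohort_cost(s: ScreeningStrategy, n_patients: int) -> float:
    """Total cost of screening ``n_patients`` with one strategy."""
    if n_patients < 0:
        raise ParameterError(f"n_patients must be >= 0, got {n_patients}")
    return n_patients * per_patient_cost(s).per_patient_total


def mixed_strategy_cost(
    a: ScreeningStrategy, b: ScreeningStrategy, fraction_a: float, n_patients: int
) -> float:
    """Cohort cost when a fraction of patients goes to strategy ``a``."""
    if not (0.0 <= fraction_a <= 1.0):
        raise ParameterError(f"fraction_a must lie in [0, 1], got {fraction_a}")
    if n_patients < 0:
        raise ParameterError(f"n_patients must be >= 0, got {n_patients}")
    return (
        n_patients * fraction_a * per_patient_cost(a).per_patient_total
        + n_patients * (1.0 - fraction_a) * per_patient_cost(b).per_patient_total
    )


def nok_to_usd(amount_nok: float, rate: ExchangeRate | float = ExchangeRate()) -> float:
    """Convert an NOK amount to USD."""
    if not isinstance(rate, ExchangeRate):
        rate = ExchangeRate(float(rate))
    return amount_nok / rate.nok_per_usd


def round_money(amount: float, digits: int = 0) -> float:
    """Round half-up to whole currency units (report-time only)."""
    q = decimal.Decimal(1).scaleb(-digits)
    return float(decimal.Decimal(repr(float(amount))).quantize(q, rounding=decimal.ROUND_HALF_UP))
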