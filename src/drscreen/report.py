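"""End-to-end analysis: agreement -> diagnostics -> costs -> sweeps.

:func:`run_analysis` composes the pipeline on a cohort of grading records
plus a cost configuration and returns a single :class:`AnalysisReport`
whose JSON serialisation is deterministic given the inputs.  Ungradable
eyes are filtered exactly once, before any paired statistic.

A statistic that is undefined on the given data — for instance a kappa on
a table with no marginal variation, or a sensitivity with no reference
positives — appears as ``null`` in the report rather than a fabricated 0.
"""

from __future__ import annotations

import importlib.resources
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

from . import __version__
from .agreement import (
    AgreementResult,
    WeightScheme,
    cohen_kappa,
    contingency_table,
    spearman_rho,
    weighted_kappa,
)
from .cohort import GRADE_LABELS, GradingRecord, filter_gradable, grade_codes
from .diagnostics import binarize, confusion_2x2, metrics
from .econ import (
    ExchangeRate,
    ScreeningStrategy,
    cohort_cost,
    cost_difference,
    mixed_strategy_cost,
    per_patient_cost,
    round_money,
)
from .errors import AnalysisError, ConfigError, UndefinedStatisticError
from .sweep import ParameterGrid, one_way_sweep, two_way_sweep

__all__ = [
    "AnalysisReport",
    "run_analysis",
    "grade_distribution",
    "default_config",
    "load_config",
    "strategies_from_config",
]

_THRESHOLDS = {"any": 1, "referable": 2, 1: 1, 2: 2, "1": 1, "2": 2}


def default_config() -> dict:
    """Packaged baseline configuration (strategies, cohort size, sweeps)."""
    text = (
        importlib.resources.files("drscreen.data")
        .joinpath("default_costs.yaml")
        .read_text(encoding="utf-8")
    )
    return yaml.safe_load(text)


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON config file, filling gaps from the packaged default."""
    with open(path, "r", encoding="utf-8") as fh:
        user = yaml.safe_load(fh) or {}
    if not isinstance(user, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    cfg = default_config()
    for key, value in user.items():
        if key == "strategies" and isinstance(value, dict):
            for name, params in value.items():
                base = dict(cfg["strategies"].get(name, {}))
                base.update(params)
                cfg["strategies"][name] = base
        else:
            cfg[key] = value
    return cfg


def strategies_from_config(cfg: Mapping) -> dict[str, ScreeningStrategy]:
    out = {}
    for name, params in cfg["strategies"].items():
        out[name] = ScreeningStrategy(name=name, **params)
    return out


def _threshold_code(value) -> int:
    try:
        return _THRESHOLDS[value]
    except KeyError as exc:
        raise ConfigError(
            f"threshold must be 'any'/'referable' (or 1/2), got {value!r}"
        ) from exc


def _round_percent(p: float) -> int:
    return int(round_money(100.0 * p, 0))


def grade_distribution(records: Iterable[GradingRecord]) -> dict:
    """Per-grader grade shares over the 4 categories, to whole percent.

    Accepts gradable records only; shares are half-up rounded and sum to
    100 within rounding.
    """
    records = list(records)
    if not records:
        raise AnalysisError("grade_distribution requires a non-empty gradable cohort")
    out: dict = {"labels": list(GRADE_LABELS), "n": len(records)}
    for grader in ("manual", "ai"):
        codes = grade_codes(records, grader)
        counts = np.bincount(codes, minlength=4)
        out[grader] = {
            "counts": counts.tolist(),
            "percent": [_round_percent(c / len(records)) for c in counts],
        }
    return out


def _agreement_or_none(func, *args) -> dict | None:
    try:
        result: AgreementResult = func(*args)
    except UndefinedStatisticError as exc:
        return {"undefined": str(exc)}
    return result.to_dict()


@dataclass(frozen=True)
class AnalysisReport:
    """Consolidated pipeline output; every number is recomputable from the
    inputs echoed in ``provenance``."""

    cohort: dict
    grade_distribution: dict
    agreement: dict
    diagnostics: dict
    costs: dict
    sweeps: list
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "grade_distribution": self.grade_distribution,
            "agreement": self.agreement,
            "diagnostics": self.diagnostics,
            "costs": self.costs,
            "sweeps": self.sweeps,
            "provenance": self.provenance,
        }

    def to_json(self, indent: int | None = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def summary(self) -> str:
        """Plain-text summary of the headline numbers."""
        d = self.to_dict()
        lines = [
            "Screening cohort: "
            f"{d['cohort']['n_patients']} patients, {d['cohort']['n_eyes']} eyes, "
            f"{d['cohort']['n_gradable']} gradable",
        ]
        ag = d["agreement"]["four_level"]
        if ag and "kappa" in ag:
            lines.append(
                f"Weighted kappa ({ag['scheme']}): {ag['kappa']:.2f} [{ag['band']}]"
            )
        dr = d["diagnostics"]["dr"]
        for mname in ("prevalence", "sensitivity", "specificity", "accuracy"):
            m = dr.get(mname)
            if m:
                lines.append(
                    f"DR {mname}: {100 * m['value']:.1f}% "
                    f"(95% CI {100 * m['ci_low']:.1f}-{100 * m['ci_high']:.1f}%, {m['ci_method']})"
                )
        c = d["costs"]
        lines.append(
            "Per-patient cost: "
            + ", ".join(
                f"{name} ${round_money(r['per_patient_total']):.0f}"
                for name, r in c["per_patient"].items()
            )
        )
        lines.append(
            f"Cost difference ({c['difference']['a']} - {c['difference']['b']}): "
            f"${round_money(c['difference']['per_patient']):.0f} per patient"
        )
        return "\n".join(lines)


def run_analysis(
    records: Sequence[GradingRecord],
    config: Mapping | None = None,
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full pipeline on a cohort and a cost configuration."""
    cfg = default_config()
    if config:
        cfg.update({k: v for k, v in config.items() if k != "strategies"})
        if "strategies" in config:
            for name, params in config["strategies"].items():
                base = dict(cfg["strategies"].get(name, {}))
                base.update(params)
                cfg["strategies"][name] = base

    records = list(records)
    gradable = filter_gradable(records)
    if not gradable:
        raise AnalysisError("no gradable eyes: every record has an ungradable grade")

    threshold = _threshold_code(cfg.get("threshold", "any"))
    ci_level = float(cfg.get("ci_level", 0.95))
    scheme_name = cfg.get("weights", "linear")

    cohort_summary = {
        "n_patients": len({r.patient_id for r in records}),
        "n_eyes": len(records),
        "n_gradable": len(gradable),
        "n_ungradable": len(records) - len(gradable),
    }

    manual = grade_codes(gradable, "manual")
    ai = grade_codes(gradable, "ai")
    table4 = contingency_table(manual, ai, 4, GRADE_LABELS)
    scheme = WeightScheme.from_name(scheme_name, 4)

    man_bin = binarize(manual, threshold)
    ai_bin = binarize(ai, threshold)
    man_mac = np.asarray([bool(r.manual_maculopathy) for r in gradable])
    ai_mac = np.asarray([bool(r.ai_maculopathy) for r in gradable])

    try:
        rho, rho_p = spearman_rho(manual, ai)
        rho_entry = {"rho": rho, "p_value": rho_p}
    except UndefinedStatisticError as exc:
        rho_entry = {"undefined": str(exc)}

    agreement = {
        "four_level": _agreement_or_none(weighted_kappa, table4, scheme),
        "binary_dr": _agreement_or_none(
            cohen_kappa, contingency_table(man_bin.astype(int), ai_bin.astype(int), 2)
        ),
        "maculopathy": _agreement_or_none(
            cohen_kappa, contingency_table(man_mac.astype(int), ai_mac.astype(int), 2)
        ),
        "spearman": rho_entry,
        "contingency_4x4": table4.counts.tolist(),
    }

    ci_methods = cfg.get("ci_methods")  # optional per-metric override
    dr_metrics = metrics(confusion_2x2(man_bin, ai_bin), ci_methods, ci_level)
    # maculopathy is a rare outcome: exact intervals throughout
    mac_methods = ci_methods if ci_methods else {"prevalence": "clopper_pearson"}
    mac_metrics = metrics(confusion_2x2(man_mac, ai_mac), mac_methods, ci_level)
    diagnostics = {
        "threshold": threshold,
        "dr": dr_metrics.to_dict(),
        "maculopathy": mac_metrics.to_dict(),
    }

    strategies = strategies_from_config(cfg)
    names = list(strategies)
    if len(names) < 2:
        raise ConfigError("config must define at least two strategies")
    a, b = strategies[names[0]], strategies[names[1]]
    n_pat = int(cfg.get("n_patients", cohort_summary["n_patients"]))
    frac = float(cfg.get("fraction_a", 0.5))
    costs = {
        "per_patient": {
            name: per_patient_cost(s).to_dict() for name, s in strategies.items()
        },
        "difference": {
            "a": a.name,
            "b": b.name,
            "per_patient": cost_difference(a, b),
        },
        "cohort": {
            "n_patients": n_pat,
            **{name: cohort_cost(s, n_pat) for name, s in strategies.items()},
            "mixed": mixed_strategy_cost(a, b, frac, n_pat),
            "fraction_a": frac,
        },
        "nok_per_usd": ExchangeRate(float(cfg.get("nok_per_usd", 9.89))).nok_per_usd,
    }

    sweeps = []
    for spec_entry in cfg.get("sweeps", []) or []:
        grids = _parse_sweep_entry(spec_entry)
        if len(grids) == 1:
            res = one_way_sweep(a, b, grids[0])
        else:
            res = two_way_sweep(a, b, grids[0], grids[1])
        sweeps.append(res.to_dict())

    provenance = {
        "config": cfg,
        "seed": seed,
        "version": __version__,
        "weights": scheme_name,
        "threshold": threshold,
    }
    return AnalysisReport(
        cohort=cohort_summary,
        grade_distribution=grade_distribution(gradable),
        agreement=agreement,
        diagnostics=diagnostics,
        costs=costs,
        sweeps=sweeps,
        provenance=provenance,
    )


def _parse_sweep_entry(entry) -> list[ParameterGrid]:
    """One config sweep entry -> one or two ParameterGrids."""
    items = entry if isinstance(entry, list) else [entry]
    if not 1 <= len(items) <= 2:
        raise ConfigError("a sweep entry must contain one or two axis specs")
    grids = []
    for item in items:
        try:
            if "values" in item:
                grids.append(
                    ParameterGrid(item["strategy"], item["parameter"], tuple(item["values"]))
                )
            else:
                grids.append(
                    ParameterGrid.linspace(
                        item["strategy"],
                        item["parameter"],
                        float(item["min"]),
                        float(item["max"]),
                        int(item["steps"]),
                    )
                )
        except KeyError as exc:
            raise ConfigError(f"sweep entry missing key {exc}") from exc
    return grids
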