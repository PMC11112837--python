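"""Two-grader screening cohorts: domain types, CSV I/O, simulation, fixture.

A cohort is a list of per-eye :class:`GradingRecord` objects, each holding
the ordinal retinopathy grade assigned by two independent graders (a human
ophthalmologist and an automated system) on the four-level ICDR analysis
scale, plus a binary maculopathy call per grader.  Eyes with an image of
insufficient quality carry the ``UNGRADABLE`` sentinel and are excluded
from every paired analysis by :func:`filter_gradable`.

The synthetic generator emulates a screening day: each patient contributes
``eyes_per_patient`` eyes, the reference (manual) grade is a draw from the
cohort grade distribution, and the automated grade is a draw from a
row-stochastic confusion matrix conditioned on the manual grade.

:func:`oslo_fixture` reconstructs, eye by eye, the pilot cohort of 33
screened patients (66 eyes, 2 concordantly ungradable) whose marginal
grade distributions and agreement statistics this package reproduces.
"""

from __future__ import annotations

import csv
import enum
import functools
import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np

from .errors import InputError, ParameterError

__all__ = [
    "ICDRGrade",
    "GradingRecord",
    "CohortSimParams",
    "generate_cohort",
    "oslo_fixture",
    "filter_gradable",
    "grade_codes",
    "read_grading_table",
    "write_grading_table",
    "GRADE_LABELS",
]

#: Ordered labels for the four analysis-scale categories (codes 0..3).
#: Severe NPDR and PDR are collapsed into the single top category, matching
#: the four-category ordinal scale used for agreement statistics.
GRADE_LABELS = ("no DR", "mild NPDR", "moderate NPDR", "severe NPDR/PDR")

_PROB_TOL = 1e-9


@functools.total_ordering
class ICDRGrade(enum.Enum):
    """ICDR severity on the collapsed 4-level analysis scale, or ungradable.

    Codes 0..3 are totally ordered; ``UNGRADABLE`` never participates in an
    ordering comparison (attempting one raises ``TypeError``).
    """

    NO_DR = 0
    MILD = 1
    MODERATE = 2
    SEVERE = 3  # severe NPDR and PDR collapsed
    UNGRADABLE = "U"

    @property
    def code(self) -> int:
        """Ordinal code 0–3; raises for the ungradable sentinel."""
        if self is ICDRGrade.UNGRADABLE:
            raise InputError("ungradable eyes have no ordinal code")
        return self.value

    @property
    def gradable(self) -> bool:
        return self is not ICDRGrade.UNGRADABLE

    def __lt__(self, other: "ICDRGrade") -> bool:
        if not isinstance(other, ICDRGrade):
            return NotImplemented
        if not (self.gradable and other.gradable):
            raise TypeError("ungradable grades are not ordered")
        return self.value < other.value

    @classmethod
    def from_token(cls, token: Union[int, str]) -> "ICDRGrade":
        """Parse a serialized grade token (``0|1|2|3|U``)."""
        if isinstance(token, str):
            token = token.strip()
            if token.upper() == "U":
                return cls.UNGRADABLE
            try:
                token = int(token)
            except ValueError as exc:
                raise InputError(f"unrecognized grade token {token!r}") from exc
        if token not in (0, 1, 2, 3):
            raise InputError(f"grade code {token!r} outside 0-3")
        return cls(token)

    @property
    def token(self) -> str:
        return "U" if self is ICDRGrade.UNGRADABLE else str(self.value)


@dataclass(slots=True)
class GradingRecord:
    """One eye's assessment by both graders.

    ``manual_maculopathy`` / ``ai_maculopathy`` are ``None`` exactly when the
    corresponding grade is ungradable (no image to call maculopathy on).
    """

    patient_id: str
    eye: str  # "left" | "right"
    manual_grade: ICDRGrade
    ai_grade: ICDRGrade
    manual_maculopathy: bool | None
    ai_maculopathy: bool | None

    def __post_init__(self) -> None:
        if self.eye not in ("left", "right"):
            raise InputError(f"eye must be 'left' or 'right', got {self.eye!r}")
        for grade, flag, who in (
            (self.manual_grade, self.manual_maculopathy, "manual"),
            (self.ai_grade, self.ai_maculopathy, "ai"),
        ):
            if grade.gradable and flag is None:
                raise InputError(f"{who} maculopathy flag missing on gradable eye")
            if not grade.gradable and flag is not None:
                raise InputError(f"{who} maculopathy flag present on ungradable eye")

    @property
    def gradable(self) -> bool:
        """True when both graders produced an ordinal grade."""
        return self.manual_grade.gradable and self.ai_grade.gradable


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{name} must lie in [0, 1], got {value}")


@dataclass(slots=True)
class CohortSimParams:
    """Parameters of the synthetic two-grader cohort generator.

    Defaults emulate the pilot screening-day cohort: 33 patients with two
    eyes each, manual grade shares (81, 3, 11, 5)% over the four ICDR
    analysis categories, maculopathy in ~3% of eyes, roughly one eye in
    thirty ungradable, and both graders flagging the same eyes ungradable.
    The default confusion matrix reproduces the observed disagreement
    pattern: a moderate-NPDR eye is under-called as mild by the automated
    grader about 2 times in 7, all other grades are read concordantly.
    """

    n_patients: int = 33
    eyes_per_patient: int = 2
    grade_probs: Sequence[float] = (0.81, 0.03, 0.11, 0.05)
    maculopathy_prob: float = 0.03
    ungradable_prob: float = 1.0 / 33.0
    ai_confusion: Sequence[Sequence[float]] = (
        (1.0, 0.0, 0.0, 0.0),
        (0.0, 1.0, 0.0, 0.0),
        (0.0, 2.0 / 7.0, 5.0 / 7.0, 0.0),
        (0.0, 0.0, 0.0, 1.0),
    )
    ungradable_concordance: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ParameterError("n_patients must be non-negative")
        if self.eyes_per_patient < 1:
            raise ParameterError("eyes_per_patient must be at least 1")
        probs = np.asarray(self.grade_probs, dtype=float)
        if probs.shape != (4,):
            raise ParameterError("grade_probs must have exactly 4 entries")
        if (probs < 0).any() or (probs > 1).any():
            raise ParameterError("grade_probs entries must lie in [0, 1]")
        if abs(probs.sum() - 1.0) > _PROB_TOL:
            raise ParameterError(
                f"grade_probs must sum to 1 (got {probs.sum():.12f})"
            )
        conf = np.asarray(self.ai_confusion, dtype=float)
        if conf.shape != (4, 4):
            raise ParameterError("ai_confusion must be a 4x4 matrix")
        if (conf < 0).any() or (conf > 1).any():
            raise ParameterError("ai_confusion entries must lie in [0, 1]")
        bad = np.abs(conf.sum(axis=1) - 1.0) > _PROB_TOL
        if bad.any():
            raise ParameterError(
                f"ai_confusion rows {np.flatnonzero(bad).tolist()} do not sum to 1"
            )
        _check_prob("maculopathy_prob", self.maculopathy_prob)
        _check_prob("ungradable_prob", self.ungradable_prob)
        _check_prob("ungradable_concordance", self.ungradable_concordance)


def generate_cohort(params: CohortSimParams) -> list[GradingRecord]:
    """Draw a synthetic two-grader cohort.

    All randomness flows from ``params.seed`` through one fresh generator;
    identical parameters give identical cohorts.  Manual grades are i.i.d.
    draws from ``grade_probs``; the automated grade of each gradable eye is
    drawn from the ``ai_confusion`` row of its manual grade.  Each eye has
    one latent maculopathy state, reported by every grader with a gradable
    image, so the two maculopathy columns are concordant wherever both
    graders see the eye.
    """
    rng = np.random.default_rng(params.seed)
    n = params.n_patients * params.eyes_per_patient
    if n == 0:
        return []

    probs = np.asarray(params.grade_probs, dtype=float)
    conf = np.asarray(params.ai_confusion, dtype=float)

    manual = _draw_categorical(rng, np.broadcast_to(probs, (n, 4)))
    ai = _draw_categorical(rng, conf[manual])
    macula = rng.random(n) < params.maculopathy_prob
    ungradable = rng.random(n) < params.ungradable_prob
    ai_ungradable = ungradable & (rng.random(n) < params.ungradable_concordance)

    eye_names = ["right", "left"]
    records: list[GradingRecord] = []
    width = max(2, len(str(params.n_patients)))
    for i in range(n):
        patient = i // params.eyes_per_patient
        eye_idx = i % params.eyes_per_patient
        man_ok = not ungradable[i]
        ai_ok = not ai_ungradable[i]
        records.append(
            GradingRecord(
                patient_id=f"P{patient + 1:0{width}d}",
                eye=eye_names[eye_idx % 2],
                manual_grade=ICDRGrade(int(manual[i])) if man_ok else ICDRGrade.UNGRADABLE,
                ai_grade=ICDRGrade(int(ai[i])) if ai_ok else ICDRGrade.UNGRADABLE,
                manual_maculopathy=bool(macula[i]) if man_ok else None,
                ai_maculopathy=bool(macula[i]) if ai_ok else None,
            )
        )
    return records


def _draw_categorical(rng: np.random.Generator, row_probs: np.ndarray) -> np.ndarray:
    """Vectorised categorical draw, one category per row of probabilities."""
    cdf = np.cumsum(row_probs, axis=1)
    u = rng.random(row_probs.shape[0])
    return (u[:, None] > cdf).sum(axis=1).astype(np.int64)


def oslo_fixture() -> list[GradingRecord]:
    """Reconstruct the pilot screening cohort eye by eye.

    33 patients, 66 eyes.  The right eyes of the first two patients are
    ungradable for both graders.  Over the 64 gradable eyes the manual
    grade counts are (52, 2, 7, 3) and the automated counts (52, 4, 5, 3)
    for categories none/mild/moderate/severe — i.e. shares (81, 3, 11, 5)%
    vs (81, 6, 8, 5)%.  The only disagreements are two moderate-NPDR eyes
    the automated grader called mild; binary any-DR agreement is therefore
    perfect with 12 positives per grader.  Two eyes are maculopathy
    positive by both graders (2/64 = 3.1%).
    """
    # Manual grades of the 64 gradable eyes, in cohort order.  Disease is
    # concentrated in the later patients; the two AI under-calls are the
    # first two moderate eyes, and maculopathy accompanies two severe eyes.
    manual_codes = [0] * 52 + [1] * 2 + [2] * 7 + [3] * 3
    ai_codes = list(manual_codes)
    ai_codes[54] = 1  # first moderate eye read as mild
    ai_codes[55] = 1  # second moderate eye read as mild
    macula = [False] * 64
    macula[61] = True
    macula[62] = True

    records: list[GradingRecord] = []
    # Patients 1 and 2: one ungradable right eye each, flagged by both graders.
    for pid in ("P01", "P02"):
        records.append(
            GradingRecord(pid, "right", ICDRGrade.UNGRADABLE, ICDRGrade.UNGRADABLE, None, None)
        )
    # Remaining 64 eyes: left eyes of P01/P02 then both eyes of P03..P33.
    slots = [("P01", "left"), ("P02", "left")]
    for p in range(3, 34):
        slots.append((f"P{p:02d}", "right"))
        slots.append((f"P{p:02d}", "left"))
    for (pid, eye), man, ai, mac in zip(slots, manual_codes, ai_codes, macula):
        records.append(
            GradingRecord(pid, eye, ICDRGrade(man), ICDRGrade(ai), mac, mac)
        )
    return records


def filter_gradable(records: Iterable[GradingRecord]) -> list[GradingRecord]:
    """Keep eyes gradable by BOTH graders.

    An eye flagged ungradable by either grader cannot enter a paired
    comparison and is dropped.
    """
    return [r for r in records if r.gradable]


def grade_codes(records: Iterable[GradingRecord], grader: str) -> np.ndarray:
    """Ordinal codes of one grader over (already gradable) records."""
    if grader not in ("manual", "ai"):
        raise InputError(f"grader must be 'manual' or 'ai', got {grader!r}")
    attr = "manual_grade" if grader == "manual" else "ai_grade"
    codes = []
    for r in records:
        g: ICDRGrade = getattr(r, attr)
        if not g.gradable:
            raise InputError(
                "ungradable eye in grade_codes input; apply filter_gradable first"
            )
        codes.append(g.value)
    return np.asarray(codes, dtype=np.int64)


# ---------------------------------------------------------------------------
# Delimited-text I/O
# ---------------------------------------------------------------------------

_HEADER = [
    "patient_id",
    "eye",
    "manual_grade",
    "ai_grade",
    "manual_maculopathy",
    "ai_maculopathy",
]


def _bool_token(flag: bool | None) -> str:
    return "" if flag is None else str(int(flag))


def _parse_bool(token: str, where: str) -> bool | None:
    token = token.strip()
    if token == "":
        return None
    if token in ("0", "1"):
        return token == "1"
    raise InputError(f"{where}: maculopathy flag must be 0, 1 or empty, got {token!r}")


def write_grading_table(records: Iterable[GradingRecord], path: Union[str, Path, io.TextIOBase]) -> None:
    """Write a cohort as UTF-8 CSV (grades ``0|1|2|3|U``, booleans ``0|1``)."""
    own = isinstance(path, (str, Path))
    fh = open(path, "w", newline="", encoding="utf-8") if own else path
    try:
        writer = csv.writer(fh)
        writer.writerow(_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.patient_id,
                    r.eye,
                    r.manual_grade.token,
                    r.ai_grade.token,
                    _bool_token(r.manual_maculopathy),
                    _bool_token(r.ai_maculopathy),
                ]
            )
    finally:
        if own:
            fh.close()


def read_grading_table(path: Union[str, Path, io.TextIOBase]) -> list[GradingRecord]:
    """Read a cohort CSV, rejecting duplicate (patient_id, eye) pairs."""
    own = isinstance(path, (str, Path))
    fh = open(path, "r", newline="", encoding="utf-8") if own else path
    try:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration as exc:
            raise InputError("empty grading table") from exc
        if [h.strip() for h in header] != _HEADER:
            raise InputError(f"unexpected header {header!r}; expected {_HEADER!r}")
        seen: set[tuple[str, str]] = set()
        records: list[GradingRecord] = []
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 6:
                raise InputError(f"line {lineno}: expected 6 fields, got {len(row)}")
            pid, eye = row[0].strip(), row[1].strip()
            key = (pid, eye)
            if key in seen:
                raise InputError(f"line {lineno}: duplicate (patient_id, eye) {key!r}")
            seen.add(key)
            records.append(
                GradingRecord(
                    patient_id=pid,
                    eye=eye,
                    manual_grade=ICDRGrade.from_token(row[2]),
                    ai_grade=ICDRGrade.from_token(row[3]),
                    manual_maculopathy=_parse_bool(row[4], f"line {lineno}"),
                    ai_maculopathy=_parse_bool(row[5], f"line {lineno}"),
                )
            )
        return records
    finally:
        if own:
            fh.close()
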