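"""Study data model, the 9-variable input table, and the default cascade.

One row of the input table describes one void of one subject-period: who the
child is (ID, study period, agricultural flag, body weight), what exposure
the void is attributed to (route/scenario code and start time), and the
urinary observation (average excretion rate, or the raw concentration +
volume + void times it is computed from).

The average urinary excretion rate between consecutive voids is

    UER_avg = C_u * V_u / (t_c - t_p)

with ``C_u`` the metabolite concentration, ``V_u`` the void volume, and
``t_p``/``t_c`` the previous/current void times.  When void times were not
recorded, the bladder collection time is imputed from the void volume and
the age/sex-matched average 24-h urine output:

    t_c - t_p ~= (V_u / V_avg24) * 24

Missing fields are resolved through a tiered cascade — measured values
first, then values derivable from the subject's own data, then reference
defaults — and every substitution is logged with its provenance tier.

Canonical internal units: µmol/L, L, hours, kg.  The file format stores the
excretion-rate column in mmol/hr for display; conversion is an exact decimal
exponent shift, so write/read round-trips are bit-exact.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, replace
from decimal import Decimal
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Mapping

import yaml

from .errors import (
    DomainError,
    IntervalError,
    ParseError,
    ResolutionError,
    RouteCodeError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Season",
    "Slot",
    "ROUTE_INHALATION",
    "ROUTE_DERMAL",
    "BOLUS_SLOTS",
    "SubjectPeriod",
    "ExposureEvent",
    "VoidSample",
    "UERRecord",
    "InputRecord",
    "ReferenceTables",
    "Substitution",
    "compute_uer",
    "impute_void_interval",
    "clamp_interval",
    "resolve_defaults",
    "read_input_table",
    "write_input_table",
    "INPUT_COLUMNS",
]


class Season(IntEnum):
    """Study period code: 1 = summer, 2 = fall."""

    SUMMER = 1
    FALL = 2


class Slot(IntEnum):
    """Bolus event/void slot codes 3-7.

    3 = first-morning void (day 2), 4 = lunchtime void (day 2),
    5 = before-bedtime void (day 1), 6 = dinnertime void (day 2),
    7 = bolus with no assigned void slot (accepted, excluded from composites).
    """

    FIRST_MORNING = 3
    LUNCH = 4
    BEDTIME = 5
    DINNER = 6
    UNASSIGNED = 7


ROUTE_INHALATION = 1
ROUTE_DERMAL = 2
BOLUS_SLOTS = (Slot.FIRST_MORNING, Slot.LUNCH, Slot.BEDTIME, Slot.DINNER)

# Void preceding each slot in the day-1-dinner-anchored schedule.  The
# bedtime void's window opens at the exposure itself.
_PREVIOUS_SLOT = {
    Slot.FIRST_MORNING: Slot.BEDTIME,
    Slot.LUNCH: Slot.FIRST_MORNING,
    Slot.DINNER: Slot.LUNCH,
}


@dataclass(frozen=True)
class SubjectPeriod:
    """A child observed in one study period."""

    subject_id: str
    period: Season
    agricultural: bool
    body_weight: float  # kg

    def __post_init__(self):
        if not (self.body_weight > 0 and math.isfinite(self.body_weight)):
            raise DomainError("body_weight must be positive and finite")

    @property
    def label(self) -> str:
        """File-format identifier, e.g. subject 114 in summer -> '114.1'."""
        return f"{self.subject_id}.{int(self.period)}"


@dataclass(frozen=True)
class ExposureEvent:
    """Route/scenario code and timing of the exposure a void is tied to."""

    route_code: int
    start_time: float  # study-clock hours
    end_time: float | None = None  # unused for bolus events

    def __post_init__(self):
        if self.route_code not in range(1, 8):
            raise DomainError(f"route_code must be 1..7, got {self.route_code}")

    @property
    def is_bolus(self) -> bool:
        return self.route_code >= 3


@dataclass(frozen=True)
class VoidSample:
    """A spot urine void: concentration, volume and window times."""

    slot: int
    concentration: float  # µmol/L
    volume: float  # L
    t_p: float  # study-clock hours, previous void
    t_c: float  # study-clock hours, this void

    def __post_init__(self):
        if self.concentration < 0:
            raise DomainError("concentration must be non-negative")
        if self.volume <= 0:
            raise DomainError("volume must be positive")
        if not self.t_c > self.t_p:
            raise IntervalError("void times must satisfy t_c > t_p")


@dataclass(frozen=True)
class UERRecord:
    """Average urinary excretion rate over a void window (canonical µmol/h)."""

    uer_avg: float  # µmol/h
    t_p: float
    t_c: float

    def __post_init__(self):
        if self.uer_avg < 0:
            raise DomainError("uer_avg must be non-negative")
        if not self.t_c > self.t_p:
            raise IntervalError("void times must satisfy t_c > t_p")

    @property
    def interval(self) -> float:
        """Window length in hours."""
        return self.t_c - self.t_p


def compute_uer(concentration: float, volume: float, t_p: float, t_c: float) -> UERRecord:
    """Average urinary excretion rate: C_u * V_u / (t_c - t_p).

    Parameters are in canonical units (µmol/L, L, hours); the result is in
    µmol/h.  Linear in concentration and in volume; halving the interval
    doubles the rate.
    """
    if not t_c > t_p:
        raise IntervalError(f"degenerate void interval: t_p={t_p}, t_c={t_c}")
    if volume <= 0:
        raise IntervalError("void volume must be positive")
    if concentration < 0:
        raise DomainError("concentration must be non-negative")
    return UERRecord(uer_avg=concentration * volume / (t_c - t_p), t_p=t_p, t_c=t_c)


def impute_void_interval(volume: float, v_avg24: float) -> float:
    """Bladder collection time implied by a void volume.

    ``(volume / v_avg24) * 24`` hours, where ``v_avg24`` is the subject's
    expected total 24-h urine output (same unit as ``volume``).  The raw
    value can exceed 24 for unusually large voids; callers clamp with
    :func:`clamp_interval`.
    """
    if volume <= 0:
        raise DomainError("volume must be positive")
    if v_avg24 <= 0:
        raise DomainError("v_avg24 must be positive")
    return (volume / v_avg24) * 24.0


def clamp_interval(raw_hours: float) -> float:
    """Clamp an imputed interval to (0, 24], warning when it overflows.

    A spot void cannot have collected for longer than the daily cycle the
    imputation formula assumes.
    """
    if raw_hours > 24.0:
        logger.warning(
            "imputed void interval %.2f h exceeds 24 h; clamped to 24", raw_hours
        )
        return 24.0
    return raw_hours


# ---------------------------------------------------------------------------
# Reference tables and the default cascade
# ---------------------------------------------------------------------------

_DEFAULT_VOID_VOLUME_ML = {  # (age, sex) -> mL / 24 h; documented placeholders
    (3, "m"): 500.0, (3, "f"): 500.0,
    (4, "m"): 550.0, (4, "f"): 540.0,
    (5, "m"): 600.0, (5, "f"): 590.0,
    (6, "m"): 650.0, (6, "f"): 640.0,
}

_DEFAULT_BODY_WEIGHT_KG = {  # (age, sex) -> kg; documented placeholders
    (3, "m"): 15.5, (3, "f"): 15.0,
    (4, "m"): 17.5, (4, "f"): 17.0,
    (5, "m"): 19.5, (5, "f"): 19.0,
    (6, "m"): 22.0, (6, "f"): 21.5,
}

_DEFAULT_EVENT_TIMES = {  # slot -> study-clock hours
    int(Slot.BEDTIME): 21.0,  # 21:00 day 1
    int(Slot.FIRST_MORNING): 31.0,  # 07:00 day 2
    int(Slot.LUNCH): 36.0,  # 12:00 day 2
    int(Slot.DINNER): 43.0,  # 19:00 day 2
}

DEFAULT_EXPOSURE_TIME = 19.0  # dinner, 19:00 day 1

_SLOT_YAML_NAMES = {
    "first_morning": Slot.FIRST_MORNING,
    "lunch": Slot.LUNCH,
    "bedtime": Slot.BEDTIME,
    "dinner": Slot.DINNER,
}


@dataclass(frozen=True)
class ReferenceTables:
    """Age/sex-graded defaults used by the bottom tier of the cascade.

    The shipped values are editable placeholders (24-h urine volumes
    500-700 mL, weights 14-23 kg for ages 3-6); override them per run with a
    YAML file when better reference data are available.
    """

    default_void_volume: Mapping[tuple[int, str], float]  # mL / 24 h
    default_body_weight: Mapping[tuple[int, str], float]  # kg
    default_event_times: Mapping[int, float]  # slot -> study-clock hours
    exposure_time: float = DEFAULT_EXPOSURE_TIME

    def __post_init__(self):
        for tbl in (self.default_void_volume, self.default_body_weight):
            if any(v <= 0 for v in tbl.values()):
                raise DomainError("reference table values must be positive")

    @classmethod
    def default(cls) -> "ReferenceTables":
        return cls(
            default_void_volume=dict(_DEFAULT_VOID_VOLUME_ML),
            default_body_weight=dict(_DEFAULT_BODY_WEIGHT_KG),
            default_event_times=dict(_DEFAULT_EVENT_TIMES),
        )

    @classmethod
    def from_yaml(cls, path) -> "ReferenceTables":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        volumes = {
            (int(age), sex): float(v)
            for age, by_sex in raw["default_void_volume_ml_per_24h"].items()
            for sex, v in by_sex.items()
        }
        weights = {
            (int(age), sex): float(v)
            for age, by_sex in raw["default_body_weight_kg"].items()
            for sex, v in by_sex.items()
        }
        times = {
            int(_SLOT_YAML_NAMES[name]): float(v)
            for name, v in raw["default_event_times_hr"].items()
        }
        return cls(
            default_void_volume=volumes,
            default_body_weight=weights,
            default_event_times=times,
            exposure_time=float(raw.get("exposure_time_hr", DEFAULT_EXPOSURE_TIME)),
        )

    def to_yaml(self, path) -> None:
        by_age = lambda tbl: {
            str(age): {sex: tbl[(age, sex)] for sex in ("m", "f") if (age, sex) in tbl}
            for age in sorted({a for a, _ in tbl})
        }
        slot_names = {int(v): k for k, v in _SLOT_YAML_NAMES.items()}
        doc = {
            "default_void_volume_ml_per_24h": by_age(self.default_void_volume),
            "default_body_weight_kg": by_age(self.default_body_weight),
            "default_event_times_hr": {
                slot_names[s]: t for s, t in self.default_event_times.items()
            },
            "exposure_time_hr": self.exposure_time,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    def v_avg24_liters(self, age: int, sex: str) -> float:
        try:
            return self.default_void_volume[(age, sex)] / 1000.0
        except KeyError:
            raise ResolutionError(
                "v_avg24", f"no reference 24-h void volume for age {age}, sex {sex!r}"
            )

    def previous_void_time(self, slot: int) -> float:
        """Default time of the void preceding ``slot`` in the study schedule."""
        s = Slot(slot)
        if s == Slot.BEDTIME:
            return self.exposure_time
        prev = _PREVIOUS_SLOT[s]
        return self.default_event_times[int(prev)]


@dataclass(frozen=True)
class Substitution:
    """One default-cascade substitution, for the audit log."""

    field: str
    value: float
    tier: str  # 'subject-derived' or 'reference-default'
    detail: str = ""


@dataclass(frozen=True)
class InputRecord:
    """One row of the 9-variable input table (possibly partially specified).

    Mandatory identity fields are the subject-period label parts, the
    agricultural flag and the route/scenario code; everything else may be
    absent and resolvable by :func:`resolve_defaults`.  Companion raw-mode
    fields (concentration, volume) let the excretion rate be computed rather
    than supplied.
    """

    subject_id: str
    period: Season
    agricultural: bool
    route_code: int
    uer_avg: float | None = None  # µmol/h (canonical; file stores mmol/hr)
    body_weight: float | None = None  # kg
    exposure_start: float | None = None  # study-clock hours
    exposure_end: float | None = None
    t_p: float | None = None
    t_c: float | None = None
    concentration: float | None = None  # µmol/L
    volume: float | None = None  # L

    def __post_init__(self):
        if self.route_code not in range(1, 8):
            raise DomainError(f"route_code must be 1..7, got {self.route_code}")
        if self.uer_avg is not None and self.uer_avg < 0:
            raise DomainError("uer_avg must be non-negative")
        if self.concentration is not None and self.concentration < 0:
            raise DomainError("concentration must be non-negative")
        if self.volume is not None and self.volume <= 0:
            raise DomainError("volume must be positive")

    # -- typed views -------------------------------------------------------
    @property
    def label(self) -> str:
        return f"{self.subject_id}.{int(self.period)}"

    @property
    def slot(self) -> int:
        return self.route_code

    @property
    def subject_period(self) -> SubjectPeriod:
        if self.body_weight is None:
            raise ResolutionError("body_weight", f"{self.label}: body weight unresolved")
        return SubjectPeriod(self.subject_id, self.period, self.agricultural, self.body_weight)

    @property
    def event(self) -> ExposureEvent:
        if self.exposure_start is None:
            raise ResolutionError("exposure_start", f"{self.label}: exposure time unresolved")
        return ExposureEvent(self.route_code, self.exposure_start, self.exposure_end)

    @property
    def uer(self) -> UERRecord:
        if self.uer_avg is None or self.t_p is None or self.t_c is None:
            raise ResolutionError("uer", f"{self.label}: excretion rate or window unresolved")
        return UERRecord(self.uer_avg, self.t_p, self.t_c)

    @property
    def void(self) -> VoidSample | None:
        if None in (self.concentration, self.volume, self.t_p, self.t_c):
            return None
        return VoidSample(self.slot, self.concentration, self.volume, self.t_p, self.t_c)

    @property
    def is_complete(self) -> bool:
        return (
            self.body_weight is not None
            and self.exposure_start is not None
            and self.uer_avg is not None
            and self.t_p is not None
            and self.t_c is not None
        )


def resolve_defaults(
    raw_record: InputRecord,
    age: int,
    sex: str,
    tables: ReferenceTables,
) -> tuple[InputRecord, list[Substitution]]:
    """Fill missing fields through the tiered default cascade.

    Tiers, most to least representative: measured values are kept untouched;
    quantities derivable from the subject's own data (interval from the void
    volume, excretion rate from concentration x volume / interval) come next;
    reference defaults (age/sex-matched weight and 24-h urine volume, the
    scheduled event times) are the last resort.

    Returns the completed record and the list of substitutions performed, in
    order.  Idempotent: resolving an already-complete record returns it
    unchanged with an empty log.

    Raises
    ------
    ResolutionError
        If a required field cannot be filled by any tier (named in the
        error), or if neither an excretion rate nor a concentration+volume
        pair is available.
    """
    rec = raw_record
    subs: list[Substitution] = []

    if rec.uer_avg is None and (rec.concentration is None or rec.volume is None):
        raise ResolutionError(
            "uer_avg",
            f"{rec.label}: need either uer_avg or concentration+volume",
        )

    if rec.body_weight is None:
        try:
            w = tables.default_body_weight[(age, sex)]
        except KeyError:
            raise ResolutionError(
                "body_weight", f"no reference weight for age {age}, sex {sex!r}"
            )
        rec = replace(rec, body_weight=w)
        subs.append(Substitution("body_weight", w, "reference-default",
                                 f"age {age} {sex} reference weight"))

    if rec.exposure_start is None:
        rec = replace(rec, exposure_start=tables.exposure_time)
        subs.append(Substitution("exposure_start", tables.exposure_time,
                                 "reference-default", "scheduled exposure anchor"))

    if rec.t_c is None:
        try:
            t_c = tables.default_event_times[rec.slot]
        except KeyError:
            raise ResolutionError(
                "t_c", f"{rec.label}: no default void time for slot {rec.slot}"
            )
        rec = replace(rec, t_c=t_c)
        subs.append(Substitution("t_c", t_c, "reference-default",
                                 f"scheduled time of slot {rec.slot}"))

    if rec.t_p is None:
        if rec.volume is not None:
            interval = clamp_interval(
                impute_void_interval(rec.volume, tables.v_avg24_liters(age, sex))
            )
            t_p = rec.t_c - interval
            rec = replace(rec, t_p=t_p)
            subs.append(Substitution("t_p", t_p, "subject-derived",
                                     f"interval {interval:.3f} h from void volume"))
        else:
            try:
                t_p = tables.previous_void_time(rec.slot)
            except KeyError:
                raise ResolutionError(
                    "t_p", f"{rec.label}: no default previous-void time for slot {rec.slot}"
                )
            if not t_p < rec.t_c:
                raise ResolutionError(
                    "t_p", f"{rec.label}: default previous void {t_p} not before t_c {rec.t_c}"
                )
            rec = replace(rec, t_p=t_p)
            subs.append(Substitution("t_p", t_p, "reference-default",
                                     "scheduled previous-void time"))

    if rec.volume is None and rec.concentration is not None:
        vol = tables.v_avg24_liters(age, sex) * (rec.t_c - rec.t_p) / 24.0
        rec = replace(rec, volume=vol)
        subs.append(Substitution("volume", vol, "reference-default",
                                 "reference 24-h output scaled to window"))

    if rec.uer_avg is None:
        uer = compute_uer(rec.concentration, rec.volume, rec.t_p, rec.t_c)
        rec = replace(rec, uer_avg=uer.uer_avg)
        subs.append(Substitution("uer_avg", uer.uer_avg, "subject-derived",
                                 "C_u * V_u / (t_c - t_p)"))

    for s in subs:
        logger.info("%s: filled %s = %.6g (%s; %s)", rec.label, s.field, s.value, s.tier, s.detail)
    return rec, subs


# ---------------------------------------------------------------------------
# Delimited-text input table
# ---------------------------------------------------------------------------

INPUT_COLUMNS = [
    "id_period",
    "agricultural",
    "uer_avg_mmol_per_hr",
    "body_weight_kg",
    "route_code",
    "exposure_start_hr",
    "exposure_end_hr",
    "prev_void_hr",
    "curr_void_hr",
]
_RAW_COLUMNS = ["conc_umol_per_L", "void_volume_L"]


def _umol_from_mmol_str(text: str) -> float:
    """Parse a display-unit (mmol/hr) cell to canonical µmol/h, exactly."""
    return float(Decimal(text).scaleb(3))


def _mmol_str_from_umol(value: float) -> str:
    """Format a canonical µmol/h value as a mmol/hr cell, exactly."""
    return format(Decimal(repr(value)).scaleb(-3), "f")


def _parse_float(text: str, row: int, column: str) -> float:
    try:
        return float(text)
    except ValueError:
        raise ParseError(row, f"column {column!r}: cannot parse {text!r} as a number")


def read_input_table(path) -> list[InputRecord]:
    """Read the 9-column (plus optional raw-mode) CSV input table.

    The ``id_period`` column encodes subject and period, e.g. ``114.1`` is
    subject 114 in the summer period.  Empty cells are missing values, to be
    filled by :func:`resolve_defaults`.
    """
    path = Path(path)
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in INPUT_COLUMNS if c not in header]
        if missing:
            raise ParseError(0, f"missing required columns: {missing}")
        records = []
        for i, row in enumerate(reader, start=2):
            records.append(_parse_row(row, i))
    return records


def _parse_row(row: Mapping[str, str], rownum: int) -> InputRecord:
    def cell(col):
        v = (row.get(col) or "").strip()
        return v or None

    id_period = cell("id_period")
    if id_period is None or "." not in id_period:
        raise ParseError(rownum, f"id_period {id_period!r} is not of the form SUBJECT.PERIOD")
    subject_id, period_txt = id_period.rsplit(".", 1)
    try:
        period = Season(int(period_txt))
    except ValueError:
        raise ParseError(rownum, f"study period {period_txt!r} must be 1 (summer) or 2 (fall)")

    agri_txt = (cell("agricultural") or "").lower()
    if agri_txt in {"1", "true", "yes"}:
        agricultural = True
    elif agri_txt in {"0", "false", "no"}:
        agricultural = False
    else:
        raise ParseError(rownum, f"agricultural flag {agri_txt!r} must be 0/1")

    route_txt = cell("route_code")
    try:
        route_code = int(route_txt)
    except (TypeError, ValueError):
        raise ParseError(rownum, f"route_code {route_txt!r} is not an integer")
    if route_code not in range(1, 8):
        raise RouteCodeError(rownum, f"unknown route/scenario code {route_code}")
    if route_code == Slot.UNASSIGNED:
        logger.warning("row %d: bolus code 7 has no assigned void slot", rownum)

    uer_txt = cell("uer_avg_mmol_per_hr")
    optional = lambda col: (
        None if cell(col) is None else _parse_float(cell(col), rownum, col)
    )
    try:
        return InputRecord(
            subject_id=subject_id,
            period=period,
            agricultural=agricultural,
            route_code=route_code,
            uer_avg=None if uer_txt is None else _umol_from_mmol_str(uer_txt),
            body_weight=optional("body_weight_kg"),
            exposure_start=optional("exposure_start_hr"),
            exposure_end=optional("exposure_end_hr"),
            t_p=optional("prev_void_hr"),
            t_c=optional("curr_void_hr"),
            concentration=optional("conc_umol_per_L"),
            volume=optional("void_volume_L"),
        )
    except DomainError as exc:
        raise ParseError(rownum, str(exc))


def write_input_table(records: Iterable[InputRecord], path) -> None:
    """Write records to the documented CSV layout (raw-mode columns included).

    ``write_input_table`` then :func:`read_input_table` is the identity on
    valid records, bit-exactly: floats are written with shortest round-trip
    precision and the display-unit shift of the excretion-rate column is an
    exact decimal operation.
    """
    path = Path(path)
    fmt = lambda v: "" if v is None else repr(float(v))
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(INPUT_COLUMNS + _RAW_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.label,
                    int(r.agricultural),
                    "" if r.uer_avg is None else _mmol_str_from_umol(r.uer_avg),
                    fmt(r.body_weight),
                    r.route_code,
                    fmt(r.exposure_start),
                    fmt(r.exposure_end),
                    fmt(r.t_p),
                    fmt(r.t_c),
                    fmt(r.concentration),
                    fmt(r.volume),
                ]
            )
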