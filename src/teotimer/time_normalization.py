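"""Normalization of time, duration and periodic expressions from report narratives.

Report narratives date events in heterogeneous ways — "July 6th", "3-29-90",
"08-08", "Eighteen days", "2 wks", "3 times/day ... for 2 weeks". This module
parses such expressions into the typed entities of :mod:`teotimer.temporal_model`,
preserving the original text verbatim, recording the granularity the text
supports, and completing missing years from the report's structured fields
(e.g., the "Vaccinated" date) via a :class:`NormalizationContext`.

The expression language is small and regular, so parsing is a set of ordered
regular-expression patterns plus a number-word table rather than a grammar.
Dates are month-day-year by default (VAERS is a US system); two-digit years
pivot at 30 (>= 30 reads as 19xx). Week arithmetic is exact (7 days);
month/year arithmetic is calendar-aware, never a 30/365-day approximation.
"""

from __future__ import annotations

import datetime as dt
import re
from dataclasses import dataclass
from typing import Optional

from dateutil.relativedelta import relativedelta

from .errors import AmbiguityError, NotPeriodicError, ParseError
from .temporal_model import (
    Duration,
    Granularity,
    PeriodicInterval,
    TimeInstant,
    precision_of,
    truncate_normalized,
)

__all__ = [
    "NormalizationContext",
    "parse_time_expression",
    "parse_duration_expression",
    "format_duration",
    "parse_periodic_expression",
    "resolve_partial_date",
    "to_date",
    "add_duration_to_date",
    "calendar_days_between",
]


@dataclass
class NormalizationContext:
    """Anchors and conventions used to complete partial dates.

    ``anchor_date`` is typically the report's structured vaccination date;
    ``anchor_year`` may be given alone when only the year is known.
    """

    anchor_year: Optional[int] = None
    anchor_date: Optional[dt.date] = None
    date_order: Optional[str] = "month-day-year"
    two_digit_year_pivot: int = 30

    def __post_init__(self):
        if not 0 <= self.two_digit_year_pivot <= 99:
            raise ParseError(f"two-digit-year pivot must be in [0, 99]")
        if self.anchor_year is None and self.anchor_date is not None:
            self.anchor_year = self.anchor_date.year

    def expand_year(self, two_digit: int) -> int:
        return (1900 if two_digit >= self.two_digit_year_pivot else 2000) + two_digit


_MONTHS = {
    name: i + 1
    for i, name in enumerate(
        "january february march april may june july august september october november december".split()
    )
}
_MONTHS.update({name[:3]: num for name, num in list(_MONTHS.items())})
_MONTHS["sept"] = 9

_ONES = "zero one two three four five six seven eight nine ten eleven twelve thirteen fourteen fifteen sixteen seventeen eighteen nineteen twenty".split()
_TENS = {"thirty": 30, "forty": 40, "fifty": 50, "sixty": 60, "seventy": 70, "eighty": 80, "ninety": 90}
NUMBER_WORDS = {w: i for i, w in enumerate(_ONES)}
NUMBER_WORDS.update(_TENS)
for tens_word, tens_val in {"twenty": 20, **_TENS}.items():
    for ones_val in range(1, 10):
        NUMBER_WORDS[f"{tens_word}-{_ONES[ones_val]}"] = tens_val + ones_val
        NUMBER_WORDS[f"{tens_word} {_ONES[ones_val]}"] = tens_val + ones_val

UNIT_SYNONYMS = {
    "second": "second", "seconds": "second", "sec": "second", "secs": "second",
    "minute": "minute", "minutes": "minute", "min": "minute", "mins": "minute",
    "hour": "hour", "hours": "hour", "hr": "hour", "hrs": "hour", "h": "hour",
    "day": "day", "days": "day", "d": "day",
    "week": "week", "weeks": "week", "wk": "week", "wks": "week", "w": "week",
    "month": "month", "months": "month", "mo": "month", "mos": "month",
    "year": "year", "years": "year", "yr": "year", "yrs": "year",
}

_UNIT_RE = "|".join(sorted(UNIT_SYNONYMS, key=len, reverse=True))
_NUMWORD_RE = "|".join(sorted(NUMBER_WORDS, key=len, reverse=True))
_DURATION_RE = re.compile(
    rf"\b(?:(?P<num>\d+(?:\.\d+)?)|(?P<word>{_NUMWORD_RE})|(?P<article>an?))"
    rf"\s+(?P<unit>{_UNIT_RE})\b",
    re.IGNORECASE,
)


def _clean(text: str) -> str:
    # strips superscript markup ("July 6^th^") and ordinal suffixes
    t = text.replace("^", " ")
    t = re.sub(r"(?<=\d)\s*(st|nd|rd|th)\b", "", t, flags=re.IGNORECASE)
    return re.sub(r"\s+", " ", t).strip(" .,;")


def parse_time_expression(text: str, ctx: Optional[NormalizationContext] = None) -> TimeInstant:
    """Parse a time expression into a :class:`TimeInstant`.

    The original text is preserved verbatim; the normalized value is filled to
    the precision the text supports, with a missing year completed from ``ctx``.
    Raises :class:`ParseError` naming the offending token when unparseable.
    """
    if not text:
        raise ParseError("empty time expression", token=text)
    ctx = ctx or NormalizationContext()
    cleaned = _clean(text)
    normalized = _normalize_date_text(cleaned, ctx)
    instant = TimeInstant(orig_text=text, normalized=normalized)
    return resolve_partial_date(instant, ctx)


def _normalize_date_text(cleaned: str, ctx: NormalizationContext) -> str:
    # ISO forms first: 2006-07-06 / 1990-03 / 2006
    m = re.fullmatch(r"(\d{4})(?:-(\d{1,2})(?:-(\d{1,2}))?)?", cleaned)
    if m:
        year, month, day = int(m.group(1)), m.group(2), m.group(3)
        return _build_iso(year, int(month) if month else None, int(day) if day else None, cleaned)

    # month-name forms: July 6 / July 6, 2006 / July 2006 / July
    m = re.fullmatch(
        r"(?P<mon>[A-Za-z]+)\.?(?:\s+(?P<day>\d{1,2}))?(?:[,\s]+\s*(?P<year>\d{2,4}))?",
        cleaned,
    )
    if m and m.group("mon").lower() in _MONTHS:
        month = _MONTHS[m.group("mon").lower()]
        day = int(m.group("day")) if m.group("day") else None
        year = m.group("year")
        if year is not None:
            year = int(year)
            if year < 100:
                year = ctx.expand_year(year)
            return _build_iso(year, month, day, cleaned)
        return _build_partial(month, day, cleaned)

    # numeric month-day(-year) forms: 3-29-90 / 03/29/1990 / 08-08
    m = re.fullmatch(r"(\d{1,2})[-/](\d{1,2})(?:[-/](\d{2,4}))?", cleaned)
    if m:
        a, b, y = int(m.group(1)), int(m.group(2)), m.group(3)
        if ctx.date_order is None and a <= 12 and b <= 12 and a != b:
            raise AmbiguityError(
                f"date {cleaned!r} is ambiguous without a date-order convention",
                token=cleaned,
            )
        if (ctx.date_order or "month-day-year") != "month-day-year":
            a, b = b, a
        month, day = a, b
        if y is not None:
            year = int(y)
            if year < 100:
                year = ctx.expand_year(year)
            return _build_iso(year, month, day, cleaned)
        return _build_partial(month, day, cleaned)

    raise ParseError(f"cannot parse time expression {cleaned!r}", token=cleaned)


def _build_iso(year: int, month: Optional[int], day: Optional[int], token: str) -> str:
    if month is None:
        return f"{year:04d}"
    if day is None:
        if not 1 <= month <= 12:
            raise ParseError(f"month out of range in {token!r}", token=token)
        return f"{year:04d}-{month:02d}"
    try:
        return dt.date(year, month, day).isoformat()
    except ValueError as exc:
        raise ParseError(f"invalid calendar date in {token!r}: {exc}", token=token) from None


def _build_partial(month: int, day: Optional[int], token: str) -> str:
    if not 1 <= month <= 12:
        raise ParseError(f"month out of range in {token!r}", token=token)
    if day is None:
        return f"--{month:02d}"
    if not 1 <= day <= 31:
        raise ParseError(f"day out of range in {token!r}", token=token)
    return f"--{month:02d}-{day:02d}"


def resolve_partial_date(
    instant: TimeInstant,
    ctx: NormalizationContext,
    ordering_hint: Optional[str] = None,
) -> TimeInstant:
    """Complete a year-less instant from the context anchor.

    With ``ordering_hint="after_anchor"`` a completed date that would precede
    the anchor date rolls the year forward by one (and symmetrically for
    ``"before_anchor"``). An instant that is already complete is returned
    unchanged; with no context year available the instant is returned with the
    ``unresolved`` flag set — not an error.
    """
    if instant.normalized is None or not instant.normalized.startswith("--"):
        return instant
    if ctx.anchor_year is None:
        return TimeInstant(
            orig_text=instant.orig_text,
            normalized=instant.normalized,
            granularity=instant.granularity,
            unresolved=True,
        )
    completed = f"{ctx.anchor_year:04d}-{instant.normalized[2:]}"
    # validate (e.g., Feb 30 with a completed year)
    if precision_of(completed) == Granularity.DAY:
        try:
            to_date(completed)
        except ParseError:
            raise ParseError(
                f"completed date {completed!r} is not a valid calendar date",
                token=instant.orig_text,
            ) from None
    if ordering_hint in ("after_anchor", "before_anchor") and ctx.anchor_date is not None:
        gran = precision_of(completed)
        anchor_trunc = truncate_normalized(ctx.anchor_date.isoformat(), gran)
        if ordering_hint == "after_anchor" and completed < anchor_trunc:
            completed = f"{ctx.anchor_year + 1:04d}-{instant.normalized[2:]}"
        elif ordering_hint == "before_anchor" and completed > anchor_trunc:
            completed = f"{ctx.anchor_year - 1:04d}-{instant.normalized[2:]}"
    return TimeInstant(
        orig_text=instant.orig_text,
        normalized=completed,
        granularity=instant.granularity,
        unresolved=False,
    )


def parse_duration_expression(text: str) -> Duration:
    """Parse a duration expression ("Eighteen days", "2 wks") into a Duration."""
    if not text:
        raise ParseError("empty duration expression", token=text)
    m = _DURATION_RE.search(text)
    if not m:
        raise ParseError(f"no quantity+unit found in {text!r}", token=text)
    if m.group("num") is not None:
        value = float(m.group("num"))
    elif m.group("word") is not None:
        value = float(NUMBER_WORDS[m.group("word").lower().replace("  ", " ")])
    else:  # "a week", "an hour"
        value = 1.0
    unit = UNIT_SYNONYMS[m.group("unit").lower()]
    return Duration(value=value, unit=Granularity(unit))


def format_duration(duration: Duration) -> str:
    """Inverse of :func:`parse_duration_expression` on the controlled vocabulary."""
    v = duration.value
    v = int(v) if float(v).is_integer() else v
    return f"{v} {duration.unit.value}{'' if v == 1 else 's'}"


_FREQ_RE = re.compile(
    rf"(?:(?P<count>\d+)\s*(?:times?|x)|(?P<once>once|twice)|(?P<times>times?))"
    rf"\s*(?:/|\s+per\s+|\s+an?\s+|\s+each\s+)\s*(?P<period>{_UNIT_RE})\b",
    re.IGNORECASE,
)


def parse_periodic_expression(
    text: str, ctx: Optional[NormalizationContext] = None
) -> PeriodicInterval:
    """Parse a repeating schedule such as
    "Exercise 20 minutes 3 times/day starting from July 21 for 2 weeks".

    Raises :class:`NotPeriodicError` when the text has no frequency pattern,
    so callers can fall back to plain time/duration parsing.
    """
    if not text:
        raise ParseError("empty periodic expression", token=text)
    ctx = ctx or NormalizationContext()
    m = _FREQ_RE.search(text)
    if not m or (m.group("count") is None and m.group("once") is None):
        raise NotPeriodicError(f"no frequency pattern in {text!r}", token=text)
    if m.group("count") is not None:
        count = int(m.group("count"))
    else:
        count = {"once": 1, "twice": 2}[m.group("once").lower()]
    period = Granularity(UNIT_SYNONYMS[m.group("period").lower()])

    prefix, suffix = text[: m.start()], text[m.end():]
    per_occurrence = None
    try:
        per_occurrence = parse_duration_expression(prefix)
    except ParseError:
        pass

    anchor_start = None
    span = None
    am = re.search(r"start(?:ing|s)?\s*(?:from|on|at)?\s+(.+?)(?:\s+for\s+|$)", suffix,
                   re.IGNORECASE)
    if am:
        anchor_start = parse_time_expression(am.group(1).strip(" .,"), ctx)
    sm = re.search(r"\bfor\s+(.+)$", suffix, re.IGNORECASE)
    if sm:
        span = parse_duration_expression(sm.group(1))

    return PeriodicInterval(
        frequency_count=count,
        frequency_period=period,
        per_occurrence=per_occurrence,
        anchor_start=anchor_start,
        span=span,
    )


# --- calendar arithmetic ------------------------------------------------------


def to_date(normalized: str) -> dt.date:
    """Convert a day-precision normalized value to a date."""
    try:
        return dt.date.fromisoformat(normalized)
    except ValueError:
        raise ParseError(
            f"{normalized!r} is not a complete day-precision date", token=normalized
        ) from None


def add_duration_to_date(date: dt.date, duration: Duration, sign: int = 1) -> dt.date:
    """Shift a date by a duration, calendar-aware for months and years.

    Weeks are exactly 7 days; sub-day durations shift via real time-of-day
    arithmetic from midnight and then truncate back to the date.
    """
    v = sign * duration.value
    unit = duration.unit.value
    if unit == "day":
        return date + dt.timedelta(days=v)
    if unit == "week":
        return date + dt.timedelta(weeks=v)
    if unit == "month":
        return date + relativedelta(months=int(v))
    if unit == "year":
        return date + relativedelta(years=int(v))
    seconds = {"hour": 3600, "minute": 60, "second": 1}[unit] * v
    moment = dt.datetime.combine(date, dt.time()) + dt.timedelta(seconds=seconds)
    return moment.date()


def calendar_days_between(start: dt.date, end: dt.date) -> int:
    return (end - start).days
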