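import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teotimer.errors import AmbiguityError, NotPeriodicError, ParseError
from teotimer.temporal_model import Duration, Granularity, precision_of, truncate_normalized
from teotimer.time_normalization import (
    NormalizationContext,
    add_duration_to_date,
    format_duration,
    parse_duration_expression,
    parse_periodic_expression,
    parse_time_expression,
    resolve_partial_date,
)

CTX_2006 = NormalizationContext(anchor_year=2006)


class TestParseTimeExpression:
    @pytest.mark.parametrize(
        "text,ctx,normalized,granularity",
        [
            ("July 6^th^", CTX_2006, "2006-07-06", "day"),
            ("3-29-90", None, "1990-03-29", "day"),
            ("08-08", CTX_2006, "2006-08-08", "day"),
            ("03/29/1990", None, "1990-03-29", "day"),
            ("2006-07-06", None, "2006-07-06", "day"),
            ("1990-03", None, "1990-03", "month"),
            ("July 2006", None, "2006-07", "month"),
            ("2006", None, "2006", "year"),
            ("July 21", CTX_2006, "2006-07-21", "day"),
            ("Aug 1990", None, "1990-08", "month"),
        ],
    )
    def test_normalization(self, text, ctx, normalized, granularity):
        instant = parse_time_expression(text, ctx)
        assert instant.orig_text == text  # byte-for-byte
        assert instant.normalized == normalized
        assert instant.granularity == Granularity(granularity)

    def test_granularity_always_matches_precision(self):
        for text in ("July 6", "3-29-90", "1990-03", "2006", "July 2006"):
            instant = parse_time_expression(text, CTX_2006)
            assert instant.granularity == precision_of(instant.normalized)

    @pytest.mark.parametrize("text", ["blorp", "13-45-90", "July 99th", "", "32/1/90"])
    def test_unparseable_raises_with_token(self, text):
        with pytest.raises(ParseError):
            parse_time_expression(text, CTX_2006)

    def test_ambiguous_order_without_convention(self):
        ctx = NormalizationContext(date_order=None)
        with pytest.raises(AmbiguityError):
            parse_time_expression("08-09", ctx)

    def test_two_digit_year_pivot(self):
        assert parse_time_expression("3-29-90").normalized == "1990-03-29"
        assert parse_time_expression("3-29-05").normalized == "2005-03-29"

    def test_partial_without_context_is_unresolved(self):
        instant = parse_time_expression("08-08", NormalizationContext())
        assert instant.normalized == "--08-08"
        assert instant.unresolved


class TestResolvePartialDate:
    def test_year_completion(self):
        instant = parse_time_expression("07-06", NormalizationContext())
        resolved = resolve_partial_date(instant, CTX_2006)
        assert resolved.normalized == "2006-07-06"
        assert resolved.granularity == instant.granularity

    def test_complete_date_is_identity(self):
        instant = parse_time_expression("3-29-90", None)
        assert resolve_partial_date(instant, CTX_2006) is instant

    def test_no_context_flags_unresolved(self):
        instant = parse_time_expression("07-06", NormalizationContext())
        out = resolve_partial_date(instant, NormalizationContext())
        assert out.normalized == "--07-06" and out.unresolved

    def test_after_anchor_rolls_year_forward(self):
        ctx = NormalizationContext(anchor_date=dt.date(2006, 12, 20))
        instant = parse_time_expression("01-09", NormalizationContext())
        out = resolve_partial_date(instant, ctx, ordering_hint="after_anchor")
        assert out.normalized == "2007-01-09"

    def test_completion_then_truncation_recovers_input(self):
        for text in ("07-06", "12-31", "Aug"):
            instant = parse_time_expression(text, NormalizationContext())
            resolved = resolve_partial_date(instant, CTX_2006)
            truncated = truncate_normalized(resolved.normalized, instant.granularity)
            assert truncated == f"2006-{instant.normalized[2:]}"
            assert truncated[5:] == instant.normalized[2:]


class TestParseDuration:
    @pytest.mark.parametrize(
        "text,value,unit",
        [
            ("Eighteen days", 18, "day"),
            ("2 wks", 2, "week"),
            ("20 minutes", 20, "minute"),
            ("1 day", 1, "day"),
            ("a week", 1, "week"),
            ("3 mos", 3, "month"),
            ("twenty-one days", 21, "day"),
            ("Dx: vasculitis 2 wks later", 2, "week"),
        ],
    )
    def test_parse(self, text, value, unit):
        assert parse_duration_expression(text) == Duration(value, Granularity(unit))

    @pytest.mark.parametrize("text", ["", "later", "three", "days"])
    def test_unparseable(self, text):
        with pytest.raises(ParseError):
            parse_duration_expression(text)

    @settings(derandomize=True, max_examples=60)
    @given(
        value=st.integers(min_value=0, max_value=500),
        unit=st.sampled_from(list(Granularity)),
    )
    def test_parse_format_roundtrip(self, value, unit):
        duration = Duration(value, unit)
        assert parse_duration_expression(format_duration(duration)) == duration


class TestParsePeriodic:
    def test_exercise_example(self):
        p = parse_periodic_expression(
            "Exercise 20 minutes 3 times/day starting from July 21 for 2 weeks",
            CTX_2006,
        )
        assert p.frequency_count == 3
        assert p.frequency_period == Granularity.DAY
        assert p.per_occurrence == Duration(20, Granularity.MINUTE)
        assert p.anchor_start.normalized == "2006-07-21"
        assert p.span == Duration(2, Granularity.WEEK)

    def test_once_a_week(self):
        p = parse_periodic_expression("once a week for 1 month")
        assert p.frequency_count == 1
        assert p.frequency_period == Granularity.WEEK
        assert p.span == Duration(1, Granularity.MONTH)
        assert p.per_occurrence is None

    def test_non_periodic_falls_through(self):
        with pytest.raises(NotPeriodicError):
            parse_periodic_expression("fever for 3 days")


class TestCalendarArithmetic:
    def test_week_is_exactly_seven_days(self):
        d = dt.date(2006, 7, 24)
        assert add_duration_to_date(d, Duration(2, Granularity.WEEK)) == d + dt.timedelta(days=14)

    def test_month_is_calendar_aware(self):
        assert add_duration_to_date(dt.date(2006, 1, 31), Duration(1, Granularity.MONTH)) == dt.date(2006, 2, 28)
        assert add_duration_to_date(dt.date(2006, 7, 6), Duration(3, Granularity.MONTH)) == dt.date(2006, 10, 6)

    def test_negative_shift(self):
        assert add_duration_to_date(dt.date(2006, 7, 24), Duration(18, Granularity.DAY), sign=-1) == dt.date(2006, 7, 6)
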