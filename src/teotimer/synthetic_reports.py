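"""Deterministic generator of VAERS-like report fixtures with known timelines.

Each generated report mimics the shape of a real adverse-event record: a
structured block (report id, sex, vaccination date, vaccine, symptom list) and
a narrative annotation list with a vaccination anchor followed by ``k`` adverse
events. Event times are expressed the way narratives express them — as
relative durations from a prior event ("18 days after ...", sometimes in weeks
or number words, chaining off the previous event half the time) or as absolute
dates, possibly year-less ("08-08") so the year must be completed from the
structured vaccination date. A minority of events carry only month-granular
dates and are unresolvable to a day offset — their ground-truth offset is None.

The ground truth returned with each record is the timeline the full pipeline
(read -> annotate -> reason -> build) must recover exactly. A single integer
seed drives everything; report ``index`` selects an independent substream, so
cohorts are reproducible regardless of generation order.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidInputError
from .ontology_annotation import default_lexicon, normalize_label
from .rdf_io import ReportRecord, read_report
from .timeline_analysis import Timeline, TimelineEntry

__all__ = ["GeneratorParams", "generate_report", "generate_cohort", "timeline_signature"]


def timeline_signature(timeline: Timeline) -> list[tuple]:
    """Order-preserving projection of a timeline onto the fields the generator
    plants: (event id, canonical term, date, day offset, unresolved flag)."""
    return [
        (e.event_id, e.term, e.date, e.day_offset, e.unresolved)
        for e in timeline.entries
    ]

_DEFAULT_POOL = [
    "rash",
    "nausea",
    "fever",
    "arthralgia",
    "injection site reaction",
    "headache",
    "vomiting",
    "fatigue",
    "dizziness",
    "myalgia",
    "chills",
]

_NUM_WORDS = {
    2: "two", 3: "three", 4: "four", 5: "five", 6: "six", 7: "seven",
    8: "eight", 9: "nine", 10: "ten", 14: "fourteen", 18: "eighteen",
}


@dataclass
class GeneratorParams:
    """Study conditions for the synthetic cohort.

    ``offset_distribution`` is either ``("uniform", lo, hi)`` — day gaps between
    consecutive events drawn uniformly — or ``("fixed", [o1, o2, ...])`` — exact
    day offsets from the anchor. ``fraction_relative`` is the probability an
    event's time is stated as a duration from a prior event rather than as an
    absolute (possibly year-less) date. ``granularity_mix`` weights day- vs
    month-granular time statements.
    """

    seed: int = 0
    n_reports: int = 3
    n_events_range: tuple = (2, 6)
    offset_distribution: tuple = ("uniform", 1, 30)
    fraction_relative: float = 0.5
    granularity_mix: dict = field(default_factory=lambda: {"day": 0.9, "month": 0.1})
    symptom_pool: list = field(default_factory=lambda: list(_DEFAULT_POOL))
    anchor_date_range: tuple = ("1990-01-01", "1999-12-31")
    vaccine: str = "hepatitis B vaccine"

    def __post_init__(self):
        lo, hi = self.n_events_range
        if lo > hi or lo < 0:
            raise InvalidInputError("n_events_range must satisfy 0 <= min <= max")
        if not 0.0 <= self.fraction_relative <= 1.0:
            raise InvalidInputError("fraction_relative must be in [0, 1]")
        if any(w < 0 for w in self.granularity_mix.values()):
            raise InvalidInputError("granularity weights must be >= 0")


def _rng_for(params: GeneratorParams, index: int) -> np.random.Generator:
    return np.random.default_rng([abs(params.seed) % (2**31), index])


def _duration_text(days: int, rng: np.random.Generator) -> str:
    if days > 0 and days % 7 == 0 and rng.random() < 0.5:
        weeks = days // 7
        return f"{weeks} wk{'s' if weeks != 1 else ''}"
    if days in _NUM_WORDS and rng.random() < 0.3:
        return f"{_NUM_WORDS[days]} days"
    return f"{days} day{'s' if days != 1 else ''}"


def generate_report(params: GeneratorParams, index: int) -> tuple[ReportRecord, Timeline]:
    """Generate one report and the ground-truth timeline it encodes."""
    if not params.symptom_pool:
        raise InvalidInputError("symptom_pool must not be empty")
    rng = _rng_for(params, index)
    lexicon = default_lexicon()

    start = dt.date.fromisoformat(params.anchor_date_range[0])
    end = dt.date.fromisoformat(params.anchor_date_range[1])
    anchor = start + dt.timedelta(days=int(rng.integers(0, (end - start).days + 1)))

    lo, hi = params.n_events_range
    if params.offset_distribution[0] == "fixed":
        offsets = [int(o) for o in params.offset_distribution[1]]
        k = len(offsets)
    else:
        _, glo, ghi = params.offset_distribution
        k = int(rng.integers(lo, hi + 1))
        offsets, cum = [], 0
        for _ in range(k):
            cum += int(rng.integers(glo, ghi + 1))
            offsets.append(cum)

    levels = sorted(params.granularity_mix)
    weights = np.array([params.granularity_mix[l] for l in levels], dtype=float)
    weights = weights / weights.sum()

    report_id = f"SYN-{params.seed}-{index}"
    annotations = [
        {"kind": "event", "id": "ev0", "text": params.vaccine},
        {"kind": "time", "event": "ev0", "text": anchor.isoformat()},
    ]
    symptoms_structured: list[str] = []
    truth_rows = [("ev0", normalize_label(params.vaccine, lexicon),
                   frozenset({"VO"}), anchor.isoformat(), 0, False, 0)]

    prev_day_event: Optional[tuple[str, int]] = ("ev0", 0)
    for i, offset in enumerate(offsets, start=1):
        eid = f"ev{i}"
        surface = str(rng.choice(params.symptom_pool))
        date = anchor + dt.timedelta(days=offset)
        gran = str(rng.choice(levels, p=weights))
        annotations.append({"kind": "event", "id": eid, "text": surface})
        symptoms_structured.append(surface)

        if gran == "month":
            # month-granular absolute date: day offset unrecoverable by design
            annotations.append(
                {"kind": "time", "event": eid, "text": f"{date.year}-{date.month:02d}"}
            )
            truth_rows.append(
                (eid, normalize_label(surface, lexicon), frozenset({"OAE", "MedDRA"}),
                 f"{date.year}-{date.month:02d}", None, True, i)
            )
            continue

        if rng.random() < params.fraction_relative:
            # relative: chain off the previous day-resolved event half the time
            target, target_offset = "ev0", 0
            if (
                prev_day_event is not None
                and prev_day_event[0] != "ev0"
                and prev_day_event[1] < offset  # keep the chain forward in time
                and rng.random() < 0.5
            ):
                target, target_offset = prev_day_event
            gap = offset - target_offset
            annotations.append(
                {"kind": "relation", "source": eid, "relation": "after",
                 "target": target, "offset": _duration_text(gap, rng)}
            )
        else:
            # absolute: year-less month-day 70% of the time (anchor completes it)
            if rng.random() < 0.7:
                text = f"{date.month:02d}-{date.day:02d}"
            else:
                text = f"{date.month}/{date.day}/{date.year}"
            annotations.append({"kind": "time", "event": eid, "text": text})
        truth_rows.append(
            (eid, normalize_label(surface, lexicon), frozenset({"OAE", "MedDRA"}),
             date.isoformat(), offset, False, i)
        )
        prev_day_event = (eid, offset)

    record = read_report(
        {
            "report_id": report_id,
            "sex": str(rng.choice(["F", "M"])),
            "age": {"value": int(rng.integers(1, 80)), "unit": "year"},
            "structured_dates": {
                "vaccinated": anchor.isoformat(),
                "onset": (anchor + dt.timedelta(days=min([o for o in offsets] or [0])))
                .isoformat(),
            },
            "vaccines": [params.vaccine],
            "symptoms": symptoms_structured,
            "narrative_annotations": annotations,
        }
    )

    # ground-truth timeline, ordered exactly as build_timeline orders entries:
    # day-resolved events by (date, narrative index); month-granular events by
    # (anchor date, flagged, narrative index) since nothing constrains them
    def sort_key(row):
        eid, term, vocabularies, date, offset, unresolved, narr = row
        if not unresolved:
            return (date, 0, narr)
        return (anchor.isoformat(), 1, narr)

    entries = [
        TimelineEntry(
            event_id=eid, label=eid, term=term, vocabularies=vocabularies,
            date=date, day_offset=offset, unresolved=unresolved,
        )
        for eid, term, vocabularies, date, offset, unresolved, narr
        in sorted(truth_rows, key=sort_key)
    ]
    truth = Timeline(report_id=report_id, anchor="ev0", entries=entries)
    return record, truth


def generate_cohort(params: GeneratorParams) -> list[tuple[ReportRecord, Timeline]]:
    """Generate ``params.n_reports`` reports sharing one symptom pool."""
    if params.n_reports < 0:
        raise InvalidInputError("n_reports must be >= 0")
    return [generate_report(params, i) for i in range(params.n_reports)]
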