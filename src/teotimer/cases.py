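"""Packaged worked cases.

Two small cases exercised throughout the tests and documentation:

* :func:`mmr_case` — the five-event MMR narrative ("18 month-old vaccinated
  w/MMR on July 6th. Eighteen days after vaccination she developed a fever of
  104 and macular rash ... Dx: vasculitis 2 wks later. Patient hospitalized
  08-08"), with the year 2006 pinned by the report's structured context.
* :func:`engerix_report` — a hepatitis-B (Engerix-B) report in the JSON report
  dialect, carrying the structured onset date 1990-03-29 and the annotation
  linking "1ST ENGERIX-B DOSE" to "3-29-90".

plus :func:`synthetic_hep_cohort`, a three-report synthetic mirror of the
canonical cross-report comparison patterns (shared symptoms at different
offsets, differing frequencies, reversed orders).
"""

from __future__ import annotations

import datetime as dt
from importlib import resources

from .rdf_io import ReportRecord, read_report
from .temporal_model import TemporalGraph, add_event, assert_relation, attach_time
from .time_normalization import NormalizationContext, parse_duration_expression, parse_time_expression

__all__ = ["mmr_context", "mmr_case", "engerix_report", "synthetic_hep_cohort"]


def mmr_context() -> NormalizationContext:
    """Context for the MMR case: the record's structured year is 2006."""
    return NormalizationContext(anchor_year=2006, anchor_date=dt.date(2006, 7, 6))


def mmr_case() -> TemporalGraph:
    """The five-event MMR worked case as a temporal graph.

    Events: vaccination (dated July 6th), fever and macular rash (each 18 days
    after vaccination), vasculitis (2 wks after fever and rash), and the
    hospitalization (dated 08-08). The hospitalization/vasculitis order is NOT
    stated — recovering it is the reasoner's job.
    """
    ctx = mmr_context()
    g = TemporalGraph()
    vaccination = add_event(g, "vaccinated w/MMR")
    attach_time(g, vaccination.id, parse_time_expression("July 6^th^", ctx))
    fever = add_event(g, "fever")
    rash = add_event(g, "macular rash")
    vasculitis = add_event(g, "vasculitis")
    hospitalization = add_event(g, "patient hospitalization")

    eighteen_days = parse_duration_expression("Eighteen days")
    two_weeks = parse_duration_expression("2 wks")
    assert_relation(g, fever.id, "after", vaccination.id, offset=eighteen_days)
    assert_relation(g, rash.id, "after", vaccination.id, offset=eighteen_days)
    assert_relation(g, vasculitis.id, "after", fever.id, offset=two_weeks)
    assert_relation(g, vasculitis.id, "after", rash.id, offset=two_weeks)
    attach_time(g, hospitalization.id, parse_time_expression("08-08", ctx))
    return g


def engerix_report() -> ReportRecord:
    """The packaged Engerix-B report fixture, parsed."""
    text = resources.files("teotimer.data").joinpath("report_engerix_b.json").read_text(
        encoding="utf-8"
    )
    return read_report(text)


def _hep_report(report_id: str, anchor: dt.date, symptoms: list[tuple[str, int]]) -> dict:
    """One synthetic hepatitis-vaccine report; symptoms are (surface, day offset)."""
    annotations = [
        {"kind": "event", "id": "ev0", "text": "hep B vaccine"},
        {"kind": "time", "event": "ev0", "text": anchor.isoformat()},
    ]
    for i, (surface, offset) in enumerate(symptoms, start=1):
        annotations.append({"kind": "event", "id": f"ev{i}", "text": surface})
        annotations.append(
            {"kind": "relation", "source": f"ev{i}", "relation": "after",
             "target": "ev0", "offset": f"{offset} days"}
        )
    return {
        "report_id": report_id,
        "structured_dates": {"vaccinated": anchor.isoformat()},
        "vaccines": ["hepatitis B vaccine"],
        "symptoms": sorted({s for s, _ in symptoms}),
        "narrative_annotations": annotations,
    }


def synthetic_hep_cohort() -> list[ReportRecord]:
    """Three synthetic hepatitis-vaccine reports mirroring the canonical
    comparison patterns:

    * rash shared at day 3 (HEP-1) vs day 8 (HEP-2); influenza-like illness and
      arthralgia shared at different days,
    * nausea twice in HEP-1, once in HEP-2, absent in HEP-3,
    * injection site reaction then arthralgia in HEP-1, the opposite order in
      HEP-2; HEP-3's injection site reaction on day 2 instead of day 1.
    """
    reports = [
        _hep_report(
            "HEP-1",
            dt.date(1999, 3, 1),
            [
                ("injection site reaction", 1),
                ("nausea", 2),
                ("rash", 3),
                ("flu-like illness", 4),
                ("arthralgia", 5),
                ("nausea", 6),
            ],
        ),
        _hep_report(
            "HEP-2",
            dt.date(1999, 4, 10),
            [
                ("arthralgia", 0),
                ("injection site reaction", 1),
                ("nausea", 5),
                ("influenza-like illness", 7),
                ("rash", 8),
            ],
        ),
        _hep_report(
            "HEP-3",
            dt.date(1999, 5, 20),
            [
                ("injection site reaction", 2),
                ("headache", 3),
            ],
        ),
    ]
    return [read_report(r) for r in reports]
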