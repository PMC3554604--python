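# teotimer

Ontology-based temporal representation, reasoning and timeline comparison for
vaccine adverse-event (AE) reports.

## The problem

Post-vaccination AE reports (VAERS-style) mix a structured block — vaccination
date, onset date, coded symptoms — with a free-text narrative that usually
carries the real temporal story: *"18 month-old vaccinated w/MMR on July 6th.
Eighteen days after vaccination she developed a fever of 104 and macular rash
... Dx: vasculitis 2 wks later. Patient hospitalized 08-08."* The narrative
dates events relative to one another, omits years, and leaves key orderings
(was the hospitalization after the vasculitis diagnosis?) implicit. For
time-trend analysis across reports, all of this has to be made explicit and
machine-comparable.

`teotimer` is for pharmacovigilance and clinical-informatics work that needs
report narratives as analyzable timelines: it represents annotated events and
time statements in a Time Event Ontology (TEO) style model, infers the
unstated dates and orderings, normalizes event names to ontology terms, and
compares resolved timelines across reports.

## The model

* **Events and time stamps.** Each event may carry a time instant or interval
  with the original expression preserved verbatim (`hasOrigTime`), a
  normalized partial ISO value (`hasNormalizedTime`: `2006`, `2006-07`,
  `2006-07-06`) and its granularity. Durations are value + unit pairs
  (`hasValue "18"`, `hasUnit "day"`); periodic schedules ("20 minutes
  3 times/day ... for 2 weeks") are first-class.
* **Allen's interval algebra.** Pairwise event relations use the 13 base
  relations (before, meets, overlaps, starts, during, finishes, equals and
  inverses), closed under inversion and composition. The composition table is
  derived from endpoint (point-algebra) semantics; path-consistency
  propagation (PC-1 to fixpoint) tightens every relation set through every
  intermediate event and detects inconsistencies. A relation may carry a
  quantitative offset ("eighteen days after"), serialized in RDF as an OWL
  annotated axiom (`owl:annotatedSource/Property/Target` + `hasTimeOffset`).
* **Date inference.** Events reachable from a date-anchored event through
  offset-bearing chains get concrete dates by calendar arithmetic (weeks are
  exactly 7 days; months/years calendar-aware), at the coarsest granularity
  seen along the chain. Dates then order events the qualitative constraints
  alone could not.
* **Term normalization.** Surface forms ("FLU-LIKE SYMPTOMS",
  "Influenza-like illness") map deterministically to canonical terms and
  identifiers in OAE (adverse-event ontology), MedDRA and VO (vaccine
  ontology) via a packaged lexicon excerpt, so cross-report matching is by
  concept, never by string.
* **Timeline comparison.** Per report: the event sequence anchored at the
  vaccination event with calendar-day offsets. Across reports: shared symptoms
  at different offsets, per-report symptom frequencies, and symptom pairs
  occurring in opposite orders.

## Worked example

The five-event MMR narrative quoted above, end to end:

```python
from teotimer.cases import mmr_case
from teotimer.ontology_annotation import annotate_events
from teotimer.allen_reasoner import infer_dates, derive_relation
from teotimer.timeline_analysis import build_timeline, timelines_to_tsv

graph = annotate_events(mmr_case())     # 5 events, 4 stated offset relations
infer_dates(graph)                      # calendar chains from July 6 anchor
timeline = build_timeline(graph, report_id="MMR")
print(timelines_to_tsv([timeline]))
print(sorted(derive_relation(graph, "event4", "event5")))
```

prints

```
report_id	term	day_offset
MMR	mmr vaccine	0
MMR	fever	18
MMR	macular rash	18
MMR	vasculitis	32
MMR	hospitalization	33

['before']
```

Reading: the vaccination anchors day 0 (2006-07-06). "Eighteen days after
vaccination" places fever and rash at day 18 (2006-07-24); "2 wks later"
places the vasculitis diagnosis at day 32 (2006-08-07); the hospitalization's
year-less "08-08" completes to 2006-08-08 (day 33). The final line is the
inferred answer to the question the narrative never states: the vasculitis
diagnosis came *before* the hospitalization.

The same stages are scriptable from a shell via the `teo-timer` CLI
(`normalize`, `export`, `reason`, `annotate`, `timeline`, `compare`,
`simulate`); `teo-timer simulate` emits synthetic VAERS-like cohorts with
ground-truth timelines for end-to-end testing.

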