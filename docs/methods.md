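# Methods

## Scope and data model

`teotimer` turns annotated adverse-event report narratives into reasoned,
comparable timelines. The in-memory model follows the Time Event Ontology
view: `Event` (a processual entity — vaccination, symptom onset,
hospitalization) optionally carries a `TimeInstant` or `TimeInterval`;
pairwise `TemporalAssertion`s hold Allen relations, optionally with a
`Duration` offset; a `TemporalGraph` is one report's unit of reasoning and
serialization. Natural-language extraction is out of scope: inputs are
pre-annotated spans (the JSON report dialect, see `report_schema.md`) or
graphs built through the API.

Design choices at this layer:

* **Single time assignment.** Re-attaching a time to an event is an error,
  not a replacement — annotations are source-of-truth records.
* **Events as intervals.** An event with a single time stamp is a zero-width
  interval, so date-resolved events compare by point algebra
  ({before, equals, after}); one algebra serves both cases.
* **Stated vs inferred.** Stated assertions are singleton relations (that is
  what report annotations look like); disjunctive relation sets appear only
  on inferred assertions. Every assertion records its provenance.
* **Offset semantics.** For "X after A offset d", d runs from the end of A to
  the start of X; with point events this is date arithmetic, which matches
  the narrative reading "eighteen days after vaccination she developed a
  fever" (onset = anchor + 18 d). "after" is strict (no simultaneity).

## Time-expression normalization

Time, duration and periodic expressions in report narratives form a small
regular language, so the parser is a set of ordered regular-expression
patterns plus a number-word table (zero–twenty, tens, and compounds) rather
than a grammar. Conventions, configurable through `NormalizationContext`:

* dates read month-day-year (VAERS is a US system), so "3-29-90" is
  March 29 1990;
* two-digit years pivot at 30: ≥ 30 → 19xx, < 30 → 20xx (the report era
  spans the 1990s);
* unit synonyms: wk/wks → week, d → day, min → minute, mo/mos → month,
  yr → year, plus full names and plurals;
* the original text is preserved byte-for-byte; the normalized value is a
  partial ISO-8601 string whose precision defines the granularity (year,
  month, day). A year-less date ("08-08") stays partial (`--08-08`) until
  completed from the context anchor — typically the structured vaccination
  date. With the `after_anchor` hint (the pipeline default: adverse events
  follow vaccination), a completed date that would precede the anchor rolls
  its year forward by one.
* weeks are exactly 7 days; month/year arithmetic is calendar-aware
  (`dateutil.relativedelta`), never 30/365-day approximations — inferred
  dates must match human calendar reading.

Out of scope: full TIMEX3 coverage, times of day/time zones, and
document-creation-time expressions ("yesterday") beyond anchor completion.

## Qualitative reasoning

The 13 Allen base relations are characterized by the 2×2 matrix of point
relations between interval endpoints; the 169-cell composition table is
computed by composing those endpoint constraints through the shared
interval's endpoints in the three-valued point algebra. The table is
validated cell-by-cell against an independent brute-force oracle that
enumerates integer assignments of the six endpoints (tests/oracles.py); the
identity (`equals ∘ r = r`) and converse (`inv(r2) ∘ inv(r1) = inv(r1 ∘ r2)`)
laws are asserted separately.

Propagation is path consistency (PC-1 iterated to fixpoint): every edge set
is intersected with the composition of each two-edge path until nothing
changes. It is monotone and idempotent; an emptied edge raises an
inconsistency naming the offending triangle. Path consistency is the
inference level because report graphs are chain-like; for graphs of at most
12 events, `validate_graph` additionally runs a backtracking search over
atomic scenarios, which is a complete decision procedure at that size.
Iteration order is deterministic (sorted event ids) so inferred provenance
traces are reproducible.

Limitation: the composition table assumes proper intervals. Point
(zero-width) events are ordered through date comparison, not through
relations like `meets` whose endpoint semantics degenerate for points.

## Quantitative (calendar) inference

`infer_dates` seeds from every event with a complete normalized date and
walks offset-bearing before/after assertions in both directions, shifting by
calendar arithmetic. The granularity of an inferred date is the coarsest seen
along its chain (week counts as day precision because weeks are exact; month
and year offsets coarsen the result). Two chains that disagree about one
event's date raise a conflict carrying both derivations — this is also how a
narrative-derived date that contradicts the structured onset field surfaces:
as a reported conflict, never an automatic resolution. Offsets compose only
along same-direction chains; anything else falls back to qualitative
reasoning.

`derive_relation` intersects the date-implied point relation with the
path-consistency closure. Dates are compared at the coarser of the two
granularities, and equality at that granularity yields
{before, equals, after} rather than `equals`: day-granular stamps cannot
order same-day events (fever and rash in the worked case).

## Term annotation

Matching is exact-after-normalization (lowercase, punctuation and hyphens
collapsed, synonym-mapped) against a packaged TSV lexicon of ~70 rows — a
deterministic, auditable excerpt, not a live ontology import. Each concept's
canonical text is its preferred label with the OAE process suffix (" AE")
stripped, so "FLU-LIKE SYMPTOMS", "Influenza-like illness" and
"influenza like illness AE" all canonicalize to "influenza like illness".
When a surface form is cross-referenced in both OAE and MedDRA, both term
references are attached rather than adjudicated. Unknown labels pass through
normalized and flagged unmapped, never dropped. The three identifiers
documented for this domain (OAE_0000100, MedDRA 10022004, VO_0010711) are
carried verbatim; all other identifiers in the lexicon are synthetic
placeholders (OAE_09xxxxx / VO_09xxxxx / 109xxxxx) — sufficient for concept
matching, not authoritative codes.

## RDF serialization

Turtle output follows the TEO triple patterns (`hasTime`, `hasOrigTime`,
`hasNormalizedTime`, `hasGranularity`, `hasValue`, `hasUnit`); offset-bearing
or inferred assertions are reified as OWL annotated axioms with
`hasTimeOffset`. Choices made for determinism and fidelity:

* the vocabulary namespace is a documented placeholder
  (`http://example.org/teo#`); the instance base namespace is configurable;
* no blank nodes — time, duration and axiom nodes get skolem IRIs derived
  from their owner (and, for axioms, from source, relations, target, offset
  and provenance), so write → read → write is byte-identical;
* normalized times serialize as `xsd:date` / `xsd:gYearMonth` / `xsd:gYear`
  matching granularity — partial dates never fabricate precision;
* triples are emitted in sorted order, enabling golden-file tests;
* the time-stamp properties hang off the `TimeInstant` node that `hasTime`
  points to (one node per stamp), keeping instants self-contained.

Annotation *order* on an event is not representable in RDF (a graph is a
set), so round-trip identity treats annotation lists as sets.

## Timelines and cohort comparison

The timeline anchor is the earliest VO-annotated (vaccine) event, tie-broken
by narrative order, or an explicit label hint. Day offsets are calendar-day
differences from the anchor; events without a day-precision date are placed
after their latest constraint-implied predecessor and flagged unresolved.
Same-day events keep stable narrative order.

Cross-report comparison matches symptoms by canonical term only. The three
outputs: offsets of symptoms shared by ≥ 2 reports; per-report frequency
counts (zeros included); and term pairs whose strict different-day order
(first occurrences compared) reverses between reports — day-granular data
cannot witness intra-day reversals, so same-day pairs never count. The
comparison is invariant to input ordering.

## Synthetic report generator

The generator emulates the structure of a VAERS-style record: a structured
block plus a narrative annotation list with one vaccination anchor (absolute
date) and k adverse events. Default study conditions: 3 reports per cohort
(20 in the end-to-end recovery runs), 2–6 events per report, consecutive-event
gaps uniform on 1–30 days, anchor dates uniform over 1990–1999 (the VAERS era
the report ids reference), half of the events timed as relative durations
(chaining off the previous event with probability 0.5, else off the anchor —
exercising multi-hop inference), the rest as absolute dates (70% year-less,
exercising anchor completion), and a 90/10 day/month granularity mix —
month-granular events are unresolvable to a day offset by design and their
planted offset is None. Symptoms draw with replacement from an
11-term lexicon pool so cohorts overlap non-trivially.

All randomness flows from one integer seed; report `index` selects an
independent substream (`numpy` `default_rng([seed, index])`), so a cohort is
reproducible regardless of generation order.

What passing recovery tests show — and what they do not: the pipeline
recovers exactly the planted timelines and cross-report differences for
records whose annotations follow the documented dialect with lexicon-covered
labels and parseable time expressions. Real narratives add extraction noise,
vocabulary gaps, and inconsistent or erroneous time statements; the package
surfaces the latter as parse/conflict/inconsistency errors but the generator
does not emulate them, and recovery rates here say nothing about extraction
quality on free text.

## Numerical and degenerate-input conventions

* Duration values are non-negative floats; calendar shifts with month/year
  units require integral values (fractional months are undefined).
* An empty temporal graph is consistent; a graph with no date anchor infers
  no dates and is returned unchanged.
* Ties in timeline order resolve by narrative (insertion) order, everywhere.
* Backtracking consistency search is bounded at 12 events; beyond that,
  consistency claims are path-consistency level only.
* Test problem sizes: 169 composition cells (exhaustive), 200 random 5-node
  networks for closure equivalence, 100 random graphs for round-trips, and a
  20-report cohort for end-to-end recovery — sizes at which the brute-force
  oracles remain exact.
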