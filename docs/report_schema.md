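# JSON report dialect

`read_report` accepts a JSON object per report. Keys beginning with `_` are
comments. Unknown keys are kept and warned about; unknown annotation kinds
are structural errors.

```json
{
  "report_id": "25319",                      // required, non-empty
  "age": {"value": 1.5, "unit": "year"},     // optional
  "sex": "F",                                // optional
  "structured_dates": {                      // values: any parseable date text
    "vaccinated": "3-29-90",                 // known keys: vaccinated, onset,
    "onset": "1990-03-29"                    //   submitted, entered
  },
  "vaccines": ["Engerix-B"],                 // surface names/codes, verbatim
  "symptoms": ["influenza", "rash"],         // MedDRA surface terms, verbatim
  "narrative_annotations": [                 // document order preserved
    {"kind": "event",    "id": "ev1", "text": "1ST ENGERIX-B DOSE"},
    {"kind": "time",     "event": "ev1", "text": "3-29-90"},
    {"kind": "duration", "event": "ev2", "text": "3 days"},
    {"kind": "relation", "source": "ev2", "relation": "after",
     "target": "ev1", "offset": "18 days"}
  ]
}
```

Annotation kinds:

* `event` — declares an event span; `id` names it for later reference
  (generated if absent), `text` is the surface label (lexicon lookups apply).
* `time` — attaches a time expression to an event. Year-less dates complete
  from the structured vaccination/onset anchor; the optional `hint` field
  (`after_anchor`, default, or `before_anchor`) controls year rollover.
* `duration` — attaches a bare duration (the event's own extent) as a
  time interval.
* `relation` — an Allen relation between two declared events; the optional
  `offset` is a duration expression annotating the gap (only for
  before/after/meets/met_by).
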