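{
  "_comment": "VAERS-style hepatitis-B (Engerix-B) case: the structured onset date, the '1ST ENGERIX-B DOSE' <-> '3-29-90' time link, and the MedDRA 'influenza' symptom coding are the documented facts of report 25319; the remaining fields are synthetic filler completing the record shape.",
  "report_id": "25319",
  "sex": "F",
  "structured_dates": {
    "vaccinated": "3-29-90",
    "onset": "3-29-90"
  },
  "vaccines": ["Engerix-B"],
  "symptoms": ["influenza", "rash", "arthralgia", "nausea"],
  "narrative_annotations": [
    {"kind": "event", "id": "ev1", "text": "1ST ENGERIX-B DOSE"},
    {"kind": "time", "event": "ev1", "text": "3-29-90"},
    {"kind": "event", "id": "ev2", "text": "FLU-LIKE SYMPTOMS"},
    {"kind": "relation", "source": "ev2", "relation": "after", "target": "ev1", "offset": "2 days"},
    {"kind": "event", "id": "ev3", "text": "rash"},
    {"kind": "relation", "source": "ev3", "relation": "after", "target": "ev2", "offset": "1 day"},
    {"kind": "event", "id": "ev4", "text": "nausea"},
    {"kind": "time", "event": "ev4", "text": "04-02"}
  ]
}
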