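[
  {"code": "A0", "rank": 0, "label": "Watchful waiting/rest"},
  {"code": "A1", "rank": 1, "label": "Self-care (rest, hydration, diet adjustment)"},
  {"code": "A2", "rank": 2, "label": "Over-the-counter or home treatment"},
  {"code": "A3", "rank": 3, "label": "Consult a pharmacist"},
  {"code": "A4", "rank": 4, "label": "Consult family or friends"},
  {"code": "A5", "rank": 5, "label": "Seek information online"},
  {"code": "A6", "rank": 6, "label": "Call a medical or triage hotline"},
  {"code": "A7", "rank": 7, "label": "Arrange a non-emergency clinic visit"},
  {"code": "A8", "rank": 8, "label": "Go to an emergency department"},
  {"code": "A9", "rank": 9, "label": "Call an ambulance/emergency services"}
]
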