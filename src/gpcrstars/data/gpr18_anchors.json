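{
  "description": "GPR18 segment spans and X.50 anchors covering all literature-labelled residues (N40=1.50, D68=2.50, R119=3.50, C172=45.50, R191=5.42 via 5.50=199, K227=6.30 via 6.50=247, D282=7.49 via 7.50=283). Spans are a working annotation, not an experimental assignment; override with a user file if needed.",
  "segments": [
    {"segment": 1, "start": 15, "end": 55, "anchor": 40},
    {"segment": 2, "start": 60, "end": 85, "anchor": 68},
    {"segment": 23, "start": 86, "end": 88, "anchor": 87},
    {"segment": 3, "start": 94, "end": 126, "anchor": 119},
    {"segment": 4, "start": 140, "end": 162, "anchor": 146},
    {"segment": 45, "start": 168, "end": 176, "anchor": 172},
    {"segment": 5, "start": 180, "end": 210, "anchor": 199},
    {"segment": 6, "start": 220, "end": 258, "anchor": 247},
    {"segment": 7, "start": 260, "end": 290, "anchor": 283}
  ]
}
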