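# Barrier regions flanking the substrate binding cleft, by parent enzyme.
# Residue ranges are inclusive author numbers.  Overlapping regions (e.g.
# bsest Δ4/Δ5, chrybhetase Δ1/Δ2) are intentional: each is designed and
# scored as its own truncation candidate.
version: 1
bsest:
  - {label: "D1", start: 60, end: 77}
  - {label: "D2", start: 105, end: 112}
  - {label: "D3", start: 267, end: 275}
  - {label: "D4", start: 401, end: 418}
  - {label: "D5", start: 410, end: 418}
chrybhetase:
  - {label: "D1", start: 63, end: 78}
  - {label: "D2", start: 66, end: 76}
  - {label: "D3", start: 267, end: 274}
  - {label: "D4", start: 319, end: 327}
  - {label: "D5", start: 368, end: 376}
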