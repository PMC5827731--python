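# Default tract annotation for human nucleophosmin (NPM1).
#
# Coordinates are 1-based inclusive. The B2-tract window (189-240) is fixed by
# the published NCPR values for the wild-type and phosphomimetic B2-tract; the
# remaining windows are derived from the construct boundaries used for the
# truncation mutants (N188 = residues 1-188, N240 = residues 1-240, CTD from
# residue 241) and from the charge blocks visible in the sequence itself:
# A2 is the first contiguous D/E-rich block of the IDR, A3 the long poly-D/E
# block preceding the B2-tract, and B1 the K/R-containing linker between them.
tracts:
  - {name: OD,  start: 1,   end: 119, polarity: folded}
  - {name: A2,  start: 120, end: 133, polarity: acidic}
  - {name: B1,  start: 134, end: 160, polarity: basic}
  - {name: A3,  start: 161, end: 188, polarity: acidic}
  - {name: B2,  start: 189, end: 240, polarity: basic}
  - {name: CTD, start: 241, end: 294, polarity: folded}
# A1 lies inside the folded oligomerization domain and is not resolved to
# residue numbers in the source figure; it is intentionally not annotated here.
phosphosites: [199, 219, 234, 237]
constructs:
  WT:   {start: 1, end: 294}
  N240: {start: 1, end: 240}
  N188: {start: 1, end: 188}
  IDR:  {start: 120, end: 240}
  CTD:  {start: 241, end: 294}
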