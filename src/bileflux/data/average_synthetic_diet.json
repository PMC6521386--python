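{
 "name": "average_synthetic_diet",
 "units": "mmol/person/day",
 "entries": {
  "EX_glc_D": [-1000.0, 1000.0],
  "EX_h2o": [-1000.0, 1000.0],
  "EX_h": [-1000.0, 1000.0],
  "EX_chsterol": [-10.0, 1000.0],
  "EX_tchola": [-1000.0, 1000.0],
  "EX_gchola": [-1000.0, 1000.0],
  "EX_tdchola": [-1000.0, 1000.0],
  "EX_dgchol": [-1000.0, 1000.0]
 }
}
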