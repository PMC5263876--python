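# Opposing lateral-medial CRABP1/CYP26B1 gradients, steep RA tilt.
description: strongly asymmetric vane (steep RA gradient)
gradients:
  BP:  {a: 0.006, v: 8.0}
  CYP: {a: 5.0,  v: -8.0}
run:
  mrf_dt: 0.01
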