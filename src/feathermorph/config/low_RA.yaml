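# Uniform low RA signalling: scarce CRABP1, abundant CYP26B1.
description: BGZ expansion and vane shrinkage under low RA
gradients:
  BP:  {a: 0.005}
  CYP: {a: 0.2}
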