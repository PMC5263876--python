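# Raised GREM1 production: BGZ expands at the expense of the vanes.
description: GREM1 mis-expression phenotype
mrf:
  GREM: {V: 1.6}
  RA_o: {V: 0.0}
gradients:
  BP:  {a: 0.0}
  CYP: {a: 0.0}
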