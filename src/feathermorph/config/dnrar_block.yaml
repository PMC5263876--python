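# Dominant-negative receptor: RA present but signalling blocked.
description: DNRAR-beta phenotype, low effective RA signal
mrf:
  R: {B: 0.005}
gradients:
  BP:  {a: 1.1}
  CYP: {a: 0.02}
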