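# Anterior-posterior module only: the RA module is silenced.
description: symmetric plume without the lateral-medial RA module
mrf:
  RA_o: {V: 0.0}
gradients:
  BP:  {a: 0.0}
  CYP: {a: 0.0}
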