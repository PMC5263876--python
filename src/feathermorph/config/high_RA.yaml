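# Uniform high RA signalling: abundant CRABP1, scarce CYP26B1.
description: symmetric vane enlargement under high RA
gradients:
  BP:  {a: 1.1}
  CYP: {a: 0.02}
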