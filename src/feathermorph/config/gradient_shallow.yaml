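description: mild vane asymmetry (shallow RA gradient)
gradients:
  BP:  {a: 0.06, v: 8.0}
  CYP: {a: 0.3,  v: -8.0}
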