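description: intermediate vane asymmetry (intermediate RA gradient)
gradients:
  BP:  {a: 0.03, v: 8.0}
  CYP: {a: 0.5,  v: -8.0}
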