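# Package defaults for the regulatory (MRF) and branching (PB) models.
# One section per species, one per Hill link.  Amplitude values inside the
# named presets are the documented CRABP1/CYP26B1 levels; everything else
# here is a package default calibrated to produce a patterned vane zone
# flanking a GDF10-high rachis and a GREM1-high BGZ in the symmetric case.

mrf:
  RA_o:   {V: 1.0, B: 0.0, D: 1.0e-4, r: 0.1}
  RA_i:   {B: 0.0, r_free: 0.5, r_bound: 0.2}
  R:      {B: 1.0, r_free: 1.0, r_bound: 1.0}
  BP:     {V: 1.0, B: 0.0, r_free: 1.0, r_bound: 0.2}
  WNT:    {V: 1.0, B: 0.01, D: 2.0e-4, r: 1.0}
  GDF:    {V: 1.0, B: 0.0, D: 1.0e-4, r: 1.0}
  GREM:   {V: 1.0, B: 0.0, D: 1.0e-4, r: 1.0}
  binding:
    k_on: 0.005
    k_off: 0.1
    m_on: 5.0
    m_off: 0.05
    j_alpha: 0.1
    j_beta: 2.0
    k_p: 1.0
    beta_loss: 0.2
  cyp:
    r_cyp: 0.2
    target: bound          # CYP26B1 degrades the CRABP1-bound RA pool
  grem_response:
    floor: 0.55            # residual GREM1 production under saturating RA

hill:
  wnt_gdf_act:   {index: 1, k: 0.3,  n: 2.0}
  wnt_grem_inh:  {index: 2, k: 0.05, n: 2.0}
  rar_grem_inh:  {index: 3, k: 0.01, n: 2.0}
  rar_gdf_inh:   {index: 4, k: 1.0,  n: 2.0}
  gdf_grem_inh:  {index: 5, k: 0.3,  n: 2.0}

gradients:
  CYP: {a: 0.0, v: 0.0, axis: lateral_medial, form: exponential}
  BP:  {a: 0.0, v: 0.0, axis: lateral_medial, form: exponential}
  WNT: {a: 1.0, v: -12.0, axis: anterior_posterior, form: exponential}
  RAo: {a: 1.0, v: 0.0, axis: anterior_posterior, form: constant}

pb:
  D_A: 2.0e-5
  D_B: 1.0e-3
  r_A: 1.0
  r_B: 1.0
  r_C: 0.04
  s: 6.0
  s_A: 0.4
  s_B: 1.0
  s_C: 1.0
  s_G: 0.5
  b_A: 0.02
  b_B: 0.01
  b_C: 0.1
  c_B: 1.0
  n_G: 4.0
  g_grem: 0.9
  g_gdf: 30.0
  s_c_placement: inhibition

# near-threshold Turing parameter sets used for wavelength diagnostics
pb_variants:
  turing_a: {s: 4.0, s_A: 0.2, s_B: 2.0, r_B: 2.0, c_B: 4.0, b_C: 0.0,
             r_C: 1.0, D_A: 7.3e-6, D_B: 3.556e-4, g_grem: 0.0, g_gdf: 0.0}
  turing_b: {s: 4.0, s_A: 0.2, s_B: 2.0, r_B: 2.0, c_B: 4.0, b_C: 0.0,
             r_C: 1.0, D_A: 8.9e-6, D_B: 3.556e-4, g_grem: 0.0, g_gdf: 0.0}
  turing_c: {s: 4.0, s_A: 0.2, s_B: 2.0, r_B: 2.0, c_B: 4.0, b_C: 0.0,
             r_C: 1.0, D_A: 1.0e-5, D_B: 3.556e-4, g_grem: 0.0, g_gdf: 0.0}

zones:
  # absolute thresholds, 50% of the symmetric preset's steady maxima
  grem_threshold: 0.4675
  gdf_threshold: 0.4410

geometry:
  elongation_V: 0.004      # feather outgrowth rate, circumference units/time
  beta_expand: 20.0        # expansion angle after maturation, degrees
  branching_threshold: 1.0 # activator level that counts as a barb ridge

run:
  n_points: 200
  mrf_dt: 0.02
  mrf_tol: 1.0e-8
  mrf_max_steps: 200000
  mrf_noise_amplitude: 1.0e-3
  pb_n_steps: 60000
  pb_record_every: 200
  pb_noise_amplitude: 1.0e-2
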