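# Healthy-baseline (M1) closed-loop model configuration.
# Units: R Pa·s·mm^-3, L Pa·s^2·mm^-3, C mm^3·Pa^-1, E Pa·mm^-3, times s.
valves:
  mitral:
    R: 3.9e-4
    L: 1.0e-5
  aortic:
    R: 1.0e-5
    L: 1.0e-5
  tricuspid:
    R: 1.0e-5
    L: 1.0e-5
  pulmonary:
    R: 1.0e-5
    L: 1.0e-5
elastance:
  E_maxL: 0.394
  E_minL: 9.0e-5
  E_maxR: 0.152
  E_minR: 9.0e-5
  T: 0.684
  t_max: 0.377
  t_toRelax: 0.104
  V0_mL: 10.0
compartments:
  lung:
    R_p: 0.00027
    C: 1.000
    R_d: 0.00265
  digestive:
    R_p: 0.05607
    C: 0.630
    R_d: 0.58110
  other_organs:
    R_p: 0.01869
    C: 6.302
    R_d: 0.19370
  central_venous:
    R_p: 0.00014
    C: 12.000
    R_d: 0.00142
  # Reconstructed pulmonary-venous / left-atrial reservoir (mm^3/Pa); see
  # docs/methods.md.
  pulmonary_venous_compliance: 12.0
hepatic:
  portal_vein:
    R_p: 0.00318
    C: 1.200
    R_d: 0.03184
  hepatic_artery:
    R_p: 0.17755
    C: 0.630
    R_d: 1.84015
  sinusoid:
    C: 1.000
    R_d: 0.00884
  hepatic_veins:
    left: 1.0e-5
    middle: 1.0e-5
    right: 1.0e-5
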