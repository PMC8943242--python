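# Specific absorption of the five breast chromophores at the 8 probing
# wavelengths.  Values are an approximate compilation in the style of the
# standard literature tables (Hb/HbO2 molar extinctions; water, lipid and
# collagen as pure-component bulk absorption); they are bundled so the whole
# pipeline runs self-contained, and can be overridden by the user.
#
# Units convention: mu_a [mm^-1] = sum_i epsilon_i(lambda) * C_i with
#   Hb, HbO2   : epsilon in mm^-1 / uM,  C in uM
#   water, lipid, collagen : epsilon in mm^-1 per unit volume fraction,
#                            C a dimensionless fraction in [0, 1]
wavelengths_nm: [635, 670, 685, 785, 905, 930, 975, 1060]
epsilon:
  Hb:       [1.06e-3, 6.9e-4, 5.8e-4, 3.1e-4, 1.8e-4, 1.7e-4, 1.5e-4, 1.1e-4]
  HbO2:     [9.2e-5, 7.4e-5, 6.7e-5, 1.70e-4, 2.76e-4, 2.81e-4, 2.65e-4, 2.07e-4]
  water:    [3.1e-4, 4.2e-4, 4.9e-4, 2.62e-3, 7.5e-3, 1.13e-2, 4.52e-2, 1.24e-2]
  lipid:    [9.0e-5, 8.0e-5, 8.0e-5, 1.1e-4, 1.2e-3, 1.10e-2, 5.3e-3, 4.3e-3]
  collagen: [1.2e-3, 1.4e-3, 1.5e-3, 2.2e-3, 4.4e-3, 5.5e-3, 7.5e-3, 1.60e-2]
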