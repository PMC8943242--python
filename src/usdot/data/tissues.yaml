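# Per-tissue chromophore concentration and scattering distributions.
# These are modeling choices (means and standard deviations of independent
# normal draws, truncated at zero), selected so that malignant lesions carry
# higher total hemoglobin, water and collagen and lower lipid than benign
# ones, and so that the bulk tissues sit in between: the qualitative contrast
# that drives benign/malignant discrimination in multi-wavelength breast
# optics.  Concentrations: tHb in uM plus an oxygen saturation so2; water,
# lipid, collagen are volume fractions.  Scattering follows
# mu_s'(lambda) = a * (lambda/lambda0)^(-b), lambda0 = 600 nm, a in mm^-1.
lambda0_nm: 600.0
refractive_index: 1.4

tissues:
  skin:      {tHb: [25.0, 3.0], so2: [0.70, 0.03], water: [0.40, 0.04], lipid: [0.10, 0.02], collagen: [0.35, 0.04], a: [2.0, 0.15], b: [1.3, 0.1]}
  adipose:   {tHb: [9.0, 1.5],  so2: [0.75, 0.03], water: [0.16, 0.03], lipid: [0.75, 0.05], collagen: [0.05, 0.01], a: [1.05, 0.10], b: [0.55, 0.1]}
  glandular: {tHb: [17.0, 2.0], so2: [0.75, 0.03], water: [0.50, 0.05], lipid: [0.30, 0.04], collagen: [0.15, 0.02], a: [1.35, 0.10], b: [1.1, 0.1]}
  muscle:    {tHb: [40.0, 4.0], so2: [0.70, 0.03], water: [0.70, 0.04], lipid: [0.05, 0.02], collagen: [0.10, 0.02], a: [0.9, 0.10], b: [0.8, 0.1]}
  duct:      {tHb: [18.0, 2.0], so2: [0.75, 0.03], water: [0.55, 0.05], lipid: [0.20, 0.04], collagen: [0.20, 0.03], a: [1.35, 0.10], b: [1.1, 0.1]}
  TDLU:      {tHb: [18.0, 2.0], so2: [0.75, 0.03], water: [0.55, 0.05], lipid: [0.20, 0.04], collagen: [0.20, 0.03], a: [1.35, 0.10], b: [1.1, 0.1]}
  ligament:  {tHb: [12.0, 2.0], so2: [0.72, 0.03], water: [0.35, 0.04], lipid: [0.30, 0.05], collagen: [0.30, 0.04], a: [1.5, 0.10], b: [1.2, 0.1]}
  artery:    {tHb: [1800.0, 100.0], so2: [0.97, 0.01], water: [0.80, 0.02], lipid: [0.01, 0.005], collagen: [0.02, 0.005], a: [1.2, 0.1], b: [1.0, 0.1]}
  vein:      {tHb: [1800.0, 100.0], so2: [0.65, 0.03], water: [0.80, 0.02], lipid: [0.01, 0.005], collagen: [0.02, 0.005], a: [1.2, 0.1], b: [1.0, 0.1]}
  nipple:    {tHb: [25.0, 3.0], so2: [0.70, 0.03], water: [0.40, 0.04], lipid: [0.10, 0.02], collagen: [0.35, 0.04], a: [2.0, 0.15], b: [1.3, 0.1]}

# Lesion classes.  Scattering amplitude distributions for benign/malignant
# lesions and the cyst sub-class (25% of benign lesions) are fixed study
# conditions; chromophore contrasts are modeling choices as above.
lesions:
  benign:    {tHb: [16.0, 2.5], so2: [0.76, 0.04], water: [0.48, 0.06], lipid: [0.32, 0.05], collagen: [0.14, 0.03], a: [1.5, 0.25], b: [1.0, 0.15]}
  malignant: {tHb: [30.0, 4.0], so2: [0.67, 0.05], water: [0.70, 0.06], lipid: [0.12, 0.04], collagen: [0.30, 0.04], a: [1.4, 0.25], b: [1.0, 0.15]}
  cyst:      {tHb: [16.0, 2.5], so2: [0.76, 0.04], water: [0.48, 0.06], lipid: [0.32, 0.05], collagen: [0.14, 0.03], a: [0.3, 0.01], b: [1.0, 0.15]}
cyst_fraction_of_benign: 0.25
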