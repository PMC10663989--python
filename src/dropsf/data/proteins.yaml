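# Tabulated constants for the two Ddx4N constructs.
# Molar volumes from amino-acid partial molar volume tables; extinction
# coefficients at 280 nm; masses of the expressed constructs (GAMGS leader,
# Cys->Ser swaps).
ddx4n_1-229:
  fasta_id: ddx4n_1-229_synthetic
  molar_mass_g_mol: 25109.54
  molar_volume_cm3_mol: 19020.3
  extinction_coeff_M_cm: 23950.0
ddx4n_1-231:
  fasta_id: ddx4n_1-231_synthetic
  molar_mass_g_mol: 25309.74
  molar_volume_cm3_mol: 19169.7
  extinction_coeff_M_cm: 23950.0
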