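# Whole-blood absorption coefficients (mm^-1) at hematocrit 45%
# (total hemoglobin ~150 g/L), computed from the Prahl/van Assendelft
# compilation of molar extinction spectra of oxy- and deoxyhemoglobin:
#   mu_a = ln(10) * epsilon(lambda) * C_Hb / M_Hb
# with C_Hb = 150 g/L and M_Hb = 64500 g/mol.  Override via
# BloodOpticalProperties.from_csv for other sources.
wavelength_nm,mu_a_hbo_mm,mu_a_hb_mm
660,0.171,1.728
880,0.650,0.395
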