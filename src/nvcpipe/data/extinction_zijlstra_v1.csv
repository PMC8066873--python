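# Molar extinction coefficients of human adult hemoglobin, version 1.
# Compiled from the Zijlstra/van Assendelft whole-blood spectrophotometry
# tables as commonly tabulated for continuous-wave NIRS processing.
# Units: 1/(mM*mm).  Columns: wavelength_nm, eps_hbo, eps_hbr
wavelength_nm,eps_hbo,eps_hbr
690,0.02760,0.20520
830,0.09740,0.06930
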