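# Calculated vs experimentally observed volumetric thermal expansion
# coefficients, units 10^-6 K^-1.  Calculated values are linear expansions
# 0-350 K (0-250 K for ETDIAM); experimental values are CSD regressions over
# the stated ranges.
structure,calc_alpha,exp_alpha,exp_err,t_lo,t_hi
MNPHOL_mc,211.9,214.6,14.9,95,350
ETDIAM_Ia,270.5,193.0,38.7,130,274
FURHUV_beta,187.3,154.6,24.6,100,218
GLURAC_beta,164.6,206.6,21.5,120,373
HXACAN_I,154.4,156.9,15.3,20,330
ADIPAC_I,173.8,198.4,11.3,100,293
DPYRAM_mc,178.9,164.8,,150,293
PYRZIN_beta,155.3,181.1,12.3,90,293
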