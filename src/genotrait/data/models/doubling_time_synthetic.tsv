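# name: doubling_time_synthetic
# units: hours
# transform: log
# bias_statistic: Karlin-Mrazek codon usage bias B (highly expressed vs background)
# note: SYNTHETIC placeholder coefficients for pipeline exercise only; not
# note: fitted to any growth-rate dataset. Replace with a trained model file.
intercept	2.5
codon_bias	-3.0
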