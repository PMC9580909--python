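# name: ogt_synthetic
# units: degC
# transform: identity
# note: SYNTHETIC placeholder coefficients for pipeline exercise only; not
# note: fitted to any growth-temperature dataset. Replace with a trained model file.
intercept	-20.0
ivywrel	120.0
genome_gc	10.0
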