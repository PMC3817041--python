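Overweight
obesity
obese
fatty
adiposity
diabetes
hypertension
high cholesterol
stroke
heart disease
arthritis
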