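stroke	pepper	2098	positive
adiposity	milk	1286	neutral
obese	candy	946	negative
diabetes	oat	880	positive
hypertension	rice	868	positive
obesity	yogurt	846	positive
arthritis	spinach	803	positive
obese	milk	643	neutral
arthritis	butter	633	positive
hypertension	pork	614	negative
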