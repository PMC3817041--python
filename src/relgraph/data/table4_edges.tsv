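palpitations	garlic	1910	positive
edema	salt	1748	negative
angina	chips	1689	negative
angina	sauces	1645	negative
atrial fibrillation	cheese	1562	negative
heart attack	garlic	1531	positive
atrial fibrillation	pasta	1457	positive
atrial fibrillation	sugar	1424	negative
myocarditis	grapefruit	1390	negative
palpitations	salt	1337	negative
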