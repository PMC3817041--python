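palpitations
edema
angina
atrial fibrillation
heart attack
myocarditis
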