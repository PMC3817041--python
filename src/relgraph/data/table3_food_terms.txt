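pepper
milk
candy
oat
rice
yogurt
spinach
butter
pork
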