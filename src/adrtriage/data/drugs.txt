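# Default drug vocabulary for the rule-based backend and the corpus generator.
pembrolizumab
rivaroxaban
cisplatin
platinol
emtricitabine
aflibercept
sildenafil
atezolizumab
xevinapant
imatinib
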