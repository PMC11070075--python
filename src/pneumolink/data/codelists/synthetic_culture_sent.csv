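code,term
CULT001,Sputum sample sent for culture (synthetic)
CULT002,Blood culture taken (synthetic)
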