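code,term
AECOPD01,Acute exacerbation of COPD (synthetic)
AECOPD02,Infective exacerbation of COPD (synthetic)
LRTI001,Lower respiratory tract infection (synthetic)
LRTI002,Acute bronchitis (synthetic)
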