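code,term
HOSP001,Admitted to hospital (synthetic generic admission)
HOSP002,Emergency hospital admission (synthetic generic admission)
HOSP003,Admitted to respiratory ward (synthetic respiratory admission)
HOSP004,Hospital admission for chest infection (synthetic respiratory admission)
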