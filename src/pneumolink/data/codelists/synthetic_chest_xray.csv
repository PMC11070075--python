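code,term
CXR001,Referral for chest X-ray (synthetic)
CXR002,Chest X-ray requested (synthetic)
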