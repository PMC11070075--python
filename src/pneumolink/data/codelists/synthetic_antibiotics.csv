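code,term
ABX001,Amoxicillin 500mg capsules (synthetic product)
ABX002,Doxycycline 100mg capsules (synthetic product)
ABX003,Clarithromycin 250mg tablets (synthetic product)
ABX004,Co-amoxiclav 625mg tablets (synthetic product)
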