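code,term
PNEU001,Pneumonia (synthetic)
PNEU002,Lobar pneumonia (synthetic)
PNEU003,Bronchopneumonia (synthetic)
PNEU004,Community acquired pneumonia (synthetic)
PNEU005,Bacterial pneumonia (synthetic)
PNEU006,Viral pneumonia (synthetic)
PNEU007,Aspiration pneumonia (synthetic)
PNEU008,Pneumonia due to Streptococcus pneumoniae (synthetic)
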