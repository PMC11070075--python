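code,term,category
SYMP101,New onset cough (synthetic),new_cough
SYMP102,Productive cough of recent onset (synthetic),new_cough
SYMP201,Purulent sputum (synthetic),sputum
SYMP202,Sputum production (synthetic),sputum
SYMP301,Breathlessness (synthetic),breathlessness
SYMP302,Dyspnoea at rest (synthetic),breathlessness
SYMP401,Fever (synthetic),fever
SYMP402,Pyrexia (synthetic),fever
SYMP501,Lethargy (synthetic),lethargy
SYMP502,Malaise and fatigue (synthetic),lethargy
SYMP601,Tachycardia (synthetic),tachycardia
SYMP602,Rapid heart rate (synthetic),tachycardia
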