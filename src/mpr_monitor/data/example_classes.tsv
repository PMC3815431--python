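# Example drug-class map (key<TAB>drug_class). Keys match either the
# medication code or the display name, case-insensitively. Medications
# absent from this file are simply unmapped: no 1-year prediction is made.
simvastatin	antihyperlipidemics
atorvastatin	antihyperlipidemics
pravastatin	antihyperlipidemics
ramipril	antihypertensives
lisinopril	antihypertensives
furosemide	antihypertensives
amlodipine	antihypertensives
metformin	oral_hypoglycemics
glipizide	oral_hypoglycemics
glyburide	oral_hypoglycemics
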