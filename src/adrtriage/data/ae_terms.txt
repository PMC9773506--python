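# Baseline adverse-event vocabulary (specific AE mentions, mild and severe).
rash
nausea
vomiting
headache
fatigue
diarrhea
diarrhoea
dizziness
pruritus
alopecia
anemia
constipation
insomnia
myositis
pneumonia
pneumonitis
ventricular fibrillation
intracranial bleeding
teratogenic effects
hepatotoxicity
neutropenia
sepsis
myocardial infarction
stroke
anaphylaxis
agranulocytosis
rhabdomyolysis
stevens-johnson syndrome
renal failure
respiratory failure
pulmonary embolism
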