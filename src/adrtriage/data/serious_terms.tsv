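role	canonical	synonym	outcome_category
serious_term	pneumonia	community-acquired pneumonia	hospitalisation
serious_term	pneumonia	aspiration pneumonia	hospitalisation
serious_term	ventricular fibrillation		life-threatening
serious_term	intracranial bleeding	intracranial haemorrhage	life-threatening
serious_term	intracranial bleeding	intracranial hemorrhage	life-threatening
serious_term	teratogenic effects		congenital anomaly
serious_term	stevens-johnson syndrome		life-threatening
serious_term	agranulocytosis		life-threatening
serious_term	rhabdomyolysis		hospitalisation
serious_term	pulmonary embolism		life-threatening
serious_term	respiratory failure		life-threatening
serious_term	myocardial infarction		life-threatening
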