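pt	soc
Vomiting	Gastrointestinal disorders
Nausea	Gastrointestinal disorders
Jaundice	Gastrointestinal disorders
Palpitations	Cardiac disorders
Acute pulmonary oedema	Respiratory, thoracic and mediastinal disorders
Drug-induced liver injury	Hepatobiliary disorders
Dermatitis	Skin and subcutaneous tissue disorders
Gastric haemorrhage	Gastrointestinal disorders
Pulmonary embolism	Vascular disorders
Small intestinal haemorrhage	Gastrointestinal disorders
Tinnitus	Ear and labyrinth disorders
Dizziness	Nervous system disorders
Hepatitis	Hepatobiliary disorders
Tremor	Nervous system disorders
Diarrhoea	Gastrointestinal disorders
Constipation	Gastrointestinal disorders
Insomnia	Psychiatric disorders
Oedema	General disorders and administration site conditions
Haematuria	Renal and urinary disorders
Urinary retention	Renal and urinary disorders
Cholecystitis	Hepatobiliary disorders
Pruritus	Skin and subcutaneous tissue disorders
Rash	Skin and subcutaneous tissue disorders
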