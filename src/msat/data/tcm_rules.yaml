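# Rule-based mapping from MedDRA terms to TCM functional systems.
#
# The vocabulary holds 16 functional systems: the Zang organs (with the
# Pericardium counted among them), the six Fu organs, and the Body Surface,
# Chong-Ren Meridians, Meridians and Collaterals, and Qi-Blood-Fluid systems.
# Exact-PT rules take precedence over SOC defaults; first match wins.
# This file is data: edit or extend it to cover additional terms.

systems:
  - Liver
  - Heart
  - Spleen
  - Lung
  - Kidney
  - Pericardium
  - Gallbladder
  - Stomach
  - Small Intestine
  - Large Intestine
  - Bladder
  - San Jiao
  - Body Surface
  - Chong-Ren Meridians
  - Meridians and Collaterals
  - Qi-Blood-Fluid

pt_rules:
  Vomiting: [Stomach]
  Nausea: [Spleen, Stomach]
  Jaundice: [Liver]
  Palpitations: [Heart]
  Acute pulmonary oedema: [Lung, Qi-Blood-Fluid]
  Drug-induced liver injury: [Liver, Qi-Blood-Fluid]
  Dermatitis: [Body Surface]
  Gastric haemorrhage: [Stomach, Qi-Blood-Fluid]
  Pulmonary embolism: [Lung, Qi-Blood-Fluid]
  Small intestinal haemorrhage: [Small Intestine, Qi-Blood-Fluid]
  Tinnitus: [Kidney]
  Dizziness: [Liver]
  Hepatitis: [Liver, Qi-Blood-Fluid]
  Tremor: [Body Surface]
  Diarrhoea: [Spleen, Large Intestine]
  Constipation: [Large Intestine]
  Palpitation: [Heart]
  Insomnia: [Heart]
  Oedema: [Spleen, Kidney, Qi-Blood-Fluid]
  Haematuria: [Bladder, Qi-Blood-Fluid]
  Urinary retention: [Bladder]
  Cholecystitis: [Gallbladder]
  Pruritus: [Body Surface]
  Rash: [Body Surface]

soc_rules:
  Gastrointestinal disorders: [Spleen, Stomach]
  Hepatobiliary disorders: [Liver, Gallbladder]
  Cardiac disorders: [Heart]
  Respiratory, thoracic and mediastinal disorders: [Lung]
  Renal and urinary disorders: [Kidney, Bladder]
  Ear and labyrinth disorders: [Kidney]
  Skin and subcutaneous tissue disorders: [Body Surface]
  Nervous system disorders: [Liver]
  Psychiatric disorders: [Heart]
  Vascular disorders: [Qi-Blood-Fluid]
  Blood and lymphatic system disorders: [Qi-Blood-Fluid]
  Musculoskeletal and connective tissue disorders: [Meridians and Collaterals]
  Reproductive system and breast disorders: [Chong-Ren Meridians]
  Eye disorders: [Liver]
  Metabolism and nutrition disorders: [Spleen]
  Immune system disorders: [Qi-Blood-Fluid]
  General disorders and administration site conditions: [Qi-Blood-Fluid]
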