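group,method,cases
malignant,ultrasonography_guided_biopsy,10
malignant,ct_guided_biopsy,3
malignant,transbronchial_biopsy,41
malignant,transbronchial_brush,33
malignant,transbronchial_wash,33
malignant,thoracotomy,14
benign,ct_guided_biopsy,2
benign,transbronchial_wash,4
benign,thoracotomy,4
benign,sputum_culture_and_followup,13
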