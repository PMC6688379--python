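NPC:
- Midbrain
AT:
- Vermis/fastigial nucleus
- Flocculus/paraflocculus
AOA1/2:
- Vermis/fastigial nucleus
- Frontoparietal cortex
GD3:
- Pons
TS:
- Midbrain
Wernicke encephalopathy:
- Pons
- Medulla oblongata
Huntington chorea:
- Basal ganglia
- Frontoparietal cortex
MS:
- Pons
Parkinsonian syndromes:
- Basal ganglia
PSP:
- Midbrain
- Basal ganglia
Tumor:
- Midbrain
Infarction/hemorrhage:
- Pons
- Medulla oblongata
Inflammatory encephalitis:
- Frontoparietal cortex
Cerebellar syndromes:
- Flocculus/paraflocculus
- Vermis/fastigial nucleus
- Nodulus/uvula
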