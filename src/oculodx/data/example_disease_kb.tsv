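# entity_kind: DISEASE
symptom	NPC	AT	AOA1/2	GD3	TS	Wernicke encephalopathy	Huntington chorea	MS	Parkinsonian syndromes	PSP	Tumor	Infarction/hemorrhage	Inflammatory encephalitis	Cerebellar syndromes
ataxia	Y	Y	Y	N	N	Y	N	N	N	N	N	N	N	HR
paresis	OTTD	N	N	OTTD	HR	N	N	Y	N	N	Y	HR	N	N
resting tremor	N	N	N	N	N	N	N	N	HR	N	N	N	N	N
intention tremor	N	N	Y	N	N	N	N	Y	N	N	N	N	N	Y
dystonia	N	N	N	N	N	N	Y	N	N	N	N	N	N	N
chorea	N	Y	N	N	N	N	HR	N	N	N	N	N	N	N
cognitive decline	Y	N	N	Y	Y	N	Y	N	N	Y	N	N	N	N
psychiatric symptoms	Y	N	N	N	Y	N	Y	N	N	N	N	N	Y	N
dysarthria	Y	Y	Y	N	N	N	N	N	N	Y	N	Y	N	Y
dysphagia	Y	N	N	N	Y	N	N	N	N	Y	N	Y	N	N
peripheral neuropathy	N	Y	Y	N	N	N	N	N	N	N	N	N	N	N
seizures	N	N	N	Y	Y	N	N	N	N	N	Y	N	Y	N
telangiectasia	N	HR	NEV	N	N	N	N	N	N	N	N	N	N	N
splenomegaly	Y	N	N	Y	N	N	N	N	N	N	N	N	N	N
hepatomegaly	Y	N	N	Y	N	N	N	N	N	N	N	N	N	N
rigidity	N	N	N	N	N	N	N	N	HR	Y	N	N	N	N
bradykinesia	N	N	N	N	N	N	N	N	HR	Y	N	N	N	N
postural instability with falls	N	N	N	N	N	N	N	N	N	HR	N	N	N	N
confusion	N	N	N	N	N	HR	N	N	N	N	Y	N	Y	N
myoclonus	N	N	N	Y	Y	N	N	N	N	N	N	N	Y	N
vertical saccade palsy	HR	N	N	N	Y	N	N	N	N	N	N	N	N	N
horizontal saccade palsy	N	N	N	HR	N	N	N	N	N	N	N	Y	N	N
vertical supranuclear gaze palsy	HR	N	N	N	N	N	N	N	N	HR	N	N	N	N
horizontal supranuclear gaze palsy	N	N	N	HR	N	Y	N	N	N	N	N	N	N	N
internuclear ophthalmoplegia aged < 60 years	N	N	N	N	N	N	N	HR	N	N	N	N	N	N
internuclear ophthalmoplegia aged >= 60 years	N	N	N	N	N	N	N	N	N	N	N	HR	N	N
oculomotor apraxia	N	HR	HR	N	N	N	N	N	N	N	N	N	N	N
slow vertical saccades	Y	N	N	N	Y	N	N	N	N	HR	N	N	N	N
slow horizontal saccades	N	N	N	Y	N	N	Y	N	N	N	N	N	N	N
hypermetric saccades	N	N	N	N	N	N	N	N	N	N	N	N	N	HR
hypometric saccades	N	Y	Y	N	N	N	Y	N	Y	N	N	N	N	N
increased saccade latency	N	Y	HR	N	N	N	Y	N	N	N	N	N	N	N
gaze-evoked nystagmus	N	N	N	N	N	HR	N	Y	N	N	Y	N	N	HR
downbeat nystagmus	N	N	N	N	N	N	N	N	N	N	N	N	N	Y
upbeat nystagmus	N	N	N	N	N	Y	N	N	N	N	N	N	N	N
rebound nystagmus	N	N	N	N	N	N	N	N	N	N	N	N	N	Y
spontaneous nystagmus	N	N	N	N	N	N	N	Y	N	N	N	Y	Y	N
head-shaking nystagmus	N	N	N	N	N	N	N	N	N	N	N	N	N	Y
periodic alternating nystagmus	N	N	N	N	N	N	N	N	N	N	N	N	N	Y
positioning nystagmus	N	N	N	N	N	N	N	N	N	N	N	N	N	Y
convergence-retraction nystagmus	N	N	N	N	N	N	N	N	N	N	HR	N	N	N
see-saw nystagmus	N	N	N	N	N	N	N	N	N	N	N	Y	N	N
square wave jerks	N	N	N	N	N	N	N	N	Y	Y	N	N	N	N
opsoclonus	N	N	N	N	N	N	N	N	N	N	N	N	HR	N
ocular flutter	N	N	N	N	N	N	N	N	N	N	N	N	HR	N
macro square wave jerks	N	N	N	N	N	N	N	N	N	N	N	N	N	Y
saccadic smooth pursuit	N	N	Y	N	N	N	N	Y	Y	N	N	N	N	Y
impaired vertical smooth pursuit	N	N	N	N	N	N	N	N	N	Y	N	N	N	N
impaired vestibulo-ocular reflex suppression	N	N	N	N	N	N	N	N	N	N	N	N	N	Y
bilateral vestibular deficit	N	N	N	N	N	Y	N	N	N	N	N	N	N	N
one-and-a-half syndrome	N	N	N	N	N	N	N	HR	N	N	N	Y	N	N
ptosis	N	N	N	N	N	N	N	N	N	N	N	N	N	N
lid retraction	N	N	N	N	N	N	N	N	N	Y	Y	N	N	N
skew deviation	N	N	N	N	N	N	N	Y	N	N	Y	Y	N	N
esotropia	N	N	N	N	N	Y	N	N	N	N	Y	N	N	N
exotropia	N	N	Y	N	N	N	N	N	N	N	N	N	N	N
impaired optokinetic nystagmus	N	N	N	N	N	Y	N	N	N	N	Y	N	N	N
impaired convergence	N	N	N	N	N	N	N	N	Y	N	Y	N	N	N
fixation instability	N	N	N	N	N	N	Y	N	N	N	N	N	Y	N
central fixation nystagmus	N	N	N	N	N	N	N	Y	N	N	N	N	N	N
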