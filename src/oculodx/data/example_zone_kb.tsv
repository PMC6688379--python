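# entity_kind: BRAIN_ZONE
symptom	Midbrain	Pons	Medulla oblongata	Basal ganglia	Frontoparietal cortex	Flocculus/paraflocculus	Vermis/fastigial nucleus	Nodulus/uvula
ataxia	N	N	N	N	N	N	HR	R
paresis	N	R	N	N	R	N	N	N
resting tremor	N	N	N	HR	N	N	N	N
intention tremor	N	N	N	N	N	N	R	N
dystonia	N	N	N	HR	N	N	N	N
chorea	N	N	N	HR	N	N	N	N
cognitive decline	N	N	N	N	R	N	N	N
psychiatric symptoms	N	N	N	N	R	N	N	N
dysarthria	N	R	R	N	N	N	R	N
dysphagia	N	N	HR	N	N	N	N	N
peripheral neuropathy	N	N	N	N	N	N	N	N
seizures	N	N	N	N	HR	N	N	N
telangiectasia	N	N	N	N	N	N	N	N
splenomegaly	N	N	N	N	N	N	N	N
hepatomegaly	N	N	N	N	N	N	N	N
rigidity	N	N	N	R	N	N	N	N
bradykinesia	N	N	N	R	N	N	N	N
postural instability with falls	N	N	N	R	N	N	N	N
confusion	N	N	N	N	R	N	N	N
myoclonus	N	N	N	N	N	N	N	N
vertical saccade palsy	HR	N	N	N	N	N	N	N
horizontal saccade palsy	N	HR	N	N	N	N	N	N
vertical supranuclear gaze palsy	HR	N	N	N	N	N	N	N
horizontal supranuclear gaze palsy	N	HR	N	N	N	N	N	N
internuclear ophthalmoplegia aged < 60 years	N	HR	N	N	N	N	N	N
internuclear ophthalmoplegia aged >= 60 years	N	HR	N	N	N	N	N	N
oculomotor apraxia	N	N	N	N	HR	N	N	N
slow vertical saccades	R	N	N	N	N	N	N	N
slow horizontal saccades	N	R	N	N	N	N	N	N
hypermetric saccades	N	N	N	N	N	N	HR	N
hypometric saccades	N	N	N	R	N	N	R	N
increased saccade latency	N	N	N	R	R	N	N	N
gaze-evoked nystagmus	N	N	N	N	N	HR	N	N
downbeat nystagmus	N	N	N	N	N	HR	N	N
upbeat nystagmus	R	N	HR	N	N	N	N	N
rebound nystagmus	N	N	N	N	N	R	N	N
spontaneous nystagmus	N	N	R	N	N	N	N	R
head-shaking nystagmus	N	N	R	N	N	N	N	R
periodic alternating nystagmus	N	N	N	N	N	N	N	HR
positioning nystagmus	N	N	N	N	N	N	N	HR
convergence-retraction nystagmus	HR	N	N	N	N	N	N	N
see-saw nystagmus	R	N	N	N	N	N	N	N
square wave jerks	N	N	N	R	N	N	N	N
opsoclonus	N	N	N	N	N	N	N	N
ocular flutter	N	N	N	N	N	N	N	N
macro square wave jerks	N	N	N	N	N	N	R	N
saccadic smooth pursuit	N	N	N	N	N	HR	N	N
impaired vertical smooth pursuit	R	N	N	N	N	R	N	N
impaired vestibulo-ocular reflex suppression	N	N	N	N	N	R	N	N
bilateral vestibular deficit	N	N	N	N	N	N	N	N
one-and-a-half syndrome	N	HR	N	N	N	N	N	N
ptosis	R	N	N	N	N	N	N	N
lid retraction	R	N	N	N	N	N	N	N
skew deviation	R	R	R	N	N	N	N	N
esotropia	N	R	N	N	N	N	N	N
exotropia	N	N	N	N	N	N	N	N
impaired optokinetic nystagmus	N	N	N	N	N	N	N	N
impaired convergence	R	N	N	N	N	N	N	N
fixation instability	N	N	N	N	R	N	N	N
central fixation nystagmus	N	N	R	N	N	R	N	N
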