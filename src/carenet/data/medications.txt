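# Medication and clinical tokens that look like person names; lower-case.
abilify
advil
albuterol
allegra
ambien
amlodipine
aricept
aspirin
atenolol
ativan
atorvastatin
benadryl
buspar
celexa
cipro
colace
coumadin
cymbalta
depakote
digoxin
dilantin
donepezil
eliquis
exelon
flomax
furosemide
gabapentin
haldol
humira
ibuprofen
insulin
januvia
keppra
klonopin
lantus
lasix
levaquin
lexapro
lipitor
lisinopril
lorazepam
losartan
lyrica
melatonin
memantine
metformin
metoprolol
miralax
mirtazapine
motrin
namenda
neurontin
norvasc
omeprazole
oxygen
paxil
plavix
pradaxa
prednisone
prilosec
prozac
quetiapine
remeron
risperdal
ritalin
seroquel
sertraline
simvastatin
sinemet
synthroid
tamsulosin
trazodone
tylenol
valium
vitamin
warfarin
wellbutrin
xanax
xarelto
zoloft
zyprexa
zyrtec
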