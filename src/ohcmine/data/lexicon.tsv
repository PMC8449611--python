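# surface	concept_id	category
lorazepam	lorazepam	drug
ativan	lorazepam	drug
amitriptyline	amitriptyline	drug
elavil	amitriptyline	drug
gabapentin	gabapentin	drug
neurontin	gabapentin	drug
methylphenidate	methylphenidate	drug
ritalin	methylphenidate	drug
quetiapine	quetiapine	drug
seroquel	quetiapine	drug
pregabalin	pregabalin	drug
lyrica	pregabalin	drug
celecoxib	celecoxib	drug
celebrex	celecoxib	drug
buprenorphine	buprenorphine	drug
buprenorphine-naloxone	buprenorphine	drug
suboxone	buprenorphine	drug
natalizumab	natalizumab	drug
tysabri	natalizumab	drug
clopidogrel	clopidogrel	drug
plavix	clopidogrel	drug
levonorgestrel	levonorgestrel	drug
levofloxacin	levofloxacin	drug
levaquin	levofloxacin	drug
anxiety	anxiety	indication
depression	depression	indication
epilepsy	epilepsy	indication
postherpetic neuralgia	postherpetic_neuralgia	indication
seizures	seizures	indication
seizure	seizures	indication
partial onset seizures	partial_onset_seizures	indication
adhd	attention_deficit_hyperactivity_disorder	indication
attention deficit hyperactivity disorder	attention_deficit_hyperactivity_disorder	indication
bipolar disorder	bipolar_disorder	indication
mania	mania	indication
schizophrenia	schizophrenia	indication
spinal cord injury	spinal_cord_injury	indication
diabetic peripheral neuropathy	diabetic_peripheral_neuropathy	indication
fibromyalgia	fibromyalgia	indication
neuropathic pain	neuropathic_pain	indication
nerve pain	neuropathic_pain	indication
acute pain	acute_pain	indication
dysmenorrhea	dysmenorrhea	indication
osteoarthritis	osteoarthritis	indication
rheumatoid arthritis	rheumatoid_arthritis	indication
juvenile rheumatoid arthritis	juvenile_rheumatoid_arthritis	indication
pain	pain	indication
overdose	overdose	indication
drug abuse	drug_abuse	indication
multiple sclerosis	multiple_sclerosis	indication
antiplatelet agent	antiplatelet_agent	indication
antiplatelet therapy	antiplatelet_agent	indication
contraception	contraception	indication
birth control	contraception	indication
broad spectrum antibiotic	broad_spectrum_antibiotic	indication
bacterial infections	broad_spectrum_antibiotic	indication
insomnia	sleep_disorder_insomnia	indication
sleep disorder	sleep_disorder_insomnia	indication
sleep problems	sleep_disorder_insomnia	indication
panic attacks	panic_attacks	indication
panic attack	panic_attacks	indication
headaches	headaches	indication
headache	headaches	indication
migraine	migraine	indication
migraines	migraine	indication
neuropathy	neuropathy	indication
numbness	numbness	indication
spasms	spasms	indication
swelling	swelling	indication
addiction	addiction	indication
heartburn	heartburn	indication
restless legs syndrome	restless_legs_syndrome	indication
menopause	menopause	indication
irritable bowel syndrome	irritable_bowel_syndrome	indication
carcinoma	carcinoma	indication
gastritis	gastritis	indication
angina	angina	indication
common cold	common_cold	indication
stroke	stroke	indication
tachycardia	tachycardia	indication
chills	chills	indication
cystitis	cystitis	indication
fatigue	fatigue	indication
stress disorder	stress_disorder	indication
cancer	cancer	indication
autism	autism	indication
nausea	nausea	indication
tumors	tumors	indication
apnea	apnea	indication
diabetes	diabetes	indication
mood control	mood_control	indication
mood swings	mood_control	indication
paranoia	paranoia	indication
agitation	agitation	indication
hallucinations	hallucinations	indication
dyskinesia	dyskinesia	indication
dizziness	dizziness	indication
palpitations	palpitations	indication
allergy	allergy	indication
psychosis	psychosis	indication
hypothyroidism	hypothyroidism	indication
hives	hives	indication
shingles	shingles	indication
influenza	influenza	indication
neuralgia	neuralgia	indication
arthritis	arthritis	indication
paresthesia	paresthesia	indication
spondylitis	spondylitis	indication
tendonitis	tendonitis	indication
hematuria	hematuria	indication
infection	infection	indication
asthma	asthma	indication
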