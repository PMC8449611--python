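{
  "version": "1.0",
  "source": "FDA drug labels (openFDA indications_and_usage), curated for the 12 study drugs",
  "drugs": {
    "lorazepam": ["anxiety", "depression"],
    "amitriptyline": ["depression"],
    "gabapentin": ["epilepsy", "postherpetic_neuralgia", "seizures"],
    "methylphenidate": ["attention_deficit_hyperactivity_disorder"],
    "quetiapine": ["bipolar_disorder", "depression", "mania", "mental_disorders", "schizophrenia"],
    "pregabalin": ["spinal_cord_injury", "diabetic_peripheral_neuropathy", "fibromyalgia", "neuropathic_pain", "partial_onset_seizures", "postherpetic_neuralgia"],
    "celecoxib": ["acute_pain", "dysmenorrhea", "juvenile_rheumatoid_arthritis", "osteoarthritis", "pain", "rheumatoid_arthritis"],
    "buprenorphine": ["overdose", "pain", "drug_abuse"],
    "natalizumab": ["multiple_sclerosis"],
    "clopidogrel": ["antiplatelet_agent"],
    "levonorgestrel": ["contraception"],
    "levofloxacin": ["broad_spectrum_antibiotic"]
  },
  "synonyms": {
    "anxiety": "anxiety",
    "anxious": "anxiety",
    "depression": "depression",
    "depressed": "depression",
    "epilepsy": "epilepsy",
    "postherpetic neuralgia": "postherpetic_neuralgia",
    "seizures": "seizures",
    "seizure": "seizures",
    "partial onset seizures": "partial_onset_seizures",
    "attention deficit hyperactivity disorder": "attention_deficit_hyperactivity_disorder",
    "adhd": "attention_deficit_hyperactivity_disorder",
    "bipolar disorder": "bipolar_disorder",
    "bipolar i disorder": "bipolar_disorder",
    "bipolar ii disorder": "bipolar_disorder",
    "bipolar": "bipolar_disorder",
    "mania": "mania",
    "manic": "mania",
    "mental disorders": "mental_disorders",
    "schizophrenia": "schizophrenia",
    "spinal cord injury": "spinal_cord_injury",
    "diabetic peripheral neuropathy": "diabetic_peripheral_neuropathy",
    "fibromyalgia": "fibromyalgia",
    "neuropathic pain": "neuropathic_pain",
    "nerve pain": "neuropathic_pain",
    "acute pain": "acute_pain",
    "dysmenorrhea": "dysmenorrhea",
    "primary dysmenorrhea": "dysmenorrhea",
    "juvenile rheumatoid arthritis": "juvenile_rheumatoid_arthritis",
    "osteoarthritis": "osteoarthritis",
    "rheumatoid arthritis": "rheumatoid_arthritis",
    "pain": "pain",
    "overdose": "overdose",
    "drug abuse": "drug_abuse",
    "opioid addiction": "drug_abuse",
    "multiple sclerosis": "multiple_sclerosis",
    "antiplatelet agent": "antiplatelet_agent",
    "antiplatelet therapy": "antiplatelet_agent",
    "contraception": "contraception",
    "birth control": "contraception",
    "broad spectrum antibiotic": "broad_spectrum_antibiotic",
    "bacterial infections": "broad_spectrum_antibiotic",
    "insomnia": "sleep_disorder_insomnia",
    "sleep disorder": "sleep_disorder_insomnia",
    "sleep problems": "sleep_disorder_insomnia",
    "sleeplessness": "sleep_disorder_insomnia",
    "panic attacks": "panic_attacks",
    "panic attack": "panic_attacks",
    "headaches": "headaches",
    "headache": "headaches",
    "migraine": "migraine",
    "migraines": "migraine",
    "neuropathy": "neuropathy",
    "restless legs syndrome": "restless_legs_syndrome",
    "irritable bowel syndrome": "irritable_bowel_syndrome",
    "common cold": "common_cold",
    "mood control": "mood_control",
    "mood swings": "mood_control",
    "stress disorder": "stress_disorder",
    "chronic fatigue syndrome": "chronic_fatigue_syndrome"
  }
}
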