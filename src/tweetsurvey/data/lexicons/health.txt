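; Starter health vocabulary (run input in production; bundled for tests and
; the synthetic generator).
health
healthcare
hospital
hospitals
doctor
doctors
nurse
nurses
medicine
medical
clinic
patient
patients
disease
illness
treatment
therapy
surgery
symptom
symptoms
diagnosis
pharmacy
prescription
drug
drugs
cancer
diabetes
obesity
fitness
exercise
diet
nutrition
wellness
mental health
insomnia
allergy
asthma
cardiology
pediatric
dental
flu
influenza
checkup
screening
physiotherapy
midwife
ambulance
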