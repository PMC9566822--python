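# Health-care-worker identification dictionary: 47 keywords in three classes
# (occupation | degree | association), built from standard clinical titles.
# Format: term<TAB>class<TAB>acronym-flag (1 = token-exact, case-sensitive)
doctor	occupation	0
physician	occupation	0
nurse	occupation	0
surgeon	occupation	0
psychiatrist	occupation	0
psychologist	occupation	0
pediatrician	occupation	0
cardiologist	occupation	0
paramedic	occupation	0
pharmacist	occupation	0
dentist	occupation	0
midwife	occupation	0
anesthesiologist	occupation	0
radiologist	occupation	0
oncologist	occupation	0
neurologist	occupation	0
nurse practitioner	occupation	0
physician assistant	occupation	0
medical student	occupation	0
med student	occupation	0
icu nurse	occupation	0
er nurse	occupation	0
registered nurse	occupation	0
family physician	occupation	0
hospitalist	occupation	0
intensivist	occupation	0
respiratory therapist	occupation	0
emergency physician	occupation	0
MD	degree	1
DO	degree	1
RN	degree	1
BSN	degree	1
MSN	degree	1
DNP	degree	1
MBBS	degree	1
PharmD	degree	0
DDS	degree	1
DMD	degree	1
doctor of medicine	degree	0
medical doctor	degree	0
FACP	association	1
FACS	association	1
FAAP	association	1
FACC	association	1
FACEP	association	1
FCCP	association	1
american medical association	association	0
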