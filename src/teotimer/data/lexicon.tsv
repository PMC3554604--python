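# teotimer packaged lexicon excerpt: surface form -> ontology term.
# Columns: surface<TAB>vocabulary<TAB>identifier<TAB>preferred_label
# The OAE/VO/MedDRA identifiers documented in the literature for
# 'influenza like illness' (OAE_0000100, MedDRA 10022004) and Engerix-B
# (VO_0010711) are used verbatim; ALL OTHER identifiers are synthetic
# placeholders (OAE_09xxxxx / VO_09xxxxx / 109xxxxx) standing in for a
# full ontology import, which is out of scope for this package.
flu-like symptoms	OAE	OAE_0000100	influenza like illness AE
flu-like illness	OAE	OAE_0000100	influenza like illness AE
influenza-like illness	OAE	OAE_0000100	influenza like illness AE
influenza like illness AE	OAE	OAE_0000100	influenza like illness AE
flu-like symptoms	MedDRA	10022004	influenza like illness
flu-like illness	MedDRA	10022004	influenza like illness
influenza-like illness	MedDRA	10022004	influenza like illness
influenza	MedDRA	10900001	influenza
Engerix-B	VO	VO_0010711	Engerix-B
engerix b vaccine	VO	VO_0010711	Engerix-B
1st engerix-b dose	VO	VO_0010711	Engerix-B
hepatitis B vaccine	VO	VO_0900002	hepatitis B vaccine
hep b vaccine	VO	VO_0900002	hepatitis B vaccine
hep vaccine	VO	VO_0900002	hepatitis B vaccine
MMR vaccine	VO	VO_0900001	MMR vaccine
mmr	VO	VO_0900001	MMR vaccine
vaccinated w/MMR	VO	VO_0900001	MMR vaccine
measles mumps and rubella vaccine	VO	VO_0900001	MMR vaccine
DTP vaccine	VO	VO_0900003	DTP vaccine
dtp	VO	VO_0900003	DTP vaccine
fever	OAE	OAE_0900001	fever AE
pyrexia	OAE	OAE_0900001	fever AE
fever	MedDRA	10900101	fever
pyrexia	MedDRA	10900101	fever
macular rash	OAE	OAE_0900002	macular rash AE
rash macular	OAE	OAE_0900002	macular rash AE
macular rash	MedDRA	10900102	macular rash
rash	OAE	OAE_0900003	rash AE
skin rash	OAE	OAE_0900003	rash AE
rash	MedDRA	10900103	rash
vasculitis	OAE	OAE_0900004	vasculitis AE
vasculitis	MedDRA	10900104	vasculitis
patient hospitalization	OAE	OAE_0900005	hospitalization AE
hospitalized	OAE	OAE_0900005	hospitalization AE
patient hospitalized	OAE	OAE_0900005	hospitalization AE
hospitalization	MedDRA	10900105	hospitalization
seizure	OAE	OAE_0900006	seizure AE
brief generalized seizure	OAE	OAE_0900006	seizure AE
convulsion	OAE	OAE_0900006	seizure AE
seizure	MedDRA	10900106	seizure
nausea	OAE	OAE_0900007	nausea AE
nauseous	OAE	OAE_0900007	nausea AE
nausea	MedDRA	10900107	nausea
arthralgia	OAE	OAE_0900008	arthralgia AE
joint pain	OAE	OAE_0900008	arthralgia AE
arthralgia	MedDRA	10900108	arthralgia
injection site reaction	OAE	OAE_0900009	injection site reaction AE
injection-site reaction	OAE	OAE_0900009	injection site reaction AE
reaction at injection site	OAE	OAE_0900009	injection site reaction AE
injection site reaction	MedDRA	10900109	injection site reaction
headache	OAE	OAE_0900010	headache AE
head ache	OAE	OAE_0900010	headache AE
headache	MedDRA	10900110	headache
vomiting	OAE	OAE_0900011	vomiting AE
emesis	OAE	OAE_0900011	vomiting AE
vomiting	MedDRA	10900111	vomiting
fatigue	OAE	OAE_0900012	fatigue AE
tiredness	OAE	OAE_0900012	fatigue AE
dizziness	OAE	OAE_0900013	dizziness AE
dizzy	OAE	OAE_0900013	dizziness AE
urticaria	OAE	OAE_0900014	urticaria AE
hives	OAE	OAE_0900014	urticaria AE
myalgia	OAE	OAE_0900015	myalgia AE
muscle pain	OAE	OAE_0900015	myalgia AE
chills	OAE	OAE_0900016	chills AE
rigors	OAE	OAE_0900016	chills AE
pruritus	OAE	OAE_0900017	pruritus AE
itching	OAE	OAE_0900017	pruritus AE
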