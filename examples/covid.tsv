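!site	COVID cases
!language	en
!category	Patients
!group	Demographics
Age	number	0:120	years	age at enrollment
Sex	enum	F|M		biological sex
Residence	coordinates			place of residence
!group	Clinical
Symptom onset	date			date of first symptoms
Fever	tristate			fever reported at onset
Cough	tristate			cough reported at onset
Hospitalized	boolean			ever admitted to hospital
Comorbidities	text			free-text comorbidity list
Info sheet	url			link to the information sheet
!category	Samplings	connection=Has Patient->Patients
!group	Sampling
Sampling date	date			date of the swab
Temperature	number	30:45	°C	body temperature at sampling
Result	enum	negative|positive		swab outcome
Severity	enum	mild|moderate|severe		clinical severity at sampling
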