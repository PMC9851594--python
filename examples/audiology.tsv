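!site	Audiological prostheses
!language	en
!category	Patients
!group	Demographics
Age	number	0:120	years	age at enrollment
!category	Visits	connection=Has Patient->Patients
!group	Audiometry
Pure tone average of vocal gain during last control exam with intracochlear device on left ear	number	0:120	dB	complex audiometric measure	measure=pure tone average; exam=last control; device=intracochlear; laterality=left; organ=ear
Pure tone average of vocal gain during last control exam with intracochlear device on right ear	number	0:120	dB	complex audiometric measure	measure=pure tone average; exam=last control; device=intracochlear; laterality=right; organ=ear
Implant date	date			date of implantation
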