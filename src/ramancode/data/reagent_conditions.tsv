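index	name	property	chemicals	purpose
1	activation	Activation agent	Cl-HOBt, DIC in DMF	Amide coupling
2	piperidine	Base/nucleophile	Piperidine	Orthogonal deprotection of Fmoc
3	imidazole_nh2oh	Base/reductant	Imidazole/NH2OH	Orthogonal deprotection of Dde
4	tfa	Strong acid	TFA	Global deprotection
5	dmso_buffer	Oxidant	DMSO in buffer (pH 6.0)	Dithiol cyclization
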