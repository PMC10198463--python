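# Reported chemical-survivability outcomes of the candidate Raman encoding
# compounds, transcribed from the published compound-by-compound account.
# The source reports 21 compounds investigated but names only 20; the 21st
# is unresolved and deliberately not invented here.
# first_failed is the reagent condition name at which the compound failed
# (empty when it passed the full panel).
compound	group	peak_cm1	outcome	first_failed
I-2295	I	2295	not_pass	piperidine
I-2245	I	2245	pass
I-2225	I	2225	pass
I-2200	I	2200	pass
I-2215	I	2215	pass
I-2210	I	2210	pass
I-2209	I	2209	not_pass	piperidine
II-2180	II	2180	not_pass	piperidine
II-2135	II	2135	not_pass	piperidine
II-2162	II	2162	not_pass	tfa
II-2158	II	2158	not_pass	tfa
II-2160	II	2160	pass
II-2156	II	2156	not_pass	tfa
II-2110	II	2110	pass
III-1585	III	1585	not_pass	piperidine
III-1143	III	1143	pass
III-1140	III	1140	pass
III-1127	III	1127	pass
III-1105	III	1105	pass
III-1142	III	1142	not_pass	tfa
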