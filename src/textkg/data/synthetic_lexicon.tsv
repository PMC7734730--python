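# term	cui	description	score
study	C0557651	Study	0.95
prevalence	C0033105	Prevalence	0.90
impairment	C0221099	Impaired	0.85
cognitive impairment	C0338656	Cognitive impairment	0.99
populations	C0032659	Population	0.80
confirm	C1456348	Confirm	0.70
attention	C0004268	Attention	0.90
development	C0243107	Development	0.80
risk factors	C0035648	Risk factor	0.90
differences	C1705241	Difference	0.60
dementia	C0011265	Dementia	0.95
diabetes mellitus	C0011849	Diabetes mellitus	0.99
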