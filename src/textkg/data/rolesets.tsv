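# lemma	sense_id	label=role pairs
confirm	confirm.01	A0=Agent A1=Theme
confirm	confirm.02	A0=Agent A1=Theme A2=Attribute
warrant	warrant.01	A0=Agent A1=Theme
highlight	highlight.01	A0=Agent A1=Theme
point	point.01	A0=Agent A1=Theme
confound	confound.01	A0=Agent A1=Theme
require	require.01	A0=Agent A1=Theme
reduce	reduce.01	A0=Agent A1=Theme
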