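peptide	activity_code	activity_name	ic50_value	ic50_unit	reference
GF	ah	ACE inhibitor	277.9	uM	aqueous garlic extract
GF	dpp	DPP-IV inhibitor	1547	uM	salmon residual meat digest (Corolase PP)
SF	ah	ACE inhibitor	130.2	uM	aqueous garlic extract
SF	dpp	DPP-IV inhibitor			synthetic dipeptide library (13.5% inhibition)
QF	dpp	DPP-IV inhibitor			synthetic dipeptide library (28.6% inhibition)
DF	ah	ACE inhibitor	360	uM	anchovy fish sauce
PGL	ah	ACE inhibitor	13.93	uM	Alaskan pollack skin gelatin
TF	ah	ACE inhibitor	18.0	uM	wheat bran autolysate
TF	dpp	DPP-IV inhibitor			synthetic dipeptide library (32.1% inhibition)
GR	ah	ACE inhibitor	162.2	uM	dry-cured meat
RL	ah	ACE inhibitor	2439	uM	beta-lactoglobulin hydrolysate
RL	dpp	DPP-IV inhibitor			synthetic dipeptide library (20.2% inhibition)
DR	dpp	DPP-IV inhibitor			synthetic dipeptide library (26.1% inhibition)
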