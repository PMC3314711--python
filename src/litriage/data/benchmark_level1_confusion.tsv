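# Level-1 confusion matrix on the 287 independent-benchmark abstracts
# confirmed curatable: rows = human-expert category, columns = classifier
# prediction.
expert	Allergy	Autoimmunity	Infectious Disease	Transplantation	Cancer	HIV	Other
Allergy	11	1	0	0	0	0	0
Autoimmunity	0	58	0	0	0	0	1
Infectious Disease	0	1	100	0	1	0	2
Transplantation	0	1	0	8	0	0	0
Cancer	0	1	0	1	41	0	2
HIV	0	0	2	0	0	33	0
Other	0	1	1	0	1	0	20
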