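# Level-2/3 agreement between classifier and human expert on the 287
# independent-benchmark curatable abstracts, by Level-1 branch.  NA marks
# levels the taxonomy skips for that branch.
level1	priority	assigned_by_expert	level2_correct	level3_correct
Allergy	high	12	11	9
Autoimmunity	high	59	58	48
Infectious Disease	high	104	98	91
Transplantation	high	9	NA	8
Cancer	low	45	NA	32
HIV	low	35	NA	NA
Other	low	23	19	19
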