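# Per-category cross-validated AUCs for the seven Autoimmunity Level-2
# classifiers, trained flat (negatives = all curatable abstracts) versus
# hierarchically (negatives = Autoimmunity siblings only).
category	n_curatable	flat_auc	hierarchical_auc
Beta-Amyloid	213	0.994	0.998
Diabetes	443	0.997	0.998
General Autoimmune	1311	0.967	0.987
Lupus	704	0.975	0.988
Multiple Sclerosis	957	0.982	0.990
Myasthenia Gravis	221	0.983	0.992
Rheumatoid Arthritis	501	0.983	0.990
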