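# Level-0 curatability outcome on the 1,388-abstract independent benchmark.
# predicted_curatable split by expert confirmation; predicted_uncuratable
# split by expert-identified curatable misses.
outcome	count
predicted_curatable_confirmed	287
predicted_curatable_rejected	355
predicted_uncuratable_missed	14
predicted_uncuratable_confirmed	732
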