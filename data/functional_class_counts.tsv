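functional_class	count
Nonsense	9757
Missense	358102
Silent	245940
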