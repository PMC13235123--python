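# Synthetic toxicity fixture: constructed normalized epitope frequencies with
# hand-computed weighted loads (42 / 21 / 10.5 -> 100% / 50% / 25%).
# a1a is HT (weight 3), a3 is MT (weight 2), a3_v3 is LT (weight 1),
# a2_v8 is NT (weight 0, must not affect the load).
genotype	a1a	a3	a3_v3	a2_v8
synthetic-high	10	5	2	0
synthetic-mid	5	2.5	1	3
synthetic-low	2	2	0.5	50
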