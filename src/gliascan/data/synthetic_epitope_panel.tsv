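# Synthetic stand-in epitope panel.
# Canonical sequences (mismatches = 0 for the alpha families) are the published
# alpha-gliadin celiac epitopes; all variant rows are CONSTRUCTED sequences with
# constructed toxicity classes, provided so the pipeline can be exercised offline.
id	name	sequence	family	toxicity_class	mismatches
a1a	DQ2.5-glia-α1a	PFPQPQLPY	alpha1	HT	0
a1b	DQ2.5-glia-α1b	PYPQPQLPY	alpha1	HT	0
a2	DQ2.5-glia-α2	PQPQLPYPQ	alpha2	HT	0
a3	DQ2.5-glia-α3	FRPQQPYPQ	alpha3	MT	0
p31	p31-43	LGQQQPFPPQQPY	p31-43	T	0
ave1b	DQ2.5-ave-1b	PYPEQEQPF	other	unk	0
g1	DQ2.5-glia-g1	PQQSFPEQQ	other	unk	0
a1a_v1	DQ2.5-glia-α1a (var1)	PFPQPELPY	alpha1	LT	1
a1a_v2	DQ2.5-glia-α1a (var2)	PFSQPQLPY	alpha1	NT	1
a1a_v3	DQ2.5-glia-α1a (var3)	PFPQPQLPV	alpha1	NT	1
a1b_v1	DQ2.5-glia-α1b (var1)	PYPQPQLPF	alpha1	RT	1
a2_v1	DQ2.5-glia-α2 (var1)	PQPQLPYSQ	alpha2	RT	1
a2_v2	DQ2.5-glia-α2 (var2)	PQPELPYPQ	alpha2	MT	1
a2_v4	DQ2.5-glia-α2 (var4)	PQSQLPYPQ	alpha2	LT	1
a2_v7	DQ2.5-glia-α2 (var7)	PQPQLSYPQ	alpha2	LT	1
a2_v8	DQ2.5-glia-α2 (var8)	PQPQLPYAQ	alpha2	NT	1
a2_v9	DQ2.5-glia-α2 (var9)	PQPQLPYPE	alpha2	unk	1
a3_v1	DQ2.5-glia-α3 (var1)	FRPQQPYPE	alpha3	RT	1
a3_v2	DQ2.5-glia-α3 (var2)	FRPQQSYPQ	alpha3	RT	1
a3_v3	DQ2.5-glia-α3 (var3)	FRPEQPYPQ	alpha3	LT	1
a3_v7	DQ2.5-glia-α3 (var7)	FPPQQPYPQ	alpha3	LT	1
a3_v8	DQ2.5-glia-α3 (var8)	FRPQQPYAQ	alpha3	unk	1
p31_v1	p31-43 (var1)	LGQQQPFPPQQPF	p31-43	RT	1
p31_v5	p31-43 (var5)	LGQQQPFPSQQPY	p31-43	LT	1
p31_55	p31-55	LGQQQPFPPQQPYPQPQPF	p31-43	RT	0
p44_55	p44-55	PQPQPFPSQQPY	p31-43	RT	0
g1_v1	DQ2.5-glia-g1 (var1)	PQQSFPEQE	other	unk	1
ave1b_v1	DQ2.5-ave-1b (var1)	PYPEQEQPY	other	unk	1
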