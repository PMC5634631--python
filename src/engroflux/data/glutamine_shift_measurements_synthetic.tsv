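# SYNTHETIC stand-in for the glutamine-limitation GC-MS fold-change table.
# Levels in the low-glutamine condition relative to the high-glutamine
# reference (= 1.0). Directions transcribed from the published narrative;
# magnitudes and sd are invented placeholders for sign-agreement scoring.
metabolite	fold_change	sd
pyruvate	1.8	0.1
acetyl-CoA	1.6	0.1
hydrogen peroxide	1.4	0.1
succinate	1.3	0.1
serine	1.15	0.1
lactate	0.75	0.1
citrate	0.5	0.1
alpha-ketoglutarate	0.6	0.1
malate	0.6	0.1
fumarate	0.65	0.1
glutamine	0.4	0.1
glutamate	0.5	0.1
aspartate	0.6	0.1
glycine	0.7	0.1
alanine	0.6	0.1
methionine	0.8	0.1
cysteine	0.7	0.1
ornithine	0.8	0.1
putrescine	0.8	0.1
glucose	1.0	0.1
trehalose	1.0	0.1
lysine	0.95	0.1
tyrosine	0.95	0.1
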