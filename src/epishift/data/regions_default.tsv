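name	domain_tag	residues
aPL_loop_1	DV	303,305,306
aPL_loop_2	DV	332,334,335
anti_A1_loop	DV	301,327,336
K269_K270	DV	269,270
motif_1	DI-II	29-36
motif_2	DI-II	35-43
motif_3	DI-II	58-62
motif_4	DI-II	69-77
motif_5	DI-II	84-91
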