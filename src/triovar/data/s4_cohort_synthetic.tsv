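# Synthetic reconstruction of the 22-dog validation cohort: 8 affected
# (all homozygous for the candidate insertion), 14 unaffected (het or
# homozygous wild type). Per-dog genotypes beyond the named carriers are
# assigned to match the published summary, not copied from the original
# supplementary table.
dog_id	phenotype	genotype
LAB5	affected	1/1
LAB6	unaffected	0/1
LAB7	unaffected	0/1
LAB8	unaffected	0/0
LAB9	affected	1/1
LAB10	affected	1/1
LAB11	unaffected	0/1
LAB12	affected	1/1
LAB13	unaffected	0/0
LAB14	unaffected	0/1
LAB15	affected	1/1
LAB16	affected	1/1
LAB17	unaffected	0/1
LAB18	affected	1/1
LAB19	unaffected	0/0
LAB20	affected	1/1
LAB21	unaffected	0/0
LAB22	unaffected	0/0
LAB23	unaffected	0/0
LAB24	unaffected	0/0
LAB25	unaffected	0/1
LAB26	unaffected	0/0
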