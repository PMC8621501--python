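gene_symbol	chrom	start	end	lipid_trait
HMGCR	5	74632154	74657929	LDL-C
NPC1L1	7	44552134	44580914	LDL-C
PCSK9	1	55505221	55530525	LDL-C
CETP	16	56995762	57017757	LDL-C
LDLR	19	11200038	11244506	LDL-C
ANGPTL3	1	63063158	63071830	TG
LPL	8	19759228	19824769	TG
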