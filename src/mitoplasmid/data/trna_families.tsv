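# Anticodon-family map for a canonical fungal mitochondrial tRNA set (24 genes).
# Each row maps one mitochondrial tRNA (isotype + anticodon, written 5'->3' as DNA)
# to the set of sense codons it decodes under the mold mitochondrial genetic code
# (TGA = Trp; TAA/TAG are the only stops, so 62 sense codons in total).
# Wobble conventions used, typical of organellar decoding:
#   - four-codon boxes are read by a single tRNA with an unmodified U34
#     ("superwobble"): Ala, Gly, Pro, Thr, Val, Ser(TGA), Leu(TAG), Arg(TCG);
#   - NNY two-codon sets are read by G34; NNR two-codon sets by U34;
#   - ATA is assigned its own tRNA-Ile(TAT); ATG to tRNA-Met(CAT);
#   - TGA joins TGG in the Trp family (tRNA-Trp(TCA) with U34).
# Every sense codon appears in exactly one family. Edit freely to match a
# curated annotation; the loader validates the partition.
isotype	anticodon	codons
Ala	TGC	GCT,GCC,GCA,GCG
Arg	TCG	CGT,CGC,CGA,CGG
Arg	TCT	AGA,AGG
Asn	GTT	AAT,AAC
Asp	GTC	GAT,GAC
Cys	GCA	TGT,TGC
Gln	TTG	CAA,CAG
Glu	TTC	GAA,GAG
Gly	TCC	GGT,GGC,GGA,GGG
His	GTG	CAT,CAC
Ile	GAT	ATT,ATC
Ile	TAT	ATA
Leu	TAA	TTA,TTG
Leu	TAG	CTT,CTC,CTA,CTG
Lys	TTT	AAA,AAG
Met	CAT	ATG
Phe	GAA	TTT,TTC
Pro	TGG	CCT,CCC,CCA,CCG
Ser	TGA	TCT,TCC,TCA,TCG
Ser	GCT	AGT,AGC
Thr	TGT	ACT,ACC,ACA,ACG
Trp	TCA	TGA,TGG
Tyr	GTA	TAT,TAC
Val	TAC	GTT,GTC,GTA,GTG
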