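# C-terminal 12-mers of pre-duplication Saccharomycetaceae IDP2 genes:
# the annotated in-frame terminus and, where present, the cryptic +1-frame
# isoform terminus revealed downstream of the stop codon. K. lactis carries
# no cryptic +1-frame PTS1-like peptide (empty field).
species	gene_id	inframe_cterm	cryptic_plus1_cterm
A. gossypii	AAL022W	RLADGYKRLFCE	RLFVNKKKQAKL
S. kluyveri	SAKL0D08426g	EKRLIAAFRDEF	FVTNFKSNLSKL
K. thermotolerans	KLTH0H12012g	EQRLIRSLKEDR	VLYVALKRTARM
K. waltii	Kwal0.191	ERRLHQGFKSQS	AFIKALNPKAKL
K. lactis	KLLA0F12342g	KRLDSEFKSSFN
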