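gene_key	cycle
K01601_rbcL	C
K11779_fbiC	C
K00239_sdhA	C
K01183_endoglucanase	C
K01209_abfA	C
K01907_acsA	C
K01429_ureB	N
K01428_ureC	N
K00372_nasA	N
K02568_napB	N
K15371_gdhA	N
K02048_cysP	S
K12339_cysM	S
K01077_phoA	P
K00937_ppk	P
K03788_phoN	P
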