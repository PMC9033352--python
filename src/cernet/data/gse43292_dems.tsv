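# Differentially expressed mRNAs, atherosclerotic plaque vs control (GSE43292).
# Note: logFC values for downregulated genes use the typographic minus sign (U+2212)
# as printed in the source table; the reader must accept both minus forms.
gene	logFC	pvalue
FABP4	2.454461	6.05E-08
IBSP	1.794982	1.03E-08
DPP4	1.610873	2.24E-07
chr4:174457998-174460620	−1.50436	1.39E-07
FHL5	−1.56465	1.17E-08
MYOCD	−1.62845	6.08E-08
CASQ2	−1.66766	2.16E-08
CNTN4	−1.79233	3.57E-09
CNTN1	−1.91103	3.00E-08
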