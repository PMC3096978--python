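gene_symbol	direction
CLIC5	-1
CXCL13	-1
MATN1	-1
RPS28	-1
ABO	-1
EXOC7	-1
HAPLN1	1
PRRG3	-1
PRTN3	-1
RFXDC2	-1
RGS4	1
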