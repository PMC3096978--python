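gene_symbol	direction
CXCL13	-1
CLIC5	-1
RGS4	1
RPS28	-1
RFXDC2	-1
EXOC7	-1
HRBL	-1
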