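# Restriction enzyme definitions: name, IUPAC recognition (top strand 5'->3'),
# top-strand cut offset relative to recognition start.
# TaqI  T/CGA       -> cut after 1 base of the site
# BsaI  GGTCTCN/    -> Type IIS, cut after the N downstream of GGTCTC
# DdeI  C/TNAG      -> cut after 1 base of the site
name	recognition	cut_offset
TaqI	TCGA	1
BsaI	GGTCTCN	7
DdeI	CTNAG	1
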