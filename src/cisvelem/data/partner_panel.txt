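# DNMT3B-partner transcription-factor panel (17 named TFs with reported
# binding sites in downregulated promoters; an 18th partner is reported
# but unnamed and therefore not listed). Edit freely: one TF per line.
SP1
EGR-1
ER
GATA-1
GR
c-JUN
YY1
ATF
CREB
ELK1
c-FOS
MYC
E2F
HOXA5
HNF4
MEF2
PPAR
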