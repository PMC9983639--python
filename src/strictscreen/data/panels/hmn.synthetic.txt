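# Hereditary motor neuropathy (HMN) panel (synthetic reconstruction).
# 36 genes with distal HMN / motor-predominant neuropathy phenotypes,
# assembled from public domain knowledge. Five genes (BICD2, DYNC1H1,
# IGHMBP2, TRPV4, UBA1) are shared with the SMA panel.
# This is a stand-in curation, not an authoritative published gene list.
IGHMBP2
DYNC1H1
BICD2
TRPV4
UBA1
GARS1
HSPB1
HSPB8
HSPB3
DNAJB2
BSCL2
REEP1
SLC5A7
MORC2
SORD
WARS1
AARS1
HINT1
FBXO38
DHTKD1
MME
SCO2
TFG
HARS1
MARS1
KIF1B
LRSAM1
ATP7A
PLEKHG5
SYT2
EMILIN1
RAB7A
GDAP1
NEFL
MFN2
SPTLC2
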