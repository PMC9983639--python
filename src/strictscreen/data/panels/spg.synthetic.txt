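# Hereditary spastic paraplegia (SPG) panel (synthetic reconstruction).
# 57 genes from the OMIM spastic paraplegia phenotypic series,
# assembled from public domain knowledge.
# This is a stand-in curation, not an authoritative published gene list.
SPAST
ATL1
REEP1
KIF5A
SPG7
SPG11
ZFYVE26
SPART
SPG21
CYP7B1
NIPA1
WASHC5
PLP1
L1CAM
CYP2U1
DDHD1
DDHD2
GJC2
FA2H
PNPLA6
C19ORF12
ERLIN1
ERLIN2
AP4B1
AP4M1
AP4E1
AP4S1
AP5Z1
TECPR2
VPS37A
ARL6IP1
KIF1A
KIF1C
RTN2
SLC33A1
B4GALNT1
GBA2
ENTPD1
ZFYVE27
ATP13A2
CAPN1
CPT1C
UBAP1
MAG
BSCL2
HSPD1
REEP2
IBA57
TFG
DSTYK
ALDH18A1
NT5C2
ARSI
PGAP1
KLC4
SELENOI
PCYT2
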