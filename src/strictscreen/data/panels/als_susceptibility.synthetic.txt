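# ALS-susceptibility panel (synthetic reconstruction).
# 48 genes reported by large-scale ALS genome-wide association studies,
# assembled from public domain knowledge. Five genes (C9ORF72, KIF5A,
# NEK1, SOD1, TBK1) are shared with the pathogenicity panel.
# This is a stand-in curation, not an authoritative published gene list.
C9ORF72
KIF5A
NEK1
SOD1
TBK1
UNC13A
MOBP
SCFD1
TNIP1
GPX3
ERGIC1
ACSL5
CFAP410
SLC9A8
SPATA2
RPSA
MOB3B
ZNF512B
CAMTA1
SARM1
DPP6
EPHA4
ELP3
HFE
PON1
ITPR2
FGGY
KIFAP3
CYP27A1
MYO18B
GGNBP2
PTPRN2
CNTN4
ZFP64
TYW3
CRYZ
FNBP1
COG3
TMEM229B
ARPP21
SS18L1
CHGB
PON2
PON3
VEGFA
PRPH
NEFH
DAO
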