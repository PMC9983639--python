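# ALS-pathogenicity panel (synthetic reconstruction).
# 32 unique genes with causal (familial) ALS links in the OMIM
# PS105400 phenotypic series, assembled from public domain knowledge.
# This is a stand-in curation, not an authoritative published gene list.
SOD1
ALS2
SETX
SPG11
FUS
VAPB
ANG
TARDBP
FIG4
OPTN
ATXN2
VCP
UBQLN2
SIGMAR1
CHMP2B
PFN1
ERBB4
HNRNPA1
MATR3
TUBA4A
ANXA11
NEK1
KIF5A
TIA1
C9ORF72
CHCHD10
SQSTM1
TBK1
CCNF
GLT8D1
SPTLC1
DCTN1
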