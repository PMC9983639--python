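# Spinocerebellar ataxia (SA) panel (synthetic reconstruction).
# 15 genes from the OMIM spinocerebellar ataxia phenotypic series,
# assembled from public domain knowledge.
# This is a stand-in curation, not an authoritative published gene list.
ATXN1
ATXN3
ATXN7
ATXN10
CACNA1A
SPTBN2
KCNC3
PRKCG
PPP2R2B
TBP
ITPR1
KCND3
NOP56
FGF14
ELOVL5
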