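# Spinal muscular atrophy (SMA) panel (synthetic reconstruction).
# 20 genes with SMA or SMA-variant phenotypes, assembled from public
# domain knowledge. Five genes (BICD2, DYNC1H1, IGHMBP2, TRPV4, UBA1)
# are shared with the HMN panel.
# This is a stand-in curation, not an authoritative published gene list.
SMN1
SMN2
IGHMBP2
DYNC1H1
BICD2
TRPV4
UBA1
ASAH1
VRK1
EXOSC3
EXOSC8
EXOSC9
TSEN54
SLC52A2
SLC52A3
AR
HEXB
ASCC1
TRIP4
GLE1
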