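# Gene -> pathway group map used for the conservation matrix rollups.
# Curated, editable: the groupings mirror the usual pHGG driver pathways
# (receptor tyrosine kinases, PI3K, histone/chromatin modifiers, integrins,
# cadherins, TP53 pathway). Genes absent from the map roll up to "other".
RTK:
  - EGFR
  - ERBB2
  - ERBB4
  - FLT1
  - EPHA2
  - EPHB2
  - PDGFRA
PI3K:
  - PIK3CA
  - PIK3CD
  - PIK3R3
  - MTOR
histone_modifiers:
  - H3F3A
  - HIST1H3B
  - ATRX
  - ZMYND11
  - EP300
  - BCOR
integrin:
  - ITGA2
  - ITGB4
cadherin:
  - CDH1
  - CDH11
TP53_pathway:
  - TP53
  - PPM1D
other:
  - IDH1
  - ACVR1
  - BRAF
  - NF1
  - CDKN2A
  - LZTR1
  - MLH1
  - RAD50
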