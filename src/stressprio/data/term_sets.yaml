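# Default stress/attribute term-set seed accessions, one block per ontology
# group.  Each label lists the seed accessions verbatim as published; note
# some trait labels are annotated with GO accessions in the source table,
# so seeds are routed to the graph matching their prefix at load time.
GO:
  biological process: [GO:0009414]
  cellular component: [GO:0005575]
  molecular function: [GO:0003674]
TO:
  drought tolerance: [GO:0009414, GO:0009819]
  chlorophyll content: [TO:0000495]
  stay green trait: [TO:0002712]
  biochemical trait: [TO:0000277]
  leaf senescence: [TO:0000249, GO:0010150]
  growth and development trait: [TO:0000357]
EO:
  drought environment: [EO:0007404]
  sodium chloride regimen: [EO:0007048]
  salt regimen: [EO:0007185]
  watering regimen: [EO:0007383]
  cold temperature regimen: [EO:0007174]
PO:
  inflorescence: [PO:0009049]
  tassel inflorescence: [PO:0020126]
GRO:
  reproductive stage: [GRO:0007140]
  seedling stage: [GRO:0007047]
  booting stage: [GRO:0007148]
  early-booting stage: [GRO:0007149]
  late-booting stage: [GRO:0007150]
  flowering stage: [GRO:0007151]
  heading stage: [GRO:0007044]
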