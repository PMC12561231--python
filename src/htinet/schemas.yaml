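# Default metapath schema lists per anchor node type.
# Schemas are compact type strings; every schema starts and ends at the
# anchor type and has at most 5 nodes.
H:
  - HH
  - HTH
  - HIH
  - HEH
  - HTTH
  - HTHTH
  - HIIH
  - HEHEH
  - HTITH
  - HITIH
T:
  - TT
  - THT
  - TIT
  - THHT
  - TITIT
  - THTHT
  - THIHT
  - TIHIT
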