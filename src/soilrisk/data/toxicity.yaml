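# Toxicity reference values per element and exposure pathway.
# rfd: non-carcinogenic reference dose, mg/(kg d); sf: carcinogenic slope
# factor, (kg d)/mg. null = no value available (pathway contributes no risk).
# Conventional USEPA-derived values widely used for Chinese soils; editable.
rfd:
  Cr: {ingestion: 3.0e-3, dermal: 6.0e-5}
  Cd: {ingestion: 1.0e-3, dermal: 1.0e-5}
  As: {ingestion: 3.0e-4, dermal: 1.23e-4}
  Pb: {ingestion: 3.5e-3, dermal: 5.25e-4}
  Hg: {ingestion: 3.0e-4, dermal: 2.1e-5}
sf:
  Cr: {ingestion: 0.5, dermal: 20.0}
  Cd: {ingestion: 6.1, dermal: null}
  As: {ingestion: 1.5, dermal: 3.66}
  Pb: {ingestion: 8.5e-3, dermal: null}
  Hg: {ingestion: null, dermal: null}
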