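# Illustrative two-deme demography for neutral null simulations:
# a domesticate (strong bottleneck, N in the low thousands) splitting from
# its wild progenitor, with weak symmetric migration. Placeholder values
# for exploration — not a fitted model.
populations:
  - name: dog
    epochs:
      - {time: 0, size: 25000}
      - {time: 500, size: 2500}
  - name: wolf
    epochs:
      - {time: 0, size: 20000}
      - {time: 4500, size: 25000}
splits:
  - {time: 4500, derived: dog, ancestral: wolf}
migration:
  - time: 0
    rates:
      "dog>wolf": 1.0e-4
      "wolf>dog": 1.0e-4
mutation_rate: 1.0e-8
window_length: 500000
blocks: 50
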