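# Binary interaction parameters k_ij (verbatim from the published table).
kij:
  - {pair: [fenofibrate, hpmc], value: 0.01}
  - {pair: [fenofibrate, water], value: 0.0}
  - {pair: [hpmc, water], value: 0.08}
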