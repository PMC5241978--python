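name: symptom_totals
items: [positive_total, negative_total]
domains:
  positive: [positive_total]
  negative: [negative_total]
item_range: [0, 49]
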