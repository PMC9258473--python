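{
  "name": "fixed_mindset",
  "item_labels": ["intelligence_cant_change", "cant_change_smartness", "talent_is_fixed"],
  "response_range": [1, 6],
  "reverse_coded": [],
  "aggregation": "unweighted_mean"
}
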