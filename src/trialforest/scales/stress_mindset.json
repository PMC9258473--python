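{
  "name": "stress_mindset",
  "item_labels": ["stress_effect_negative", "stress_depletes", "stress_debilitates", "stress_should_be_avoided"],
  "response_range": [1, 6],
  "reverse_coded": [],
  "aggregation": "unweighted_mean"
}
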