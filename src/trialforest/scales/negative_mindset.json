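{
  "name": "negative_mindset",
  "item_labels": ["stress_stops_learning", "stress_effects_bad", "avoid_stress", "stress_harms_me"],
  "response_range": [1, 6],
  "reverse_coded": [],
  "aggregation": "unweighted_mean"
}
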