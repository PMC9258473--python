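{
  "name": "appraisal_index",
  "item_labels": ["stress_hurt_performance", "stress_helped_performance"],
  "response_range": [1, 5],
  "reverse_coded": ["stress_helped_performance"],
  "aggregation": "unweighted_mean"
}
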