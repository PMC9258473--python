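{
  "name": "wellbeing",
  "item_labels": ["felt_good_about_self", "felt_liked", "felt_powerful", "self_esteem_high", "felt_disconnected", "felt_rejected", "felt_insecure"],
  "response_range": [1, 7],
  "reverse_coded": ["felt_disconnected", "felt_rejected", "felt_insecure"],
  "aggregation": "unweighted_mean"
}
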