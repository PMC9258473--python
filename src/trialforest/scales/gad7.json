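{
  "name": "gad7",
  "item_labels": ["nervous", "cant_stop_worrying", "worry_too_much", "trouble_relaxing", "restless", "irritable", "afraid"],
  "response_range": [0, 3],
  "reverse_coded": [],
  "aggregation": "sum"
}
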