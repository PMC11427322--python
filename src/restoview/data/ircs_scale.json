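{
  "name": "IRCS",
  "response_range": [1, 5],
  "items": [
    {"item_id": "BA1", "subscale": "BeingAway", "reverse": false},
    {"item_id": "BA2", "subscale": "BeingAway", "reverse": false},
    {"item_id": "BA3", "subscale": "BeingAway", "reverse": false},
    {"item_id": "BA4", "subscale": "BeingAway", "reverse": false},
    {"item_id": "FS1", "subscale": "Fascination", "reverse": false},
    {"item_id": "FS2", "subscale": "Fascination", "reverse": false},
    {"item_id": "FS3", "subscale": "Fascination", "reverse": false},
    {"item_id": "FS4", "subscale": "Fascination", "reverse": false},
    {"item_id": "EX1", "subscale": "Extent", "reverse": false},
    {"item_id": "EX2", "subscale": "Extent", "reverse": true},
    {"item_id": "EX3", "subscale": "Extent", "reverse": true}
  ]
}
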