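{
  "test_ids": [2, 4, 9, 20, 22, 27, 30]
}
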