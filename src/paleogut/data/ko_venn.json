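{
  "universe": 1487,
  "shared_all": 117,
  "brs_unique": 72
}
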