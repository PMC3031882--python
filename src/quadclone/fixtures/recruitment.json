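{
  "recruited": 19,
  "dropped_single_timepoint": 6,
  "no_chemo_rt": 3
}
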