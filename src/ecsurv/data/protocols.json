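{
  "CROSS": [3, 6, 9, 12, 18, 24, 36, 48, 60],
  "NEOCRT5010": [3, 6, 9, 12, 18, 24, 30, 36, 42, 48, 54, 60],
  "NCCN": [3, 6, 9, 12, 15, 18, 21, 24, 30, 36, 42, 48, 54, 60],
  "NCT1596": [1, 4, 7, 10, 13, 16, 19, 22, 30, 36, 42, 48, 54, 60]
}
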