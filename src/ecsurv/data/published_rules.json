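[
  {"group": "IV",  "all": [{"covariate": "pN", "op": "==", "value": 3}]},
  {"group": "III", "all": [{"covariate": "pN", "op": "==", "value": 2}]},
  {"group": "III", "all": [{"covariate": "pN", "op": "==", "value": 1},
                            {"covariate": "lnr", "op": ">", "value": 0.05}]},
  {"group": "II",  "all": [{"covariate": "pN", "op": "==", "value": 1},
                            {"covariate": "lnr", "op": "<=", "value": 0.05}]},
  {"group": "II",  "all": [{"covariate": "pN", "op": "==", "value": 0},
                            {"covariate": "lvi", "op": "==", "value": 1}]},
  {"group": "II",  "all": [{"covariate": "pN", "op": "==", "value": 0},
                            {"covariate": "pni", "op": "==", "value": 1}]},
  {"group": "I",   "all": [{"covariate": "pN", "op": "==", "value": 0}]}
]
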