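{
  "background":  {"id": 0, "r1": 0.0,  "pd": 0.0,     "mtsat": 0.0,   "r2star": 0.0},
  "CSF":         {"id": 1, "r1": 0.23, "pd": 20000.0, "mtsat": 0.0,   "r2star": 4.0},
  "cortical_GM": {"id": 2, "r1": 0.65, "pd": 16000.0, "mtsat": 0.012, "r2star": 35.0},
  "WM":          {"id": 3, "r1": 1.0,  "pd": 13000.0, "mtsat": 0.025, "r2star": 45.0},
  "thalamus":    {"id": 4, "r1": 0.75, "pd": 15500.0, "mtsat": 0.016, "r2star": 40.0},
  "putamen":     {"id": 5, "r1": 0.78, "pd": 15200.0, "mtsat": 0.014, "r2star": 55.0}
}
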