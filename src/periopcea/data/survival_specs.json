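{
  "pembrolizumab": {
    "os": {"family": "lognormal", "params": {"meanlog": 5.023, "sdlog": 2.074}, "time_unit": "months"},
    "efs": {"family": "gengamma", "params": {"mu": 2.866, "sigma": 1.951, "Q": -1.399}, "time_unit": "months"}
  },
  "placebo": {
    "os": {"family": "weibull", "params": {"shape": 1.232, "scale": 70.275}, "time_unit": "months"},
    "efs": {"family": "gengamma", "params": {"mu": 2.677, "sigma": 1.316, "Q": -0.498}, "time_unit": "months"}
  }
}
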