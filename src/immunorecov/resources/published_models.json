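{
  "version": 1,
  "description": "Published three-predictor logistic models for PIR/AIR outcome. P(PIR) = 1 / (1 + exp(a + b*x1 + c*x2 + d*x3)); the linear predictor is on the AIR scale (outcome coded Y=1 for AIR). Units: age in years, viral load in log10 copies/mL, CD4 counts in cells/uL, RTE in percent of CD4+ T cells, CD4 slope in cells/uL/month.",
  "models": {
    "1": {
      "name": "Model 1",
      "n": 31,
      "a": -8.670,
      "b": -0.102,
      "c": 1.985,
      "d": 0.105,
      "predictors": ["age_years", "log10_vl_baseline", "rte_pct_6mo"]
    },
    "2": {
      "name": "Model 2",
      "n": 30,
      "a": -15.182,
      "b": 2.519,
      "c": 0.133,
      "d": -2.179,
      "predictors": ["log10_vl_baseline", "cd4_slope_0_6", "rte_ratio_0_6"]
    },
    "3": {
      "name": "Model 3",
      "n": 33,
      "a": -9.703,
      "b": -0.103,
      "c": 1.897,
      "d": 0.013,
      "predictors": ["age_years", "log10_vl_baseline", "cd4_count_6mo"]
    },
    "4": {
      "name": "Model 4",
      "n": 31,
      "a": -10.971,
      "b": -0.160,
      "c": 2.610,
      "d": 0.012,
      "predictors": ["age_years", "log10_vl_baseline", "cd4_count_2mo"]
    }
  }
}
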