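{
  "overall": {
    "outcome": "overall",
    "intercept": 2.910,
    "coefficients": {
      "sqrt_greenery": 0.010,
      "geom_fractal_brightness_large": 0.035,
      "stat_fractal_brightness_large": 0.033,
      "color_fractal": -0.121
    },
    "rmse_train": 0.231,
    "rmse_test": 0.256
  },
  "being_away": {
    "outcome": "being_away",
    "intercept": 2.972,
    "coefficients": {
      "sqrt_greenery": 0.114,
      "geom_fractal_brightness_large": 0.005,
      "color_fractal": -0.106
    },
    "rmse_train": 0.247,
    "rmse_test": 0.241
  },
  "fascination": {
    "outcome": "fascination",
    "intercept": 2.822,
    "coefficients": {
      "sqrt_greenery": 0.099,
      "geom_fractal_brightness_large": 0.005,
      "stat_fractal_brightness_large": 0.062,
      "color_fractal": -0.101
    },
    "rmse_train": 0.216,
    "rmse_test": 0.245
  },
  "extent": {
    "outcome": "extent",
    "intercept": 2.928,
    "coefficients": {},
    "rmse_train": 0.437,
    "rmse_test": 0.420
  }
}
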