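{
  "version": 1,
  "description": "Built-in multinomial logistic coefficients of the eye-regularity classifier. Rows are degeneration classes 0-3 expressed relative to reference class 4 (fully degenerate, implicit all-zero row). Columns: intercept, distm, distskew, lognnvar. Features are on the development scale: distances in units of the 1.85 um reference pixel pitch.",
  "feature_names": ["distm", "distskew", "lognnvar"],
  "reference_class": 4,
  "coefficients": {
    "0": {"independent": 84.366, "distm": -13.681, "distskew": 20.391, "lognnvar": -17.321},
    "1": {"independent": 60.004, "distm": -11.097, "distskew": 15.005, "lognnvar": -6.976},
    "2": {"independent": 29.07,  "distm": -4.448,  "distskew": 7.663,  "lognnvar": -3.308},
    "3": {"independent": 1.299,  "distm": 0.242,   "distskew": -17.746, "lognnvar": -0.104}
  }
}
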