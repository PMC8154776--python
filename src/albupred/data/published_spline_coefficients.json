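{
  "description": "Published 4-knot linear-spline coefficient sets estimating ln(median uACR, mg/gCr) from ln(uPCR, mg/gCr) in adults with lifestyle-related disease and uPCR < 0.5 g/gCr. Knots at uPCR 20, 60, 120, 350 mg/gCr (percentiles 5/35/65/95 of 846 measurements). Segment bounds are [lo, hi) in mg/gCr; the model domain extends to 500 mg/gCr inclusive.",
  "knots_mg_per_gcr": [20, 60, 120, 350],
  "domain_mg_per_gcr": [1, 500],
  "populations": {
    "all": {
      "label": "non-diabetes and diabetes",
      "segments": [
        {"lo": 0, "hi": 20, "intercept": 1.2232, "slope": 0.3719},
        {"lo": 20, "hi": 60, "intercept": 0.4727, "slope": 0.6224},
        {"lo": 60, "hi": 120, "intercept": -3.3183, "slope": 1.5483},
        {"lo": 120, "hi": 350, "intercept": -1.4229, "slope": 1.1524},
        {"lo": 350, "hi": 500, "intercept": -0.6880, "slope": 1.0269}
      ]
    },
    "non_diabetic": {
      "label": "non-diabetes",
      "segments": [
        {"lo": 0, "hi": 20, "intercept": 1.4345, "slope": 0.2801},
        {"lo": 20, "hi": 60, "intercept": 0.2352, "slope": 0.6804},
        {"lo": 60, "hi": 120, "intercept": -3.7678, "slope": 1.6581},
        {"lo": 120, "hi": 350, "intercept": -1.2878, "slope": 1.1401},
        {"lo": 350, "hi": 500, "intercept": -0.4592, "slope": 0.9986}
      ]
    },
    "diabetic": {
      "label": "diabetes",
      "segments": [
        {"lo": 0, "hi": 20, "intercept": 1.5706, "slope": 0.2210},
        {"lo": 20, "hi": 60, "intercept": -0.2471, "slope": 0.8277},
        {"lo": 60, "hi": 120, "intercept": -1.7535, "slope": 1.1957},
        {"lo": 120, "hi": 350, "intercept": -0.9770, "slope": 1.0335},
        {"lo": 350, "hi": 500, "intercept": -5.5472, "slope": 1.8136}
      ]
    }
  }
}
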