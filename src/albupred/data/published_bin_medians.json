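{
  "description": "Published binned association of uPCR (g/gCr, 0.01 bins) with median uACR (mg/gCr) and its IQR, by population, in adults with lifestyle-related disease.",
  "bin_width_g_per_gcr": 0.01,
  "populations": {
    "all": [
      {"upcr": 0.01, "n": 41, "median": 8.0, "q1": 6.0, "q3": 15.0},
      {"upcr": 0.02, "n": 58, "median": 10.5, "q1": 7.0, "q3": 15.0},
      {"upcr": 0.03, "n": 67, "median": 11.0, "q1": 7.0, "q3": 17.0},
      {"upcr": 0.04, "n": 64, "median": 16.0, "q1": 10.0, "q3": 28.0},
      {"upcr": 0.05, "n": 58, "median": 17.5, "q1": 10.3, "q3": 29.0},
      {"upcr": 0.06, "n": 65, "median": 21.0, "q1": 12.0, "q3": 37.0},
      {"upcr": 0.07, "n": 56, "median": 29.5, "q1": 13.0, "q3": 41.0},
      {"upcr": 0.08, "n": 36, "median": 26.0, "q1": 18.0, "q3": 53.3},
      {"upcr": 0.09, "n": 40, "median": 39.0, "q1": 24.8, "q3": 57.3},
      {"upcr": 0.10, "n": 28, "median": 51.0, "q1": 35.8, "q3": 63.0},
      {"upcr": 0.11, "n": 26, "median": 60.5, "q1": 44.3, "q3": 73.5},
      {"upcr": 0.12, "n": 29, "median": 57.0, "q1": 34.0, "q3": 78.0},
      {"upcr": 0.13, "n": 23, "median": 71.0, "q1": 55.0, "q3": 92.0},
      {"upcr": 0.14, "n": 27, "median": 67.0, "q1": 40.0, "q3": 88.0},
      {"upcr": 0.15, "n": 25, "median": 71.0, "q1": 48.0, "q3": 104.0},
      {"upcr": 0.16, "n": 25, "median": 95.0, "q1": 53.0, "q3": 120.0}
    ],
    "non_diabetic": [
      {"upcr": 0.01, "n": 24, "median": 8.0, "q1": 5.8, "q3": 12.5},
      {"upcr": 0.02, "n": 35, "median": 8.0, "q1": 6.0, "q3": 15.5},
      {"upcr": 0.03, "n": 42, "median": 12.0, "q1": 8.3, "q3": 17.0},
      {"upcr": 0.04, "n": 39, "median": 19.0, "q1": 9.0, "q3": 32.0},
      {"upcr": 0.05, "n": 35, "median": 18.0, "q1": 10.5, "q3": 27.0},
      {"upcr": 0.06, "n": 43, "median": 19.0, "q1": 11.5, "q3": 36.5},
      {"upcr": 0.07, "n": 37, "median": 28.0, "q1": 12.0, "q3": 35.0},
      {"upcr": 0.08, "n": 25, "median": 25.0, "q1": 14.0, "q3": 53.0},
      {"upcr": 0.09, "n": 27, "median": 43.0, "q1": 25.0, "q3": 57.5},
      {"upcr": 0.10, "n": 22, "median": 48.0, "q1": 36.5, "q3": 58.8},
      {"upcr": 0.11, "n": 16, "median": 68.0, "q1": 58.3, "q3": 77.3},
      {"upcr": 0.12, "n": 18, "median": 59.0, "q1": 46.3, "q3": 79.3},
      {"upcr": 0.13, "n": 13, "median": 79.0, "q1": 55.0, "q3": 101.0},
      {"upcr": 0.14, "n": 18, "median": 78.5, "q1": 39.0, "q3": 104.3},
      {"upcr": 0.15, "n": 18, "median": 72.5, "q1": 50.3, "q3": 104.8},
      {"upcr": 0.16, "n": 13, "median": 116.0, "q1": 79.0, "q3": 133.0}
    ],
    "diabetic": [
      {"upcr": 0.01, "n": 17, "median": 8.0, "q1": 6.0, "q3": 20.0},
      {"upcr": 0.02, "n": 23, "median": 12.0, "q1": 8.5, "q3": 13.5},
      {"upcr": 0.03, "n": 25, "median": 11.0, "q1": 6.0, "q3": 18.0},
      {"upcr": 0.04, "n": 25, "median": 12.0, "q1": 10.0, "q3": 27.0},
      {"upcr": 0.05, "n": 23, "median": 17.0, "q1": 11.0, "q3": 27.5},
      {"upcr": 0.06, "n": 22, "median": 25.0, "q1": 14.0, "q3": 36.8},
      {"upcr": 0.07, "n": 19, "median": 41.0, "q1": 25.0, "q3": 47.0},
      {"upcr": 0.08, "n": 11, "median": 32.0, "q1": 22.0, "q3": 45.5},
      {"upcr": 0.09, "n": 13, "median": 32.0, "q1": 23.0, "q3": 43.0},
      {"upcr": 0.10, "n": 6, "median": 63.0, "q1": 42.0, "q3": 66.8},
      {"upcr": 0.11, "n": 10, "median": 46.0, "q1": 42.3, "q3": 54.8},
      {"upcr": 0.12, "n": 11, "median": 52.0, "q1": 32.5, "q3": 71.5},
      {"upcr": 0.13, "n": 10, "median": 64.0, "q1": 55.8, "q3": 77.8},
      {"upcr": 0.14, "n": 9, "median": 51.0, "q1": 48.0, "q3": 74.0},
      {"upcr": 0.15, "n": 7, "median": 69.0, "q1": 52.5, "q3": 88.0},
      {"upcr": 0.16, "n": 12, "median": 80.0, "q1": 51.8, "q3": 98.5}
    ]
  }
}
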