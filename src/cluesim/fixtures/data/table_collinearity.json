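{
  "_comment": "Published multicollinearity diagnostics of the seven driving factors (Weishan mining-area calibration): tolerance = 1 - R2 of each driver regressed on the others, VIF its reciprocal. All tolerances exceed the 0.1 critical value and all VIFs stay below 5.",
  "tolerance": {
    "dist_residential": 0.563,
    "dist_mines": 0.351,
    "dist_roads": 0.228,
    "dist_rivers": 0.207,
    "dist_ditches": 0.329,
    "elevation": 0.888,
    "slope": 0.874
  },
  "vif": {
    "dist_residential": 1.777,
    "dist_mines": 2.846,
    "dist_roads": 4.387,
    "dist_rivers": 4.833,
    "dist_ditches": 3.037,
    "elevation": 1.126,
    "slope": 1.144
  }
}
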