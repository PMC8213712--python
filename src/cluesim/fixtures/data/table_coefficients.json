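{
  "_comment": "Published logistic regression coefficients (standardized drivers) for the six-class Weishan mining-area calibration. Drivers absent for a class were excluded from that class's model (structural zero). The slope row of the printed source is typographically ambiguous; the subsided-seeper and water-area slope entries are marked uncertain.",
  "driver_order": [
    "dist_residential",
    "dist_mines",
    "dist_roads",
    "dist_rivers",
    "dist_ditches",
    "elevation",
    "slope"
  ],
  "classes": {
    "1": {
      "name": "farmland",
      "intercept": -0.009,
      "coefficients": {
        "dist_residential": -0.974,
        "dist_roads": 0.894,
        "dist_rivers": -1.769,
        "dist_ditches": 1.588,
        "elevation": -0.19,
        "slope": -0.136
      }
    },
    "2": {
      "name": "other agricultural land",
      "intercept": -1.284,
      "coefficients": {
        "dist_residential": 0.136,
        "dist_mines": 0.316,
        "dist_roads": -0.101,
        "dist_rivers": -0.738,
        "dist_ditches": 0.655,
        "elevation": 0.045,
        "slope": 0.104
      }
    },
    "3": {
      "name": "urban and rural construction land",
      "intercept": -5.483,
      "coefficients": {
        "dist_residential": -3.282,
        "dist_mines": -1.112,
        "dist_roads": -0.216,
        "dist_ditches": 0.207,
        "elevation": 0.044,
        "slope": -0.057
      }
    },
    "4": {
      "name": "subsided seeper area",
      "intercept": -8.94,
      "coefficients": {
        "dist_residential": 1.197,
        "dist_mines": -5.813,
        "dist_roads": -0.833,
        "dist_rivers": -1.562,
        "dist_ditches": 0.481,
        "elevation": 0.571
      }
    },
    "5": {
      "name": "water area",
      "intercept": -1.779,
      "coefficients": {
        "dist_residential": 1.564,
        "dist_mines": -0.419,
        "dist_roads": -1.221,
        "dist_rivers": 3.396,
        "dist_ditches": -3.337,
        "elevation": 0.214,
        "slope": 0.051
      }
    },
    "6": {
      "name": "tidal wetland",
      "intercept": -4.237,
      "coefficients": {
        "dist_residential": 0.562,
        "dist_mines": 1.274,
        "dist_roads": -0.603,
        "dist_ditches": -2.287,
        "elevation": 0.225,
        "slope": 0.275
      }
    }
  },
  "uncertain": [
    ["4", "slope"],
    ["5", "slope"]
  ]
}
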