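{
  "version": "1.0",
  "provenance": "Published 21-patient hydrogel-spacer rectal dose-reduction study (60 Gy / 20 fx VMAT); coefficients and statistics transcribed verbatim.",
  "n": 21,
  "models": {
    "delta_rv55_model1": {
      "dependent": "delta_rv55_pct",
      "intercept": {"est": -4.26, "se": 4.09},
      "terms": [
        {"name": "norm_rinptv_pct", "beta": 1.25, "se": 0.18, "rs2": 0.97},
        {"name": "rw_to_ctv_cm", "beta": 0.23, "se": 0.17, "rs2": 0.38},
        {"name": "rectum_vol_cc", "beta": -0.0077, "se": 0.0101, "rs2": 0.18}
      ],
      "r_squared": 0.83,
      "predicted_r_squared": 0.63,
      "mae": 1.29,
      "pct_mae": 12.90,
      "p_value_upper": 0.0001,
      "note": "Shipped verbatim; evaluating these printed coefficients at the cohort means does not reproduce the cohort-mean endpoint (the RWtoCTV coefficient is inconsistent with the OLS centroid identity as printed). Use with caution."
    },
    "delta_rv55_model2": {
      "dependent": "delta_rv55_pct",
      "intercept": {"est": 0.73, "se": 0.51},
      "terms": [
        {"name": "norm_rinptv_pct", "beta": 1.10, "se": 0.12, "rs2": 1.00}
      ],
      "r_squared": 0.81,
      "predicted_r_squared": 0.76,
      "mae": 0.96,
      "pct_mae": 9.60,
      "p_value_upper": 0.0001
    },
    "pre_rv55_model1": {
      "dependent": "pre_rv55_pct",
      "intercept": {"est": -0.45, "se": 1.10},
      "terms": [
        {"name": "norm_rinptv_pct", "beta": 1.19, "se": 0.20, "rs2": 0.97},
        {"name": "norm_ctv_pct", "beta": 0.012, "se": 0.007, "rs2": 0.12},
        {"name": "rw_to_ctv_inv_cubed", "beta": 13.88, "se": 11.4, "rs2": 0.33}
      ],
      "r_squared": 0.88,
      "predicted_r_squared": 0.76,
      "mae": 1.48,
      "pct_mae": 11.62,
      "p_value_upper": 0.0001
    },
    "pre_rv55_model2": {
      "dependent": "pre_rv55_pct",
      "intercept": {"est": 0.67, "se": 0.61},
      "terms": [
        {"name": "norm_rinptv_pct", "beta": 1.37, "se": 0.13, "rs2": 0.98},
        {"name": "norm_ctv_pct", "beta": 0.009, "se": 0.006, "rs2": 0.12}
      ],
      "r_squared": 0.87,
      "predicted_r_squared": 0.79,
      "mae": 1.35,
      "pct_mae": 10.65,
      "p_value_upper": 0.0001
    }
  },
  "pearson": {
    "delta_rv55_pct": {
      "rectum_vol_cc": -0.38,
      "rw_vol_cc": -0.37,
      "rinptv_cc": 0.68,
      "norm_rinptv_pct": 0.90,
      "ctv_vol_cc": 0.22,
      "norm_ctv_pct": 0.29,
      "rw_to_ctv_cm": -0.56,
      "rw_to_ctv_inv_cubed": 0.33
    },
    "pre_rv55_pct": {
      "rectum_vol_cc": -0.33,
      "rw_vol_cc": -0.32,
      "rinptv_cc": 0.76,
      "norm_rinptv_pct": 0.92,
      "ctv_vol_cc": 0.27,
      "norm_ctv_pct": 0.32,
      "rw_to_ctv_cm": -0.61,
      "rw_to_ctv_inv_cubed": 0.54
    }
  },
  "endpoint_summary": {
    "delta_rv55_pct": {"mean": 4.5, "sd": 3.0, "min": 0.8, "max": 10.8},
    "pre_rv55_pct": {"mean": 5.9, "sd": 3.7, "min": 0.8, "max": 13.5}
  },
  "feature_summary": {
    "rectum_vol_cc": {"mean": 79.2, "sd": 32.1, "min": 35.5, "max": 149.7},
    "rw_vol_cc": {"mean": 35.5, "sd": 9.7, "min": 20.5, "max": 57.8},
    "ctv_vol_cc": {"mean": 39.9, "sd": 17.2, "min": 24.6, "max": 91.5},
    "norm_ctv_pct": {"mean": 62.3, "sd": 51.7, "min": 19.6, "max": 257.7},
    "rinptv_cc": {"mean": 2.4, "sd": 1.5, "min": 0.1, "max": 5.3},
    "norm_rinptv_pct": {"mean": 3.4, "sd": 2.4, "min": 0.2, "max": 10.4},
    "rw_to_ctv_cm": {"mean": 2.18, "sd": 0.26, "min": 1.71, "max": 2.63},
    "rw_to_ctv_cubed_cc": {"mean": 10.36, "sd": 4.06, "min": 4.99, "max": 18.21}
  }
}
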