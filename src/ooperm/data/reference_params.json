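{
  "_comment": "Published reference permeability values for X. laevis oocytes expressing aquaporin constructs; used as generating parameters for synthetic benchmarks. Lp in um/(min*atm); Ps (ethylene glycol) in cm/min. sigma values were not published; the 'sigma_assumed' entries are benchmark conventions, not measurements.",
  "sucrose_lp": {
    "water": {"lp_2min": 1.40, "lp_10min": 0.69},
    "DrAqp3b-WT": {"lp_2min": 2.15, "lp_10min": 0.89},
    "DrAqp3b-H53A/G54H/T85A": {"lp_2min": 1.94, "lp_10min": 0.88},
    "DrAqp3b-T85A": {"lp_2min": 2.57, "lp_10min": 1.02},
    "HsAQP3": {"lp_2min": 1.93, "lp_10min": 0.87}
  },
  "ethylene_glycol": {
    "water": {"Lp": 0.36, "Ps": 0.00047, "sigma_assumed": 0.9},
    "DrAqp3b-WT (1 ng)": {"Lp": 2.15, "Ps": 0.01759, "sigma_assumed": 0.8},
    "DrAqp3b-H53A/G54H/T85A (1 ng)": {"Lp": 1.55, "Ps": 0.01306, "sigma_assumed": 0.8},
    "DrAqp3b-T85A (1 ng)": {"Lp": 2.64, "Ps": 0.02549, "sigma_assumed": 0.8},
    "HsAQP3 (1 ng)": {"Lp": 1.31, "Ps": 0.01073, "sigma_assumed": 0.8},
    "DrAqp3b-WT (20 ng)": {"Lp": 2.63, "Ps": 0.04006, "sigma_assumed": 0.8},
    "DrAqp3b-H53A/G54H/T85A (20 ng)": {"Lp": 2.27, "Ps": 0.03658, "sigma_assumed": 0.8},
    "DrAqp3b-T85A (20 ng)": {"Lp": 3.24, "Ps": 0.05391, "sigma_assumed": 0.8},
    "HsAQP3 (20 ng)": {"Lp": 1.96, "Ps": 0.02224, "sigma_assumed": 0.8}
  }
}
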