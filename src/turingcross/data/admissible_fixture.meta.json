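{
  "d_star_A": 65.10287350229919,
  "d_star_B": 205.2246510758996,
  "d_star_F1": 37.564407436177135,
  "d_used": 49.45251121536971,
  "margin": 0.03,
  "procedure": "search_admissible + 9-genotype margin screen",
  "search_seed": 30,
  "sigma_max_by_genotype": {
    "U:AA,V:AA": -0.04254974499774633,
    "U:AA,V:AB": 0.22127937916543772,
    "U:AA,V:BB": -1.055160909169631,
    "U:AB,V:AA": -0.48639606644703953,
    "U:AB,V:AB": 0.04643691699917518,
    "U:AB,V:BB": -1.006659507170293,
    "U:BB,V:AA": -0.05800416864275171,
    "U:BB,V:AB": -0.14467887984298322,
    "U:BB,V:BB": -0.20434955478119576
  },
  "try_index": 30
}
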