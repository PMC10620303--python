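{
  "d_star_F1": 7.365225623128936,
  "d_star_parent": 14.414755889680237,
  "d_used": 10.303782287578752,
  "m_vu": 0.3,
  "parent_kappa": {
    "uu": 1.117041709183327,
    "uv": 3.097437600083355,
    "vu": 0.75053694836738,
    "vv": 0.19154618335025128
  },
  "parent_rates": {
    "u": {
      "alpha": 0.024265498969014233,
      "beta": 0.4082029468594586,
      "gamma": 22.97739595808255
    },
    "v": {
      "alpha": 0.01381485984644087,
      "beta": 0.16704722428014107,
      "gamma": 5.240844853744937
    }
  },
  "procedure": "symmetric stream search + monotone sweep screen",
  "stream_seed": 7,
  "trial": 73
}
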