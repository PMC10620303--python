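{
  "D_u": 0.5852704937901213,
  "D_v": 6.030499747357122,
  "kappa": {
    "uu_AA": 1.117041709183327,
    "uu_AB": 1.117041709183327,
    "uu_BA": 1.117041709183327,
    "uu_BB": 1.117041709183327,
    "uv_AA": 3.097437600083355,
    "uv_AB": 3.097437600083355,
    "uv_BA": 3.097437600083355,
    "uv_BB": 3.097437600083355,
    "vu_AA": 0.75053694836738,
    "vu_AB": 0.225161084510214,
    "vu_BA": 0.225161084510214,
    "vu_BB": 0.75053694836738,
    "vv_AA": 0.19154618335025128,
    "vv_AB": 0.19154618335025128,
    "vv_BA": 0.19154618335025128,
    "vv_BB": 0.19154618335025128
  },
  "rates": {
    "u_A": {
      "alpha": 0.024265498969014233,
      "beta": 0.4082029468594586,
      "gamma": 22.97739595808255
    },
    "u_B": {
      "alpha": 0.024265498969014233,
      "beta": 0.4082029468594586,
      "gamma": 22.97739595808255
    },
    "v_A": {
      "alpha": 0.01381485984644087,
      "beta": 0.16704722428014107,
      "gamma": 5.240844853744937
    },
    "v_B": {
      "alpha": 0.01381485984644087,
      "beta": 0.16704722428014107,
      "gamma": 5.240844853744937
    }
  }
}
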