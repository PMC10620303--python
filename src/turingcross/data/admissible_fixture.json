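{
  "D_u": 1.0075105331916796,
  "D_v": 49.82392594226465,
  "kappa": {
    "uu_AA": 2.4109958586260993,
    "uu_AB": 0.4942529257792154,
    "uu_BA": 0.23325311438216012,
    "uu_BB": 0.9011264597739125,
    "uv_AA": 7.9569530898425205,
    "uv_AB": 2.7971121689729967,
    "uv_BA": 0.8684371920673339,
    "uv_BB": 8.565548101457653,
    "vu_AA": 0.8127880637179272,
    "vu_AB": 0.3235418721701368,
    "vu_BA": 0.06553711737877027,
    "vu_BB": 0.1162215433375438,
    "vv_AA": 0.5170130581509974,
    "vv_AB": 0.0727290777578911,
    "vv_BA": 0.028132577850278267,
    "vv_BB": 0.21518027901191397
  },
  "rates": {
    "u_A": {
      "alpha": 0.06708491888177984,
      "beta": 1.296515588130185,
      "gamma": 22.00050852563678
    },
    "u_B": {
      "alpha": 0.17539173334507474,
      "beta": 1.9035905886088782,
      "gamma": 8.324879281055138
    },
    "v_A": {
      "alpha": 0.13982669705818832,
      "beta": 1.0118038793146293,
      "gamma": 17.11025348507613
    },
    "v_B": {
      "alpha": 0.013147832476540638,
      "beta": 1.4774680389770123,
      "gamma": 13.776223277229128
    }
  }
}
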