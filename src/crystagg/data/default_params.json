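{
  "rates": {
    "k_mis": 0.002,
    "k_fold": 0.00413,
    "k_ox": 0.0251,
    "k_red": 0.005127,
    "k_dim": 1.07e-05,
    "k_diss": 0.01,
    "k_elong": 0.000186,
    "k_coal": 0.0002,
    "k_settle": 0.0002,
    "K_I": 46.6136,
    "w_P": 0.01,
    "w_G": 0.02,
    "dim_oxidizes": true,
    "inhibit_coal": false
  }
}
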