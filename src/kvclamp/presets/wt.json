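{
  "name": "wt",
  "g0": 0.02,
  "act_v_half": 5.0,
  "act_k": 8.0,
  "tau_act": 1.0,
  "tau_deact": 3.0,
  "inact_v_half_ref": -35.0,
  "inact_k": 5.0,
  "inact_floor": 0.05,
  "tau_inact_1": 250.0,
  "tau_inact_2": 80.0,
  "a1_frac": 0.3,
  "persistent_frac": 0.05,
  "tau_rec_ref": 1000.0,
  "k_shift_delta": 6.0,
  "k_rec_gamma": 0.5,
  "k_gain_alpha": 0.35,
  "source": {
    "g0": "calibrated",
    "act_v_half": "calibrated",
    "act_k": "calibrated",
    "tau_act": "calibrated",
    "tau_deact": "calibrated",
    "inact_v_half_ref": "calibrated",
    "inact_k": "calibrated",
    "inact_floor": "calibrated",
    "tau_inact_1": "calibrated",
    "tau_inact_2": "calibrated",
    "a1_frac": "calibrated",
    "persistent_frac": "calibrated",
    "tau_rec_ref": "calibrated",
    "k_shift_delta": "calibrated",
    "k_rec_gamma": "calibrated",
    "k_gain_alpha": "calibrated"
  }
}
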