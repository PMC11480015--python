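{
  "name": "e675k",
  "g0": 0.014,
  "act_v_half": 5.0,
  "act_k": 8.0,
  "tau_act": 1.0,
  "tau_deact": 3.0,
  "inact_v_half_ref": -35.0,
  "inact_k": 5.0,
  "inact_floor": 0.02,
  "tau_inact_1": 250.0,
  "tau_inact_2": 80.0,
  "a1_frac": 0.3,
  "persistent_frac": 0.05,
  "tau_rec_ref": 1500.0,
  "k_shift_delta": 6.0,
  "k_rec_gamma": 0.5,
  "k_gain_alpha": 0.35,
  "source": {
    "g0": "reported: ~30% peak-amplitude reduction vs wild-type",
    "inact_floor": "calibrated: more complete cumulative inactivation",
    "tau_rec_ref": "calibrated: deeper frequency-dependent inactivation",
    "act_v_half": "reported: unchanged vs wild-type",
    "act_k": "reported: unchanged vs wild-type",
    "inact_v_half_ref": "reported: unchanged vs wild-type",
    "inact_k": "reported: unchanged vs wild-type",
    "tau_act": "calibrated",
    "tau_deact": "calibrated",
    "tau_inact_1": "calibrated",
    "tau_inact_2": "calibrated",
    "a1_frac": "calibrated",
    "persistent_frac": "calibrated",
    "k_shift_delta": "calibrated",
    "k_rec_gamma": "calibrated",
    "k_gain_alpha": "calibrated"
  }
}
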