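{
  "kb_er_syn": 0.05,
  "ki_er_syn": 0.5,
  "K_er_syn": 0.3,
  "kdeg_er": 0.2,
  "k_er_act": 1.0,
  "kdeg_era": 0.5,
  "k_egfr_phos_egf": 10.0,
  "k_egfr_phos_er": 5.0,
  "K_egfr_phos": 0.5,
  "kdeph_egfr": 5.0,
  "k_erk_phos": 20.0,
  "K_erk_phos": 0.5,
  "kdeph_erk": 2.0,
  "k_pip3_prod": 1.0,
  "kdeg_pip3": 0.05,
  "k_pip3_rem": 2.0,
  "K_pip3_rem": 0.5,
  "k_akt_phos": 10.0,
  "K_akt_phos": 0.5,
  "kdeph_akt": 2.0,
  "k_pten_syn": 0.04,
  "K_pten_syn": 0.6,
  "n_pten": 2.0,
  "kdeg_pten": 0.04,
  "kb_notch_syn": 0.02,
  "ki_notch_syn": 0.3,
  "K_notch_syn": 0.5,
  "kdeg_notch": 0.02,
  "k_notch_cleave": 2.0,
  "kdeg_nicd": 0.8,
  "kb_hes_syn": 0.01,
  "ki_hes_syn": 1.0,
  "K_hes_syn": 0.5,
  "kdeg_hes1": 0.3,
  "k_gsk_phos_akt": 0.12,
  "k_gsk_phos_erk": 0.12,
  "K_gsk_phos": 0.5,
  "kdeph_gsk": 1.0,
  "kb_bcat_syn": 0.1,
  "ki_bcat_syn": 0.5,
  "K_bcat_syn": 0.3,
  "k_bcat_deg": 0.5,
  "K_bcat_deg": 0.5,
  "kdeg_bcat_basal": 0.05,
  "Ki_gef": 1.0,
  "Ki_ful": 0.1
}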