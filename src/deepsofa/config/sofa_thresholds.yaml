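# SOFA component thresholds: a transcription of the original Sequential
# Organ Failure Assessment definition (Vincent et al., Intensive Care Med
# 1996).  Each component maps trailing-24h worst values to a score in 0-4.
respiratory:
  # PaO2/FiO2 ratio (mmHg, FiO2 as a fraction); scores 3-4 additionally
  # require respiratory support (mechanical ventilation in-window)
  ratio_cuts: [400.0, 300.0, 200.0, 100.0]
  support_required_from: 3
coagulation:
  platelet_cuts: [150.0, 100.0, 50.0, 20.0]   # x10^3/mm^3, score k if < cut k
liver:
  bilirubin_cuts: [1.2, 2.0, 6.0, 12.0]       # mg/dL, score k if >= cut k
cardiovascular:
  map_hypotension: 70.0                        # MAP < 70 -> score 1
  dopamine_low: 5.0                            # <=5 -> 2, >5 -> 3, >15 -> 4
  dopamine_high: 15.0
  epinephrine_cut: 0.1                         # <=0.1 -> 3, >0.1 -> 4
  norepinephrine_cut: 0.1
  # any dobutamine -> score >= 2
cns:
  gcs_cuts: [15, 13, 10, 6]                    # 15->0, 13-14->1, 10-12->2, 6-9->3, <6->4
renal:
  creatinine_cuts: [1.2, 2.0, 3.5, 5.0]        # mg/dL, score k if >= cut k
  urine_cuts: [500.0, 200.0]                   # mL/24h: <500 -> 3, <200 -> 4
spo2_fallback:
  # Optional SpO2/FiO2 substitute for the respiratory ratio when PaO2 was
  # never measured; disabled by default (no published SOFA cut-points).
  enabled: false
  ratio_cuts: [512.0, 357.0, 214.0, 89.0]
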