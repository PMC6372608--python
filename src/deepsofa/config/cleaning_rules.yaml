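# Outlier-removal rules: expert-style valid ranges (inclusive) plus a
# modified Z-score screen (Iglewicz-Hoaglin, 0.6745*(x - median)/MAD) for
# continuous labs and vitals.  Ranges for the eight tabulated clinical
# variables follow the cohort summary (min, max) bounds; dose, flag and
# device channels get physical/pharmacological bounds and no Z-score screen.
modified_zscore_threshold: 3.5
variables:
  MAP:            {lo: 1.0,  hi: 300.0,  zscore: true}
  FiO2:           {lo: 21.0, hi: 100.0,  zscore: false}   # hard physical bounds
  PaO2:           {lo: 9.0,  hi: 720.0,  zscore: true}
  SpO2:           {lo: 1.0,  hi: 100.0,  zscore: true}
  GCS:            {lo: 3.0,  hi: 15.0,   zscore: false}   # bounded ordinal score
  urine:          {lo: 0.0,  hi: 1090.0, zscore: true}
  platelets:      {lo: 1.0,  hi: 832.0,  zscore: true}
  bilirubin:      {lo: 0.1,  hi: 49.2,   zscore: true}
  creatinine:     {lo: 0.1,  hi: 26.5,   zscore: true}
  dopamine:       {lo: 0.0,  hi: 50.0,   zscore: false}
  dobutamine:     {lo: 0.0,  hi: 40.0,   zscore: false}
  epinephrine:    {lo: 0.0,  hi: 5.0,    zscore: false}
  norepinephrine: {lo: 0.0,  hi: 5.0,    zscore: false}
  mech_vent:      {lo: 0.0,  hi: 1.0,    zscore: false}
  o2_device:      {lo: 0.0,  hi: 5.0,    zscore: false}
  o2_flow:        {lo: 0.0,  hi: 80.0,   zscore: false}
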