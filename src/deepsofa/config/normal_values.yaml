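# Clinically normal default values imputed where a channel has no
# measurement yet (or none at all during the stay).  Configurable; these
# shipped defaults are textbook normal-range midpoints chosen by this
# package, with urine expressed as mL per hour.
MAP: 80.0
FiO2: 21.0
PaO2: 95.0
SpO2: 98.0
GCS: 15.0
urine: 100.0
platelets: 250.0
bilirubin: 0.6
creatinine: 0.9
dopamine: 0.0
dobutamine: 0.0
epinephrine: 0.0
norepinephrine: 0.0
mech_vent: 0.0
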