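# Conversion from oxygen-delivery device + flow rate (L/min) to estimated
# FiO2 (%), used where FiO2 itself was not charted.  Estimates are clamped
# to [21, 100].  Device codes are the integers stored in o2_device event
# values.  "per_lpm" adds that many percent per L/min of flow above zero,
# capped at "max".
clamp: [21.0, 100.0]
devices:
  room_air:        {code: 0, base: 21.0, per_lpm: 0.0, max: 21.0}
  nasal_cannula:   {code: 1, base: 21.0, per_lpm: 4.0, max: 45.0}
  simple_mask:     {code: 2, base: 35.0, per_lpm: 5.0, flow_offset: 5.0, max: 60.0}
  non_rebreather:  {code: 3, base: 80.0, per_lpm: 0.0, max: 80.0}
  # high-flow systems and ventilators chart FiO2 directly; recorded FiO2
  # events pass through and no estimate is emitted for these devices
  high_flow:       {code: 4, passthrough: true}
  ventilator:      {code: 5, passthrough: true}
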