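"""Canonical clinical variable registry.

Thirteen variables enter the SOFA score proper (six organ systems); SpO2 is
carried alongside them as the fourteenth channel because it is the usual
respiratory measurement when PaO2 is unavailable.  ``o2_device`` and
``o2_flow`` are raw-event-only variables consumed by FiO2 imputation and
never appear in the hourly grid.
"""

from __future__ import annotations

# Hourly-grid channels, fixed order (13 SOFA variables + SpO2 = 14).
CHANNELS: tuple[str, ...] = (
    "MAP",            # mean arterial pressure, mmHg
    "FiO2",           # fraction of inspired oxygen, %
    "PaO2",           # arterial O2 partial pressure, mmHg
    "SpO2",           # peripheral O2 saturation, %
    "GCS",            # Glasgow Coma Scale, 3-15
    "urine",          # urine output, mL (volume per event)
    "platelets",      # platelet count, x10^3/mm^3
    "bilirubin",      # serum bilirubin, mg/dL
    "creatinine",     # serum creatinine, mg/dL
    "dopamine",       # ug/kg/min
    "dobutamine",     # ug/kg/min
    "epinephrine",    # ug/kg/min
    "norepinephrine", # ug/kg/min
    "mech_vent",      # mechanical ventilation status, {0,1}
)

# Raw-event variables that feed FiO2 imputation only.
RAW_ONLY: tuple[str, ...] = ("o2_device", "o2_flow")

ALL_VARIABLES: tuple[str, ...] = CHANNELS + RAW_ONLY

VASOPRESSORS: tuple[str, ...] = (
    "dopamine",
    "dobutamine",
    "epinephrine",
    "norepinephrine",
)

# Channels gap-filled with zero (absence of a rate/flag means "off"); all
# other channels forward-fill like vitals and labs.
ZERO_FILLED: tuple[str, ...] = VASOPRESSORS + ("mech_vent",)

# Urine is a volume: hourly cells hold in-hour sums, not means, so that the
# 24-hour total needed by the renal SOFA component is conserved.
SUM_AGGREGATED: tuple[str, ...] = ("urine",)

# O2 delivery device codes used in ``o2_device`` event values.
O2_DEVICE_CODES: dict[int, str] = {
    0: "room_air",
    1: "nasal_cannula",
    2: "simple_mask",
    3: "non_rebreather",
    4: "high_flow",
    5: "ventilator",
}

ORGAN_SYSTEMS: dict[str, tuple[str, ...]] = {
    "resp": ("PaO2", "FiO2", "SpO2", "mech_vent"),
    "coag": ("platelets",),
    "liver": ("bilirubin",),
    "cardio": ("MAP", "dopamine", "dobutamine", "epinephrine", "norepinephrine"),
    "cns": ("GCS",),
    "renal": ("creatinine", "urine"),
}
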