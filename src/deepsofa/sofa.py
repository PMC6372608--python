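"""Hourly SOFA scoring from trailing-24-hour worst values.

The Sequential Organ Failure Assessment score sums six organ-system
components (respiratory, coagulation, liver, cardiovascular, CNS, renal),
each an integer 0-4 assigned by fixed thresholds applied to the *worst*
value of its inputs over a trailing window (24 h here, shorter early in the
stay when fewer hours exist).  "Worst" direction depends on the channel:
minimum for MAP, PaO2/FiO2 ratio, platelets and GCS; maximum for bilirubin,
creatinine and vasopressor doses; urine is a 24-h total (windows shorter
than 24 h are scaled up to a 24-h-equivalent volume so early hours are not
spuriously oliguric); mechanical ventilation counts if present anywhere in
the window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from deepsofa.config import load_packaged_yaml
from deepsofa.preprocessing import HourlyGrid

WINDOW_HOURS = 24

COMPONENTS = ("resp", "coag", "liver", "cardio", "cns", "renal")

# worst-direction registry for raw channels and derived ratios
_MIN_CHANNELS = {"MAP", "platelets", "GCS", "pf_ratio", "sf_ratio"}
_MAX_CHANNELS = {
    "bilirubin",
    "creatinine",
    "dopamine",
    "dobutamine",
    "epinephrine",
    "norepinephrine",
    "PaO2",
    "FiO2",
    "SpO2",
}


@dataclass
class SofaThresholds:
    """Component cut-points; defaults transcribed from the original SOFA definition."""

    respiratory_ratio_cuts: tuple[float, ...] = (400.0, 300.0, 200.0, 100.0)
    respiratory_support_from: int = 3
    platelet_cuts: tuple[float, ...] = (150.0, 100.0, 50.0, 20.0)
    bilirubin_cuts: tuple[float, ...] = (1.2, 2.0, 6.0, 12.0)
    map_hypotension: float = 70.0
    dopamine_low: float = 5.0
    dopamine_high: float = 15.0
    epinephrine_cut: float = 0.1
    norepinephrine_cut: float = 0.1
    gcs_cuts: tuple[int, ...] = (15, 13, 10, 6)
    creatinine_cuts: tuple[float, ...] = (1.2, 2.0, 3.5, 5.0)
    urine_cuts: tuple[float, ...] = (500.0, 200.0)
    spo2_fallback_enabled: bool = False
    spo2_ratio_cuts: tuple[float, ...] = (512.0, 357.0, 214.0, 89.0)

    @classmethod
    def default(cls) -> "SofaThresholds":
        raw = load_packaged_yaml("sofa_thresholds.yaml")
        return cls(
            respiratory_ratio_cuts=tuple(raw["respiratory"]["ratio_cuts"]),
            respiratory_support_from=int(raw["respiratory"]["support_required_from"]),
            platelet_cuts=tuple(raw["coagulation"]["platelet_cuts"]),
            bilirubin_cuts=tuple(raw["liver"]["bilirubin_cuts"]),
            map_hypotension=float(raw["cardiovascular"]["map_hypotension"]),
            dopamine_low=float(raw["cardiovascular"]["dopamine_low"]),
            dopamine_high=float(raw["cardiovascular"]["dopamine_high"]),
            epinephrine_cut=float(raw["cardiovascular"]["epinephrine_cut"]),
            norepinephrine_cut=float(raw["cardiovascular"]["norepinephrine_cut"]),
            gcs_cuts=tuple(raw["cns"]["gcs_cuts"]),
            creatinine_cuts=tuple(raw["renal"]["creatinine_cuts"]),
            urine_cuts=tuple(raw["renal"]["urine_cuts"]),
            spo2_fallback_enabled=bool(raw["spo2_fallback"]["enabled"]),
            spo2_ratio_cuts=tuple(raw["spo2_fallback"]["ratio_cuts"]),
        )


def worst_window(grid: HourlyGrid, hour: int, channel: str):
    """Worst value of ``channel`` over the trailing-24h window ending at ``hour``.

    ``channel`` may be a grid channel, ``"pf_ratio"`` / ``"sf_ratio"``
    (hourly PaO2/FiO2 or SpO2/FiO2 with FiO2 as a fraction), ``"urine"``
    (24-h-equivalent total) or ``"mech_vent"`` (1.0 if ventilated anywhere
    in-window).
    """
    if not 1 <= hour <= grid.n_hours:
        raise ValueError(f"hour {hour} outside 1..{grid.n_hours}")
    lo = max(1, hour - (WINDOW_HOURS - 1))
    win = grid.values.loc[lo:hour]
    n = len(win)
    if channel == "urine":
        return float(win["urine"].sum() * (WINDOW_HOURS / n))
    if channel == "mech_vent":
        return float(win["mech_vent"].max())
    if channel == "pf_ratio":
        series = win["PaO2"] / (win["FiO2"] / 100.0)
    elif channel == "sf_ratio":
        series = win["SpO2"] / (win["FiO2"] / 100.0)
    else:
        series = win[channel]
    if channel in _MIN_CHANNELS:
        return float(series.min())
    if channel in _MAX_CHANNELS:
        return float(series.max())
    raise ValueError(f"unknown channel {channel!r}")


def _band_ge(value: float, cuts: tuple[float, ...]) -> int:
    """Score k for the largest k with value >= cuts[k-1] (ascending severity cuts)."""
    score = 0
    for k, cut in enumerate(cuts, start=1):
        if value >= cut:
            score = k
    return score


def _band_lt(value: float, cuts: tuple[float, ...]) -> int:
    """Score k for the smallest cut with value < cuts[k-1] (descending cuts)."""
    score = 0
    for k, cut in enumerate(cuts, start=1):
        if value < cut:
            score = k
    return score


def component_score(
    component: str, worst: dict, thresholds: SofaThresholds | None = None
) -> int:
    """Score one organ system (0-4) from its trailing-window worst values.

    ``worst`` holds the relevant entries: resp -> ``pf_ratio`` (or
    ``sf_ratio`` when the fallback is enabled) and ``mech_vent``; coag ->
    ``platelets``; liver -> ``bilirubin``; cardio -> ``MAP`` and the four
    vasopressor doses; cns -> ``GCS``; renal -> ``creatinine`` and the
    24-h ``urine`` total.
    """
    t = thresholds or SofaThresholds.default()
    if component == "resp":
        if "pf_ratio" in worst:
            score = _band_lt(worst["pf_ratio"], t.respiratory_ratio_cuts)
        elif t.spo2_fallback_enabled and "sf_ratio" in worst:
            score = _band_lt(worst["sf_ratio"], t.spo2_ratio_cuts)
        else:
            return 0
        if score >= t.respiratory_support_from and not worst.get("mech_vent", 0.0):
            score = t.respiratory_support_from - 1
        return score
    if component == "coag":
        return _band_lt(worst["platelets"], t.platelet_cuts)
    if component == "liver":
        return _band_ge(worst["bilirubin"], t.bilirubin_cuts)
    if component == "cardio":
        score = 1 if worst["MAP"] < t.map_hypotension else 0
        dopa = worst.get("dopamine", 0.0)
        dobu = worst.get("dobutamine", 0.0)
        epi = worst.get("epinephrine", 0.0)
        nor = worst.get("norepinephrine", 0.0)
        if dopa > 0 or dobu > 0:
            score = max(score, 2)
        if (dopa > t.dopamine_low) or (0 < epi <= t.epinephrine_cut) or (
            0 < nor <= t.norepinephrine_cut
        ):
            score = max(score, 3)
        if (dopa > t.dopamine_high) or (epi > t.epinephrine_cut) or (
            nor > t.norepinephrine_cut
        ):
            score = max(score, 4)
        return score
    if component == "cns":
        g = worst["GCS"]
        c15, c13, c10, c6 = t.gcs_cuts
        if g >= c15:
            return 0
        if g >= c13:
            return 1
        if g >= c10:
            return 2
        if g >= c6:
            return 3
        return 4
    if component == "renal":
        score = _band_ge(worst["creatinine"], t.creatinine_cuts)
        urine = worst.get("urine")
        if urine is not None:
            if urine < t.urine_cuts[1]:
                score = max(score, 4)
            elif urine < t.urine_cuts[0]:
                score = max(score, 3)
        return score
    raise ValueError(f"unknown component {component!r}")


def hourly_sofa(
    grid: HourlyGrid, thresholds: SofaThresholds | None = None
) -> pd.DataFrame:
    """Six component scores + total for every hour 1..T of one encounter.

    Returns a DataFrame indexed by hour with columns ``resp, coag, liver,
    cardio, cns, renal, total``.  Uses vectorized trailing-window statistics;
    equivalence with a per-hour rescan of all raw window values is exercised
    in the test suite.
    """
    t = thresholds or SofaThresholds.default()
    v = grid.values
    roll = lambda s: s.rolling(WINDOW_HOURS, min_periods=1)

    pf = v["PaO2"] / (v["FiO2"] / 100.0)
    worst_pf = roll(pf).min()
    any_vent = roll(v["mech_vent"]).max()
    worst_platelets = roll(v["platelets"]).min()
    worst_bili = roll(v["bilirubin"]).max()
    worst_map = roll(v["MAP"]).min()
    worst_gcs = roll(v["GCS"]).min()
    worst_creat = roll(v["creatinine"]).max()
    n_in_window = roll(pd.Series(1.0, index=v.index)).sum()
    urine_24h = roll(v["urine"]).sum() * (WINDOW_HOURS / n_in_window)
    max_dose = {c: roll(v[c]).max() for c in
                ("dopamine", "dobutamine", "epinephrine", "norepinephrine")}

    use_sf = False
    if t.spo2_fallback_enabled:
        # fall back only when PaO2 was never measured during the stay
        use_sf = bool((grid.provenance["PaO2"] == "normal_imputed").all())
        worst_sf = roll(v["SpO2"] / (v["FiO2"] / 100.0)).min()

    rows = np.empty((grid.n_hours, 7), dtype=int)
    for i, h in enumerate(v.index):
        worst_resp = (
            {"sf_ratio": worst_sf.loc[h]} if use_sf else {"pf_ratio": worst_pf.loc[h]}
        )
        worst_resp["mech_vent"] = any_vent.loc[h]
        comp = (
            component_score("resp", worst_resp, t),
            component_score("coag", {"platelets": worst_platelets.loc[h]}, t),
            component_score("liver", {"bilirubin": worst_bili.loc[h]}, t),
            component_score(
                "cardio",
                {"MAP": worst_map.loc[h],
                 **{c: s.loc[h] for c, s in max_dose.items()}},
                t,
            ),
            component_score("cns", {"GCS": worst_gcs.loc[h]}, t),
            component_score(
                "renal",
                {"creatinine": worst_creat.loc[h], "urine": urine_24h.loc[h]},
                t,
            ),
        )
        rows[i] = (*comp, sum(comp))
    return pd.DataFrame(
        rows, index=v.index, columns=[*COMPONENTS, "total"]
    )


def sofa_table(grids: dict, thresholds: SofaThresholds | None = None) -> pd.DataFrame:
    """Long-format SOFA table for a cohort: encounter_id, hour, components, total."""
    t = thresholds or SofaThresholds.default()
    frames = []
    for eid, grid in grids.items():
        df = hourly_sofa(grid, t).reset_index()
        df.insert(0, "encounter_id", eid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
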