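"""Raw events -> complete hourly channel grid.

Pipeline order per encounter:

1. outlier removal (expert ranges, then a modified Z-score screen computed
   per variable across the whole cohort),
2. FiO2 imputation from oxygen-device/flow events where FiO2 is not charted,
3. hourly resampling: hour ``h`` covers the left-open interval ``(h-1, h]``;
   multiple in-window values are averaged, except urine which is summed
   (it is a volume and the renal SOFA component needs conserved 24-h totals),
4. gap filling: forward fill for vitals and labs, zero for vasopressor rates
   and mechanical-ventilation status,
5. clinically-normal-value imputation for anything still missing (leading
   hours, or variables never measured during the stay).

Every cell of the resulting grid carries a provenance flag:
``measured_mean``, ``forward_filled``, ``zero_filled`` or ``normal_imputed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from deepsofa.config import load_packaged_yaml
from deepsofa.variables import CHANNELS, O2_DEVICE_CODES, SUM_AGGREGATED, ZERO_FILLED

logger = logging.getLogger(__name__)

MEASURED = "measured_mean"
FFILL = "forward_filled"
ZERO = "zero_filled"
NORMAL = "normal_imputed"


@dataclass
class CleaningRules:
    """Per-variable valid ranges plus the modified Z-score screen.

    ``ranges[var] = (lo, hi)`` (inclusive); ``zscore_flags[var]`` says whether
    the Z-score screen applies (continuous labs/vitals only by default).
    """

    ranges: dict[str, tuple[float, float]]
    zscore_flags: dict[str, bool]
    modified_zscore_threshold: float = 3.5

    def __post_init__(self) -> None:
        for var, (lo, hi) in self.ranges.items():
            if not lo < hi:
                raise ValueError(f"{var}: lo must be < hi, got ({lo}, {hi})")

    @classmethod
    def default(cls) -> "CleaningRules":
        raw = load_packaged_yaml("cleaning_rules.yaml")
        return cls(
            ranges={v: (d["lo"], d["hi"]) for v, d in raw["variables"].items()},
            zscore_flags={v: bool(d["zscore"]) for v, d in raw["variables"].items()},
            modified_zscore_threshold=float(raw["modified_zscore_threshold"]),
        )

    @classmethod
    def from_yaml(cls, path) -> "CleaningRules":
        with open(path, encoding="utf-8") as fh:
            import yaml

            raw = yaml.safe_load(fh)
        return cls(
            ranges={v: (d["lo"], d["hi"]) for v, d in raw["variables"].items()},
            zscore_flags={v: bool(d["zscore"]) for v, d in raw["variables"].items()},
            modified_zscore_threshold=float(raw["modified_zscore_threshold"]),
        )


@dataclass
class NormalValues:
    """Clinically normal default per channel, imputed where nothing else is known."""

    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = set(CHANNELS) - set(self.values)
        if missing:
            raise ValueError(f"normal values missing channels: {sorted(missing)}")

    @classmethod
    def default(cls) -> "NormalValues":
        return cls(values={k: float(v) for k, v in load_packaged_yaml("normal_values.yaml").items()})

    @classmethod
    def from_yaml(cls, path) -> "NormalValues":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls(values={k: float(v) for k, v in yaml.safe_load(fh).items()})

    def __getitem__(self, var: str) -> float:
        return self.values[var]


@dataclass
class HourlyGrid:
    """Per-encounter hour x channel matrix with per-cell provenance.

    ``values`` and ``provenance`` share an integer index 1..T
    (T = ceil(icu_los_hours)) and the 14 channel columns.
    """

    encounter_id: object
    values: pd.DataFrame
    provenance: pd.DataFrame

    @property
    def n_hours(self) -> int:
        return len(self.values)

    def to_array(self, channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
        return self.values[list(channels)].to_numpy(dtype=float)

    def validate(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("grid contains missing cells")
        if list(self.values.columns) != list(CHANNELS):
            raise ValueError("grid channels out of order")
        fio2 = self.values["FiO2"]
        if ((fio2 < 21) | (fio2 > 100)).any():
            raise ValueError("FiO2 outside [21, 100]")
        mv = self.values["mech_vent"]
        if not mv.isin([0.0, 1.0]).all():
            raise ValueError("mech_vent not binary")


def remove_outliers(
    events: pd.DataFrame, rules: CleaningRules | None = None
) -> tuple[pd.DataFrame, dict]:
    """Drop out-of-range values, then modified Z-score outliers.

    The Z-score screen uses the Iglewicz-Hoaglin statistic
    ``0.6745*(x - median)/MAD`` computed per variable across the whole event
    table (cohort level), applied only to variables flagged in the rules;
    a zero MAD disables the screen for that variable.  Returns the cleaned
    events plus a per-variable removal report.
    """
    rules = rules or CleaningRules.default()
    events = events.reset_index(drop=True)
    report: dict[str, dict[str, int]] = {}
    keep = np.ones(len(events), dtype=bool)
    values = events["value"].to_numpy(dtype=float)
    for var, grp in events.groupby("variable"):
        pos = grp.index.to_numpy()  # positions == labels after reset_index
        v = values[pos]
        rep = {"range": 0, "zscore": 0}
        if var in rules.ranges:
            lo, hi = rules.ranges[var]
            bad = (v < lo) | (v > hi)
            keep[pos[bad]] = False
            rep["range"] = int(bad.sum())
            pos, v = pos[~bad], v[~bad]
        if rules.zscore_flags.get(var, False) and len(v):
            med = np.median(v)
            mad = np.median(np.abs(v - med))
            if mad > 0:
                z = 0.6745 * (v - med) / mad
            else:
                # Iglewicz-Hoaglin fallback: mean absolute deviation
                mean_ad = np.mean(np.abs(v - med))
                if mean_ad == 0:
                    logger.info("zero spread for %s; Z-score screen skipped", var)
                    z = np.zeros_like(v)
                else:
                    z = (v - med) / (1.253314 * mean_ad)
            bad = np.abs(z) > rules.modified_zscore_threshold
            keep[pos[bad]] = False
            rep["zscore"] = int(bad.sum())
        report[var] = rep
    return events[keep].reset_index(drop=True), report


@dataclass
class Fio2Table:
    """Device + flow (L/min) -> estimated FiO2 (%) conversion table."""

    devices: dict[str, dict]
    clamp: tuple[float, float] = (21.0, 100.0)

    @classmethod
    def default(cls) -> "Fio2Table":
        raw = load_packaged_yaml("fio2_table.yaml")
        return cls(devices=raw["devices"], clamp=tuple(raw["clamp"]))

    def estimate(self, device_name: str, flow_lpm: float) -> float | None:
        spec = self.devices.get(device_name)
        if spec is None or spec.get("passthrough", False):
            return None
        flow = max(0.0, flow_lpm - spec.get("flow_offset", 0.0))
        est = spec["base"] + spec.get("per_lpm", 0.0) * flow
        est = min(est, spec.get("max", self.clamp[1]))
        return float(np.clip(est, *self.clamp))


def impute_fio2(
    events: pd.DataFrame, table: Fio2Table | None = None
) -> pd.DataFrame:
    """Emit estimated FiO2 events from oxygen device/flow observations.

    For each ``o2_device`` event without a charted FiO2 at the same offset in
    the same encounter, an FiO2 event is appended using the device table;
    flow is taken from the ``o2_flow`` event at the matching offset (0 L/min
    if absent).  Passthrough devices (ventilator, high-flow) chart FiO2
    directly and are skipped, as are unknown device codes (logged).
    """
    table = table or Fio2Table.default()
    dev = events.loc[events["variable"] == "o2_device",
                     ["encounter_id", "offset_hours", "value"]].copy()
    if dev.empty:
        return events
    flow = (
        events.loc[events["variable"] == "o2_flow",
                   ["encounter_id", "offset_hours", "value"]]
        .groupby(["encounter_id", "offset_hours"], as_index=False)["value"]
        .mean()
        .rename(columns={"value": "flow"})
    )
    dev = dev.groupby(["encounter_id", "offset_hours"], as_index=False)["value"].max()
    dev = dev.merge(flow, on=["encounter_id", "offset_hours"], how="left")
    dev["flow"] = dev["flow"].fillna(0.0)
    charted = events.loc[events["variable"] == "FiO2",
                         ["encounter_id", "offset_hours"]].drop_duplicates()
    dev = dev.merge(charted.assign(_charted=True),
                    on=["encounter_id", "offset_hours"], how="left")
    dev = dev[dev["_charted"].isna()]
    if dev.empty:
        return events

    unknown = ~dev["value"].astype(int).isin(O2_DEVICE_CODES)
    if unknown.any():
        logger.warning("skipping %d events with unknown o2_device codes",
                       int(unknown.sum()))
        dev = dev[~unknown]
    est = np.full(len(dev), np.nan)
    codes = dev["value"].astype(int).to_numpy()
    flows = dev["flow"].to_numpy(dtype=float)
    for code, name in O2_DEVICE_CODES.items():
        sel = codes == code
        if not sel.any():
            continue
        spec = table.devices.get(name)
        if spec is None or spec.get("passthrough", False):
            continue
        f = np.maximum(0.0, flows[sel] - spec.get("flow_offset", 0.0))
        e = np.minimum(spec["base"] + spec.get("per_lpm", 0.0) * f,
                       spec.get("max", table.clamp[1]))
        est[sel] = np.clip(e, *table.clamp)
    keep = ~np.isnan(est)
    if not keep.any():
        return events
    new = pd.DataFrame(
        {
            "encounter_id": dev["encounter_id"].to_numpy()[keep],
            "variable": "FiO2",
            "offset_hours": dev["offset_hours"].to_numpy()[keep],
            "value": np.round(est[keep], 3),
        }
    )
    return pd.concat([events, new], ignore_index=True)


def build_hourly_grid(
    events: pd.DataFrame,
    encounter,
    normals: NormalValues | None = None,
) -> HourlyGrid:
    """Resample one encounter's cleaned events into a complete hourly grid.

    Hour ``h`` (1-based) aggregates events with offset in ``(h-1, h]``;
    events at offset exactly 0 land in hour 1.  See the module docstring for
    the fill hierarchy.  GCS cells are rounded to integers in [3, 15] and
    mech_vent cells thresholded to {0, 1} after averaging.
    """
    normals = normals or NormalValues.default()
    T = int(np.ceil(float(encounter["icu_los_hours"])))
    if T < 1:
        raise ValueError("encounter shorter than one hour")
    ev = events[events["variable"].isin(CHANNELS)].copy()
    if len(ev) == 0:
        raise ValueError(
            f"encounter {encounter['encounter_id']}: no usable events after "
            "cleaning (should have been excluded by cohort filtering)"
        )
    hours = np.ceil(ev["offset_hours"].to_numpy(dtype=float)).astype(int)
    hours[hours < 1] = 1
    ev["hour"] = hours
    ev = ev[ev["hour"] <= T]

    index = pd.RangeIndex(1, T + 1, name="hour")
    values = pd.DataFrame(np.nan, index=index, columns=list(CHANNELS))
    for var, grp in ev.groupby("variable"):
        agg = grp.groupby("hour")["value"].sum() if var in SUM_AGGREGATED else grp.groupby("hour")["value"].mean()
        values.loc[agg.index, var] = agg.to_numpy()

    measured = values.notna()
    provenance = pd.DataFrame("", index=index, columns=list(CHANNELS))
    provenance = provenance.where(~measured, MEASURED)

    ffill_cols = [c for c in CHANNELS if c not in ZERO_FILLED]
    filled = values[ffill_cols].ffill()
    ff_mask = filled.notna() & ~measured[ffill_cols]
    values[ffill_cols] = filled
    for c in ffill_cols:
        provenance.loc[ff_mask[c], c] = FFILL

    for c in ZERO_FILLED:
        miss = values[c].isna()
        values.loc[miss, c] = 0.0
        provenance.loc[miss, c] = ZERO

    for c in ffill_cols:
        miss = values[c].isna()
        values.loc[miss, c] = normals[c]
        provenance.loc[miss, c] = NORMAL

    # channel-specific sanitation after averaging
    values["GCS"] = values["GCS"].round().clip(3, 15)
    values["mech_vent"] = (values["mech_vent"] > 0.5).astype(float)
    values["FiO2"] = values["FiO2"].clip(21.0, 100.0)

    grid = HourlyGrid(
        encounter_id=encounter["encounter_id"], values=values, provenance=provenance
    )
    grid.validate()
    return grid


def preprocess_cohort(
    cohort,
    rules: CleaningRules | None = None,
    fio2_table: Fio2Table | None = None,
    normals: NormalValues | None = None,
) -> tuple[dict, dict]:
    """Full pipeline for a cohort: returns ({encounter_id: HourlyGrid}, report)."""
    rules = rules or CleaningRules.default()
    normals = normals or NormalValues.default()
    events = impute_fio2(cohort.events, fio2_table)
    events, removal_report = remove_outliers(events, rules)
    grids: dict = {}
    skipped = []
    by_enc = dict(tuple(events.groupby("encounter_id")))
    for _, enc in cohort.encounters.iterrows():
        eid = enc["encounter_id"]
        ev = by_enc.get(eid)
        if ev is None or len(ev) == 0:
            skipped.append(eid)
            continue
        grids[eid] = build_hourly_grid(ev, enc, normals)
    if skipped:
        logger.warning("%d encounters had no events after cleaning", len(skipped))
    return grids, {"outlier_removals": removal_report, "skipped_encounters": skipped}
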