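"""Cohort data model, CSV readers, outcome labelling and inclusion filtering.

An ICU *encounter* is the unit of prediction.  Raw measurements are long-format
timestamped events; all times are real-valued hours since ICU admission
(de-identified data carry no usable wall clock).  Two CSV files define a
cohort:

``events.csv``
    columns ``encounter_id, variable, offset_hours, value``

``encounters.csv``
    columns ``encounter_id, patient_id, age_years, icu_los_hours,
    hosp_discharge_offset_hours, died_in_hospital, hospice_discharge,
    days_discharge_to_death, icu_type``

Inclusion criteria: age >= 18 years, ICU stay between 4 hours and 30 days
(closed interval), and at least one MAP measurement plus at least one PaO2 or
SpO2 measurement.  The outcome is in-hospital mortality, counting hospice
discharges with death within 7 days of hospital discharge as mortalities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from deepsofa.variables import ALL_VARIABLES

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ("encounter_id", "variable", "offset_hours", "value")
ENCOUNTER_COLUMNS = (
    "encounter_id",
    "patient_id",
    "age_years",
    "icu_los_hours",
    "hosp_discharge_offset_hours",
    "died_in_hospital",
    "hospice_discharge",
    "days_discharge_to_death",
    "icu_type",
)

MIN_STAY_HOURS = 4.0
MAX_STAY_HOURS = 30.0 * 24.0
MIN_AGE_YEARS = 18.0
HOSPICE_DEATH_WINDOW_DAYS = 7.0

DedupMode = Literal["none", "first_stay_only", "drop_multistay_patients"]


class CohortValidationError(ValueError):
    """Raised when a cohort violates referential or schema invariants."""


@dataclass
class Cohort:
    """An encounter table plus the long-format measurement events.

    ``encounters`` is indexed by position with an ``encounter_id`` column;
    ``events`` rows reference those ids.  ``load_report`` carries row-drop
    counts from parsing, ``filter_report`` per-criterion removal counts from
    :func:`filter_encounters`.
    """

    encounters: pd.DataFrame
    events: pd.DataFrame
    load_report: dict = field(default_factory=dict)
    filter_report: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for col in ENCOUNTER_COLUMNS:
            if col not in self.encounters.columns:
                raise CohortValidationError(f"encounters missing column {col!r}")
        for col in EVENT_COLUMNS:
            if col not in self.events.columns:
                raise CohortValidationError(f"events missing column {col!r}")
        ids = set(self.encounters["encounter_id"])
        if len(ids) != len(self.encounters):
            dupes = self.encounters["encounter_id"][
                self.encounters["encounter_id"].duplicated()
            ].tolist()
            raise CohortValidationError(f"duplicate encounter ids: {dupes[:5]}")
        orphans = set(self.events["encounter_id"]) - ids
        if orphans:
            raise CohortValidationError(
                f"events reference {len(orphans)} unknown encounter ids: "
                f"{sorted(map(str, orphans))[:5]}"
            )
        if len(self.encounters) and (self.encounters["icu_los_hours"] <= 0).any():
            raise CohortValidationError("icu_los_hours must be positive")

    @property
    def n_encounters(self) -> int:
        return len(self.encounters)

    def labels(self) -> pd.Series:
        """In-hospital mortality label per encounter, indexed by encounter_id."""
        lab = self.encounters.apply(apply_outcome_label, axis=1)
        lab.index = self.encounters["encounter_id"]
        return lab.astype(bool)

    def events_for(self, encounter_id) -> pd.DataFrame:
        return self.events[self.events["encounter_id"] == encounter_id]

    def subset(self, encounter_ids) -> "Cohort":
        keep = set(encounter_ids)
        return Cohort(
            encounters=self.encounters[
                self.encounters["encounter_id"].isin(keep)
            ].reset_index(drop=True),
            events=self.events[self.events["encounter_id"].isin(keep)].reset_index(
                drop=True
            ),
            load_report=dict(self.load_report),
        )

    def write(self, events_path, encounters_path) -> None:
        """Write the two canonical CSV files (UTF-8, comma, '.' decimal)."""
        self.events.to_csv(events_path, index=False)
        self.encounters.to_csv(encounters_path, index=False)


def read_cohort(events_path, encounters_path) -> Cohort:
    """Read and validate a cohort from the two canonical CSV files.

    Rows with unparseable numeric values or unknown variable names are
    dropped and counted in ``cohort.load_report``; a missing required column
    is a hard error.
    """
    encounters = pd.read_csv(encounters_path)
    for col in ENCOUNTER_COLUMNS:
        if col not in encounters.columns:
            raise CohortValidationError(
                f"encounters file missing required column {col!r}"
            )
    events = pd.read_csv(events_path)
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise CohortValidationError(f"events file missing required column {col!r}")

    report: dict = {"events_total": int(len(events))}
    if len(events) == 0:
        logger.warning("events file %s contains no data rows", events_path)

    # numeric coercion: unparseable -> NaN -> dropped
    events["offset_hours"] = pd.to_numeric(events["offset_hours"], errors="coerce")
    events["value"] = pd.to_numeric(events["value"], errors="coerce")
    bad_numeric = events["offset_hours"].isna() | ~np.isfinite(
        events["value"].to_numpy(dtype=float)
    )
    unknown_var = ~events["variable"].isin(ALL_VARIABLES)
    if unknown_var.any():
        names = events.loc[unknown_var, "variable"].unique().tolist()
        logger.warning("rejecting events with unknown variables: %s", names[:10])
    neg_offset = events["offset_hours"] < 0
    drop = bad_numeric | unknown_var | neg_offset
    report["events_dropped_unparseable"] = int(bad_numeric.sum())
    report["events_dropped_unknown_variable"] = int(unknown_var.sum())
    report["events_dropped_negative_offset"] = int(neg_offset.sum())
    events = events[~drop].reset_index(drop=True)
    report["events_kept"] = int(len(events))

    for col in ("age_years", "icu_los_hours", "hosp_discharge_offset_hours",
                "days_discharge_to_death"):
        encounters[col] = pd.to_numeric(encounters[col], errors="coerce")
    for col in ("died_in_hospital", "hospice_discharge"):
        encounters[col] = _to_bool(encounters[col])
    bad_enc = encounters["icu_los_hours"].isna() | (encounters["icu_los_hours"] <= 0)
    report["encounters_dropped_unparseable"] = int(bad_enc.sum())
    encounters = encounters[~bad_enc].reset_index(drop=True)
    report["encounters_kept"] = int(len(encounters))

    return Cohort(encounters=encounters, events=events, load_report=report)


def _to_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s
    return (
        s.astype(str)
        .str.strip()
        .str.lower()
        .map({"true": True, "1": True, "1.0": True,
              "false": False, "0": False, "0.0": False, "nan": False})
        .fillna(False)
        .astype(bool)
    )


def apply_outcome_label(encounter) -> bool:
    """In-hospital mortality label for one encounter (row or mapping).

    True iff the patient died in hospital, or was discharged to hospice and
    died within 7 days of hospital discharge.  A hospice discharge with an
    unknown death date is conservatively labelled a non-mortality.
    """
    if bool(encounter["died_in_hospital"]):
        return True
    if bool(encounter["hospice_discharge"]):
        days = encounter["days_discharge_to_death"]
        if days is None or (isinstance(days, float) and np.isnan(days)):
            logger.warning(
                "encounter %s: hospice discharge without a death date; "
                "labelled non-mortality", encounter["encounter_id"]
            )
            return False
        return float(days) <= HOSPICE_DEATH_WINDOW_DAYS
    return False


def filter_encounters(cohort: Cohort, dedup_mode: DedupMode = "none") -> Cohort:
    """Apply the cohort inclusion criteria; optionally de-duplicate patients.

    Criteria (all required): age >= 18 years; ICU length of stay in the
    closed interval [4 h, 720 h]; at least one MAP measurement and at least
    one PaO2 or SpO2 measurement.  ``dedup_mode`` is applied afterwards:
    ``first_stay_only`` keeps each patient's earliest-admitted stay (ties by
    encounter_id), ``drop_multistay_patients`` removes patients with more
    than one remaining stay entirely.  Per-criterion removal counts are
    recorded in ``filter_report`` (criteria assessed independently, so
    counts may overlap).
    """
    enc = cohort.encounters
    ev = cohort.events

    age_ok = enc["age_years"] >= MIN_AGE_YEARS
    los_ok = (enc["icu_los_hours"] >= MIN_STAY_HOURS) & (
        enc["icu_los_hours"] <= MAX_STAY_HOURS
    )
    has_map = enc["encounter_id"].isin(
        ev.loc[ev["variable"] == "MAP", "encounter_id"]
    )
    has_oxy = enc["encounter_id"].isin(
        ev.loc[ev["variable"].isin(["PaO2", "SpO2"]), "encounter_id"]
    )
    base_ok = age_ok & los_ok & has_map & has_oxy

    report = {
        "input": int(len(enc)),
        "removed_age": int((~age_ok).sum()),
        "removed_los": int((~los_ok).sum()),
        "removed_no_map_or_oxygenation": int((~(has_map & has_oxy)).sum()),
        "removed_base_total": int((~base_ok).sum()),
        "dedup_mode": dedup_mode,
    }
    kept = enc[base_ok]

    if dedup_mode == "first_stay_only":
        # encounter ids sort in admission order within a patient (the CSV
        # schema carries no absolute admission time)
        ordered = kept.sort_values("encounter_id", kind="stable")
        first_ids = ordered.loc[~ordered["patient_id"].duplicated(), "encounter_id"]
        kept = kept[kept["encounter_id"].isin(set(first_ids))]
        report["removed_dedup"] = int(base_ok.sum() - len(kept))
    elif dedup_mode == "drop_multistay_patients":
        counts = kept["patient_id"].value_counts()
        multi = counts[counts > 1].index
        kept = kept[~kept["patient_id"].isin(multi)]
        report["removed_dedup"] = int(base_ok.sum() - len(kept))
    elif dedup_mode != "none":
        raise ValueError(f"unknown dedup_mode {dedup_mode!r}")

    if len(kept) == 0:
        logger.warning("filter_encounters removed every encounter")

    out = cohort.subset(kept["encounter_id"])
    out.filter_report = report
    return out
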