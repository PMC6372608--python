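"""SOFA-based mortality baselines and aggregate-feature conventional models.

Three baselines accompany the sequence model, all consuming the same hourly
inputs:

``BedsideSofaModel``
    maps the current (trailing-24h) SOFA total to a published band-level
    mortality probability, as a clinician would with an online calculator.
    Requires no training.

``TraditionalSofaModel``
    uses the raw SOFA total itself as the ranking statistic from which AUC
    is computed retrospectively.  Requires no training.

``AggregateFeatureModel``
    logistic regression or random forest on 84 causal aggregate features
    (min, max, mean, sd, first, last for each of the 14 SOFA variables over
    hours 1..h), recalculated every hour.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

from deepsofa.config import load_packaged_yaml
from deepsofa.preprocessing import HourlyGrid
from deepsofa.variables import CHANNELS

# the 14 model variables (13 SOFA score inputs + SpO2): 6 statistics x 14 = 84
SOFA_VARIABLES = CHANNELS
AGG_STATS = ("min", "max", "mean", "sd", "first", "last")


@dataclass
class BedsideMortalityTable:
    """Ordered SOFA-score bands mapped to mortality probabilities.

    Bands must tile 0..24 exactly once with non-decreasing probabilities.
    The shipped default is a clearly-annotated synthetic placeholder (the
    published correlation table lives outside this package).
    """

    bands: list[tuple[int, int, float]]
    source: str = ""

    def __post_init__(self) -> None:
        covered = []
        last_p = -1.0
        for lo, hi, p in self.bands:
            covered.extend(range(lo, hi + 1))
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
            if p < last_p:
                raise ValueError("band probabilities must be non-decreasing")
            last_p = p
        if sorted(covered) != list(range(25)):
            raise ValueError("bands must cover scores 0..24 exactly once")
        self._lookup = {s: p for lo, hi, p in self.bands for s in range(lo, hi + 1)}

    @classmethod
    def default(cls) -> "BedsideMortalityTable":
        raw = load_packaged_yaml("bedside_table.yaml")
        return cls(
            bands=[(int(b["lo"]), int(b["hi"]), float(b["mortality"]))
                   for b in raw["bands"]],
            source=raw.get("source", ""),
        )

    @classmethod
    def from_yaml(cls, path) -> "BedsideMortalityTable":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(
            bands=[(int(b["lo"]), int(b["hi"]), float(b["mortality"]))
                   for b in raw["bands"]],
            source=raw.get("source", ""),
        )

    def probability(self, total: int) -> float:
        return self._lookup[int(total)]


class BedsideSofaModel(BaseEstimator):
    """Band-lookup mortality probability from the current SOFA total.

    A fixed lookup, not a learned model: ``fit`` only validates the table.
    ``predict_proba_from_totals`` vectorizes the band lookup.
    """

    def __init__(self, table: BedsideMortalityTable | None = None):
        self.table = table

    def fit(self, X=None, y=None) -> "BedsideSofaModel":
        self.table_ = self.table or BedsideMortalityTable.default()
        return self

    def predict_proba_from_totals(self, totals) -> np.ndarray:
        if not hasattr(self, "table_"):
            self.fit()
        return np.array([self.table_.probability(t) for t in np.asarray(totals)])

    def predict_table(self, sofa: pd.DataFrame) -> pd.DataFrame:
        """encounter_id/hour/probability from a long-format SOFA table."""
        out = sofa[["encounter_id", "hour"]].copy()
        out["probability"] = self.predict_proba_from_totals(sofa["total"])
        return out


class TraditionalSofaModel(BaseEstimator):
    """Raw SOFA total as the retrospective ranking score (identity map)."""

    def fit(self, X=None, y=None) -> "TraditionalSofaModel":
        self.fitted_ = True
        return self

    @staticmethod
    def score_from_totals(totals) -> np.ndarray:
        return np.asarray(totals, dtype=float)

    def predict_table(self, sofa: pd.DataFrame) -> pd.DataFrame:
        out = sofa[["encounter_id", "hour"]].copy()
        out["probability"] = self.score_from_totals(sofa["total"])
        return out


def aggregate_features(grid: HourlyGrid, hour: int) -> np.ndarray:
    """84 causal aggregate features at ``hour``: 6 statistics x 14 variables.

    Statistics are computed over hours 1..hour only; the standard deviation
    of a single hour is 0.
    """
    if not 1 <= hour <= grid.n_hours:
        raise ValueError(f"hour {hour} outside 1..{grid.n_hours}")
    x = grid.values.loc[:hour, list(SOFA_VARIABLES)].to_numpy(dtype=float)
    feats = np.concatenate(
        [
            x.min(axis=0),
            x.max(axis=0),
            x.mean(axis=0),
            x.std(axis=0),
            x[0],
            x[-1],
        ]
    )
    assert feats.shape == (len(SOFA_VARIABLES) * len(AGG_STATS),)
    return feats


def aggregate_feature_table(grids: dict, hours: dict | None = None) -> pd.DataFrame:
    """Feature rows for every (encounter, hour); causal cumulative statistics.

    Vectorized over hours via cumulative min/max/moments rather than calling
    :func:`aggregate_features` per hour.
    """
    frames = []
    cols = [f"{v}_{s}" for s in AGG_STATS for v in SOFA_VARIABLES]
    for eid, grid in grids.items():
        x = grid.values[list(SOFA_VARIABLES)].to_numpy(dtype=float)
        T = len(x)
        cmin = np.minimum.accumulate(x, axis=0)
        cmax = np.maximum.accumulate(x, axis=0)
        csum = np.cumsum(x, axis=0)
        csq = np.cumsum(x**2, axis=0)
        n = np.arange(1, T + 1)[:, None]
        mean = csum / n
        var = np.maximum(csq / n - mean**2, 0.0)
        feats = np.concatenate(
            [cmin, cmax, mean, np.sqrt(var), np.broadcast_to(x[0], x.shape), x],
            axis=1,
        )
        df = pd.DataFrame(feats, columns=cols)
        df.insert(0, "hour", np.arange(1, T + 1))
        df.insert(0, "encounter_id", eid)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


class AggregateFeatureModel(BaseEstimator, ClassifierMixin):
    """Conventional-ML sensitivity baseline on 84 aggregate features.

    Parameters
    ----------
    model : {"logistic", "random_forest"}
    seed : int
        Fixes the underlying estimator's randomness; training is
        deterministic given the seed.
    train_hour_stride : int
        Train on every k-th hour row of each stay to keep fitting cheap
        while predicting at every hour.
    """

    def __init__(self, model: str = "logistic", seed: int = 0,
                 train_hour_stride: int = 4):
        self.model = model
        self.seed = seed
        self.train_hour_stride = train_hour_stride

    def _make(self):
        if self.model == "logistic":
            return make_pipeline(
                StandardScaler(),
                LogisticRegression(max_iter=2000, random_state=self.seed),
            )
        if self.model == "random_forest":
            return RandomForestClassifier(
                n_estimators=100, random_state=self.seed, n_jobs=1
            )
        raise ValueError(f"unknown model {self.model!r}")

    def fit(self, feature_table: pd.DataFrame, labels: pd.Series) -> "AggregateFeatureModel":
        y = labels.loc[feature_table["encounter_id"]].to_numpy(dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training labels contain a single class")
        rows = feature_table["hour"] % self.train_hour_stride == 1 if self.train_hour_stride > 1 else np.ones(len(y), bool)
        X = feature_table.drop(columns=["encounter_id", "hour"]).to_numpy(dtype=float)
        self.estimator_ = self._make().fit(X[np.asarray(rows)], y[np.asarray(rows)])
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba_rows(self, feature_table: pd.DataFrame) -> np.ndarray:
        X = feature_table.drop(columns=["encounter_id", "hour"]).to_numpy(dtype=float)
        return self.estimator_.predict_proba(X)[:, 1]

    def predict_table(self, feature_table: pd.DataFrame) -> pd.DataFrame:
        out = feature_table[["encounter_id", "hour"]].copy()
        out["probability"] = self.predict_proba_rows(feature_table)
        return out
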