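"""Hourly-AUC evaluation protocol with bootstrap confidence intervals.

Discrimination is measured as AUC at every hour under two time alignments:

``since_admission``
    hour ``h`` uses each encounter's prediction at hour ``h``; encounters
    shorter than ``h`` contribute their final prediction (carry-forward), so
    every hour's AUC covers the full cohort.

``before_end``
    hour ``k`` (0 = the last in-stay hour) uses the prediction at hour
    ``max(1, T - k)``, looking backwards from ICU discharge or death.

Confidence intervals are percentile bootstrap over encounters; model
comparison uses a paired bootstrap (shared resamples) of the AUC
difference.  Internal 5-fold cross-validation and external train-on-A /
test-on-B orchestration mirror the study protocol.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclass
class EvalConfig:
    n_bootstrap: int = 100
    ci_level: float = 0.95
    max_hours: int = 100
    n_cv_folds: int = 5
    comparison_alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 2 or self.n_cv_folds < 2:
            raise ValueError("n_bootstrap and n_cv_folds must be >= 2")


def auc(scores, labels) -> float:
    """Tie-corrected AUC: (concordant + 0.5 * tied) / (pos x neg pairs)."""
    labels = np.asarray(labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined with a single class")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _score_matrix(preds: pd.DataFrame, labels: pd.Series, alignment: str,
                  max_hours: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_encounters, max_hours) score matrix under the carry-forward rule."""
    if alignment not in ("since_admission", "before_end"):
        raise ValueError(f"unknown alignment {alignment!r}")
    enc_ids = labels.index.to_numpy()
    y = labels.to_numpy(dtype=int)
    mat = np.empty((len(enc_ids), max_hours))
    by_enc = preds.sort_values("hour").groupby("encounter_id")["probability"]
    series = {k: v.to_numpy() for k, v in by_enc}
    for i, eid in enumerate(enc_ids):
        p = series[eid]
        T = len(p)
        if alignment == "since_admission":
            if T >= max_hours:
                mat[i] = p[:max_hours]
            else:
                mat[i, :T] = p
                mat[i, T:] = p[-1]          # carry forward the final prediction
        else:
            # k hours before the end; clamp to the first prediction
            idx = np.maximum(T - 1 - np.arange(max_hours), 0)
            mat[i] = p[idx]
    return mat, y, enc_ids


def hourly_curve(preds: pd.DataFrame, labels: pd.Series,
                 alignment: str = "since_admission",
                 config: EvalConfig | None = None) -> pd.DataFrame:
    """Per-hour AUC with percentile-bootstrap CIs.

    ``preds``: columns encounter_id, hour, probability (every in-stay hour).
    ``labels``: boolean Series indexed by encounter_id.  Hours where the
    bootstrap or point estimate is undefined (single class) are skipped with
    a warning.  Returns columns: alignment, hour, auc, ci_lo, ci_hi,
    n_encounters, n_deaths.
    """
    cfg = config or EvalConfig()
    if labels.sum() == 0:
        raise ValueError("no deaths in cohort; AUC undefined")
    mat, y, _ = _score_matrix(preds, labels, alignment, cfg.max_hours)
    n = len(y)
    rng = np.random.default_rng(cfg.seed)
    boot_idx = rng.integers(0, n, size=(cfg.n_bootstrap, n))
    alpha = (1.0 - cfg.ci_level) / 2.0
    rows = []
    for h in range(cfg.max_hours):
        scores = mat[:, h]
        point = auc(scores, y)
        boot = []
        for b in range(cfg.n_bootstrap):
            yb = y[boot_idx[b]]
            if yb.min() == yb.max():
                continue
            boot.append(auc(scores[boot_idx[b]], yb))
        if not boot:
            logger.warning("hour %d: all bootstrap resamples single-class", h)
            continue
        lo, hi = np.quantile(boot, [alpha, 1.0 - alpha])
        rows.append(
            {"alignment": alignment,
             "hour": h + 1 if alignment == "since_admission" else h,
             "auc": point, "ci_lo": float(lo), "ci_hi": float(hi),
             "n_encounters": n, "n_deaths": int(y.sum())}
        )
    return pd.DataFrame(rows)


def bootstrap_se(scores, labels, n_bootstrap: int = 100, seed: int = 0) -> float:
    """Bootstrap standard error of a single AUC."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    vals = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, len(y), size=len(y))
        if y[idx].min() == y[idx].max():
            continue
        vals.append(auc(scores[idx], y[idx]))
    return float(np.std(vals, ddof=1))


def compare_models(preds_a: pd.DataFrame, preds_b: pd.DataFrame,
                   labels: pd.Series, hour: int,
                   alignment: str = "since_admission",
                   config: EvalConfig | None = None) -> dict:
    """Paired bootstrap test of AUC(A) - AUC(B) at one evaluation hour.

    Both models must predict the same encounters; each bootstrap iteration
    resamples encounters once and applies the same resample to both models.
    Returns the difference, percentile CI and a two-sided bootstrap p-value
    (tail mass of the difference distribution crossing zero).
    """
    cfg = config or EvalConfig()
    ids_a = set(preds_a["encounter_id"])
    ids_b = set(preds_b["encounter_id"])
    if ids_a != ids_b:
        raise ValueError("prediction tables cover different encounter sets")
    col = hour - 1 if alignment == "since_admission" else hour
    mat_a, y, _ = _score_matrix(preds_a, labels, alignment, max(hour, 1))
    mat_b, _, _ = _score_matrix(preds_b, labels, alignment, max(hour, 1))
    sa, sb = mat_a[:, col], mat_b[:, col]
    diff = auc(sa, y) - auc(sb, y)
    rng = np.random.default_rng(cfg.seed)
    n = len(y)
    diffs = []
    for _ in range(cfg.n_bootstrap):
        idx = rng.integers(0, n, size=n)
        if y[idx].min() == y[idx].max():
            continue
        diffs.append(auc(sa[idx], y[idx]) - auc(sb[idx], y[idx]))
    diffs = np.asarray(diffs)
    alpha = (1.0 - cfg.ci_level) / 2.0
    lo, hi = np.quantile(diffs, [alpha, 1.0 - alpha])
    # two-sided bootstrap p: how often the resampled difference crosses zero
    tail = min((diffs <= 0).mean(), (diffs >= 0).mean())
    p = min(1.0, 2.0 * tail)
    return {"auc_difference": float(diff), "ci_lo": float(lo),
            "ci_hi": float(hi), "p_value": float(p),
            "significant": bool(p < cfg.comparison_alpha)}


def run_internal_cv(grids: dict, labels: pd.Series, model_factory,
                    config: EvalConfig | None = None) -> pd.DataFrame:
    """5-fold cross-validation pooled predictions.

    Folds partition encounters; each encounter is predicted exactly once, by
    the model from the fold where it was held out.  A fold whose training or
    test part is single-class triggers a reshuffled refold (logged).
    ``model_factory(fold_seed)`` must return an unfitted estimator with
    ``fit(grids, y)`` and ``predict_cohort(grids)``.
    """
    cfg = config or EvalConfig()
    enc_ids = np.array(list(grids.keys()), dtype=object)
    y = labels.loc[enc_ids].to_numpy(dtype=int)
    rng = np.random.default_rng(cfg.seed)
    for attempt in range(20):
        order = rng.permutation(len(enc_ids))
        folds = np.array_split(order, cfg.n_cv_folds)
        if all(0 < y[f].sum() < len(f) for f in folds) and all(
            0 < y[np.concatenate([g for j, g in enumerate(folds) if j != i])].sum()
            for i in range(len(folds))
        ):
            break
        logger.warning("single-class fold on attempt %d; refolding", attempt)
    else:
        raise ValueError("could not build folds with both classes")

    pooled = []
    for i, test_idx in enumerate(folds):
        train_idx = np.concatenate([g for j, g in enumerate(folds) if j != i])
        model = model_factory(int(rng.integers(2**31)))
        model.fit([grids[enc_ids[j]] for j in train_idx], y[train_idx])
        test_grids = {enc_ids[j]: grids[enc_ids[j]] for j in test_idx}
        preds = model.predict_cohort(test_grids)
        preds["fold"] = i
        pooled.append(preds)
    return pd.concat(pooled, ignore_index=True)


def run_external_validation(train_grids: dict, train_labels: pd.Series,
                            test_grids: dict, test_labels: pd.Series,
                            model_factory,
                            config: EvalConfig | None = None) -> dict:
    """Train on cohort A, predict cohort B; baselines need no training.

    Returns ``{"model": fitted model, "preds": prediction table}``; curves
    are produced downstream by :func:`hourly_curve` on identical test
    encounters for the sequence model and the baselines.
    """
    overlap = set(train_grids) & set(test_grids)
    if overlap:
        raise ValueError(f"cohorts overlap on {len(overlap)} encounter ids")
    cfg = config or EvalConfig()
    model = model_factory(cfg.seed)
    y_train = train_labels.loc[list(train_grids.keys())].to_numpy(dtype=int)
    model.fit(list(train_grids.values()), y_train)
    preds = model.predict_cohort(test_grids)
    return {"model": model, "preds": preds}


def stratified_mean_probability(preds: pd.DataFrame, labels: pd.Series,
                                alignment: str = "since_admission",
                                config: EvalConfig | None = None) -> pd.DataFrame:
    """Mean predicted probability per hour, stratified by outcome.

    Also reports, per hour, the number of encounters still active (stay not
    yet ended under ``since_admission``) and the death fraction among them.
    Returns columns: alignment, hour, mean_survivor, lo_survivor,
    hi_survivor, mean_nonsurvivor, lo_nonsurvivor, hi_nonsurvivor,
    n_active, active_mortality_rate.
    """
    cfg = config or EvalConfig()
    mat, y, enc_ids = _score_matrix(preds, labels, alignment, cfg.max_hours)
    T_per_enc = preds.groupby("encounter_id")["hour"].max().loc[enc_ids].to_numpy()
    rng = np.random.default_rng(cfg.seed)
    alpha = (1.0 - cfg.ci_level) / 2.0
    rows = []
    for h in range(cfg.max_hours):
        row = {"alignment": alignment,
               "hour": h + 1 if alignment == "since_admission" else h}
        for name, m in (("survivor", y == 0), ("nonsurvivor", y == 1)):
            vals = mat[m, h]
            boots = [
                vals[rng.integers(0, len(vals), size=len(vals))].mean()
                for _ in range(cfg.n_bootstrap)
            ]
            row[f"mean_{name}"] = float(vals.mean())
            row[f"lo_{name}"], row[f"hi_{name}"] = (
                float(v) for v in np.quantile(boots, [alpha, 1 - alpha])
            )
        if alignment == "since_admission":
            active = T_per_enc >= h + 1
        else:
            active = T_per_enc >= h + 1  # stays long enough to look back k hours
        row["n_active"] = int(active.sum())
        row["active_mortality_rate"] = (
            float(y[active].mean()) if active.any() else np.nan
        )
        rows.append(row)
    return pd.DataFrame(rows)


def render_reports(curves: pd.DataFrame, out_dir,
                   stratified: pd.DataFrame | None = None,
                   attention: dict | None = None,
                   grids: dict | None = None) -> list:
    """Write evaluation figures: AUC curves, stratified means, attention maps.

    ``attention`` maps encounter_id -> T x T matrix; for each, a heatmap of
    the full matrix and a diagonal bar strip (aligned with the channel time
    series when ``grids`` is given) are rendered.  Returns written paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    for alignment, grp in curves.groupby("alignment"):
        fig, ax = plt.subplots(figsize=(7, 4))
        if "model" in grp.columns:
            for model, sub in grp.groupby("model"):
                ax.plot(sub["hour"], sub["auc"], label=str(model))
                ax.fill_between(sub["hour"], sub["ci_lo"], sub["ci_hi"], alpha=0.25)
            ax.legend()
        else:
            ax.plot(grp["hour"], grp["auc"])
            ax.fill_between(grp["hour"], grp["ci_lo"], grp["ci_hi"], alpha=0.25)
        ax.set_xlabel(
            "hours since ICU admission" if alignment == "since_admission"
            else "hours before discharge/death"
        )
        ax.set_ylabel("AUC")
        ax.set_ylim(0.4, 1.0)
        path = out / f"auc_{alignment}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)

    if stratified is not None:
        for alignment, grp in stratified.groupby("alignment"):
            fig, ax = plt.subplots(figsize=(7, 4))
            for name, color in (("survivor", "tab:blue"), ("nonsurvivor", "tab:red")):
                ax.plot(grp["hour"], grp[f"mean_{name}"], color=color, label=name)
                ax.fill_between(grp["hour"], grp[f"lo_{name}"], grp[f"hi_{name}"],
                                color=color, alpha=0.25)
            ax2 = ax.twinx()
            ax2.fill_between(grp["hour"], 0, grp["active_mortality_rate"],
                             color="gray", alpha=0.3)
            ax2.set_ylabel("active-encounter mortality rate")
            ax.set_ylabel("mean predicted mortality probability")
            ax.legend()
            path = out / f"stratified_{alignment}.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(path)

    for eid, A in (attention or {}).items():
        fig, axes = plt.subplots(
            2, 1, figsize=(7, 6), gridspec_kw={"height_ratios": [4, 1]}
        )
        axes[0].imshow(A, origin="upper", aspect="auto", cmap="Greys")
        axes[0].set_xlabel("prediction hour")
        axes[0].set_ylabel("attended hour")
        diag = np.diag(A)
        axes[1].bar(np.arange(1, len(diag) + 1), diag, color="black")
        axes[1].set_ylabel("diag")
        path = out / f"attention_{eid}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        written.append(path)
        if grids and eid in grids:
            grid = grids[eid]
            fig, axes = plt.subplots(4, 1, figsize=(7, 8), sharex=True)
            for ax_i, ch in zip(axes[:3], ("MAP", "GCS", "creatinine")):
                ax_i.plot(grid.values.index, grid.values[ch])
                ax_i.set_ylabel(ch)
            axes[3].bar(np.arange(1, len(diag) + 1), diag, color="black")
            axes[3].set_ylabel("attention")
            axes[3].set_xlabel("hours since ICU admission")
            path = out / f"trajectory_{eid}.png"
            fig.savefig(path, dpi=120, bbox_inches="tight")
            plt.close(fig)
            written.append(path)
    return written
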