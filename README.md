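# deepsofa

Continuous, hourly ICU acuity scoring from electronic-health-record time
series, with interpretable attention — plus the traditional SOFA-score
baselines it is measured against, a seeded synthetic-cohort simulator, and
the full hourly evaluation protocol.

## The problem

The SOFA (Sequential Organ Failure Assessment) score summarizes six organ
systems — respiratory, coagulation, liver, cardiovascular, central nervous
system, renal — by applying fixed thresholds to each system's *worst* value
over a trailing window (typically 24 h) and summing the six 0–4 component
scores into a 0–24 total. It is the bedside standard for judging illness
severity and mortality risk in intensive care, but it discards almost all
temporal structure: a patient deteriorating rapidly and a patient recovering
can carry the same score.

This package implements a recurrent alternative: a GRU (gated recurrent
unit) network over the hourly channel matrix of the 13 SOFA input variables
plus SpO2, topped with a **causal self-attention** head. At every hour `t`
of an ICU stay it emits an in-hospital mortality probability `p[t]` using
only hours `1..t`:

```
h_1..h_T        = GRU(x_1..x_T)                      hidden states
e(s,t)          = v · tanh(W h_s + U h_t),  s ≤ t    attention energies
A[s,t]          = softmax_s e(s,t)                   column-stochastic weights
c_t             = Σ_s A[s,t] h_s                     context
p[t]            = σ(w·[h_t ; c_t] + b)               hourly mortality probability
```

The attention matrix `A` is non-negative, zero for `s > t`, and each column
sums to 1 — so for every prediction hour you can read off exactly which
earlier hours the model weighted, and the diagonal `A[t,t]` answers "how
important was each hour's data the moment it arrived".

Two baselines consume the same inputs: **Bedside SOFA** maps the current
trailing-24h SOFA total to a published band-level mortality probability
(band lookup, no training), and **Traditional SOFA** uses the raw total
itself as the ranking statistic for retrospective AUC. A conventional-ML
sensitivity baseline (logistic regression / random forest on 84 causal
aggregate features, 6 statistics × 14 variables) is also included.

Because the real cohorts behind this design require credentialed access,
the package ships a seeded simulator (`deepsofa.simulate`) that emulates
their structure: per-variable sampling frequencies and missingness, an
in-hospital mortality rate near 10.4%, and a latent AR(1) organ-severity
mechanism with a logistic discrete-time hazard, so that trajectories carry
temporal signal that worst-value summaries discard.

## Worked example

```python
from deepsofa import (SimConfig, simulate_cohort, filter_encounters,
                      preprocess_cohort)
from deepsofa.sofa import sofa_table
from deepsofa.model import DeepSofaClassifier

cohort = filter_encounters(simulate_cohort(SimConfig(n_encounters=400, seed=7)))
print(f"encounters: {cohort.n_encounters}, mortality: {cohort.labels().mean():.1%}")

grids, _ = preprocess_cohort(cohort)          # hourly grids with provenance
sofa = sofa_table(grids)                      # hourly SOFA components + total

labels = cohort.labels()
ids = list(grids)
model = DeepSofaClassifier(max_epochs=8, seed=0)
model.fit([grids[i] for i in ids[:300]], labels.loc[ids[:300]].to_numpy(int))

traj = model.predict_trajectory(grids[ids[300]])
print(f"T={len(traj.p)} h, p[1]={traj.p[0]:.3f}, p[T]={traj.p[-1]:.3f}")
```

prints (exact numbers from this seed):

```
encounters: 400, mortality: 11.0%
T=64 h, p[1]=0.400, p[T]=0.183
```

`traj.A` is the 64×64 attention matrix (columns sum to 1; `traj.diag` is
the real-time importance strip), and `sofa` holds one row per
(encounter, hour) with the six components and total — the first encounter
here scores `[0, 0, 1, 1, 1]` over its first five hours. Note that a
400-encounter cohort is only a demo: the sequence model needs on the order
of 1,500+ training stays before it overtakes the SOFA baselines (see the
acceptance run below, where it does).

The same pipeline is scriptable from the shell:

```bash
deepsofa simulate --seed 1 --n 400 --out-dir data/
deepsofa preprocess --events data/events.csv --encounters data/encounters.csv --out grids/
deepsofa sofa --grids grids/ --out sofa.csv
deepsofa baseline --sofa sofa.csv --model bedside --out bedside.csv
deepsofa train --grids grids/ --encounters data/encounters.csv --seed 1 --out model/
deepsofa predict --model model/ --grids grids/ --out preds.csv --attention attn.npz
deepsofa evaluate --preds preds.csv --encounters data/encounters.csv --out curve.csv
deepsofa report --curves curve.csv --attention attn.npz --out figures/
```

## Evaluation protocol

AUC is computed at every hour under two alignments: hours since ICU
admission (encounters already ended contribute their final prediction, so
every hour covers the full cohort — the carry-forward rule) and hours
before discharge/death. Confidence intervals are percentile bootstrap over
encounters (100 resamples); model comparison uses a paired bootstrap with
shared resamples. 5-fold cross-validation and train-on-A/test-on-B
external validation are provided in `deepsofa.evaluation`.

## Layout

| module | contents |
|---|---|
| `deepsofa.cohort` | data model, CSV I/O, outcome labelling, inclusion filtering |
| `deepsofa.simulate` | seeded synthetic-cohort generator + summary table |
| `deepsofa.preprocessing` | outlier removal, FiO2 imputation, hourly grid with provenance |
| `deepsofa.sofa` | trailing-24h worst values and SOFA component/total scoring |
| `deepsofa.baselines` | Bedside/Traditional SOFA + aggregate-feature models |
| `deepsofa.model` | `DeepSofaClassifier` (GRU + causal self-attention, numpy autodiff) |
| `deepsofa.evaluation` | hourly AUC curves, bootstrap CIs, CV/external validation, reports |
| `deepsofa.config` | shipped YAML tables (cleaning rules, normal values, FiO2 map, SOFA cuts, Bedside bands) |

`docs/methods.md` documents the model, the simulator's assumptions and
every configurable table in detail.
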