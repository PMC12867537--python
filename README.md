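# strokerecovnet

EEG-based prediction of upper-limb motor recovery after stroke.

After a stroke, most patients regain roughly 70% of their lost
upper-extremity function — the *proportional recovery rule* (PRR):

```
ΔFMAUE = β (66 − FMAUE_T0) + C,        β = 0.7,  C = 0.4
```

where FMAUE is the Fugl-Meyer Assessment of the Upper Extremity
(0–66, higher = better).  A sizeable minority of "non-recoverers"
deviates badly from this rule, and identifying them early is the central
problem of neurorehabilitation prognosis.  `strokerecovnet` implements a
resting-state-EEG pipeline for this task:

1. **Biomarker extraction** — 221 quantitative EEG features per 10-s
   window: relative band powers, delta/alpha ratio (DAR), DTABR,
   pairwise-derived brain symmetry index (pdBSI) and its directional
   variant, individual alpha frequency, plus imaginary-coherency
   functional-connectivity graphs over six scalp regions with weighted
   network metrics (degree, strength, path length, Onnela clustering,
   small-world ω, rich club, nodal motor-ROI metrics).
2. **Regression model** — a small feed-forward ReLU network
   (*StrokeRecovNet*) mapping up to four selected EEG features plus three
   clinical inputs (baseline FMAUE, days since stroke, days to follow-up)
   onto the follow-up FMAUE, with window-median aggregation per subject.
3. **Honest evaluation** — nested leave-one-subject-out cross-validation
   over a hyperparameter grid (window overlap, ReliefF/mRMR selection,
   feature subset, layer configuration, batch size), compared against the
   PRR baseline by median absolute error and paired permutation tests.
4. **Feature-consistency analysis** — domain- and cluster-level agreement
   of selected features across models (hierarchical clustering of
   |Spearman ρ|, Jaccard similarity).
5. **Synthetic cohorts** — a generator producing 50-channel recordings
   with band-limited oscillations, hemispheric asymmetries, 1/f noise,
   lagged inter-regional coupling and outcomes tied to the PRR and
   (optionally) to a planted EEG effect, so every stage is testable
   without clinical data.

The package is aimed at researchers in clinical neurophysiology and
machine-learning methodologists who want a fully reproducible, leakage-
audited reference implementation of this kind of prognosis pipeline.

## Worked example

```python
import numpy as np
from strokerecovnet import (
    SimConfig, simulate_cohort, feature_table,
    nested_loso, prr_evaluate,
)
from strokerecovnet.evaluation import reduced_grid

cohort = simulate_cohort(SimConfig(n_subjects=10, seed=7))
feats = {0.0: feature_table(cohort.records, cohort.recordings,
                            overlap_fraction=0.0, seed=0)}
report = nested_loso(cohort.records, feats, reduced_grid(), seed=7)

results, _ = prr_evaluate(cohort.records)
prr = {r.subject_id: r.abs_error for r in results}
print("model MAE:", round(report.median, 2))
print("PRR   MAE:", round(float(np.median([prr[i] for i in report.subject_ids])), 2))
```

Output:

```
model MAE: 4.23
PRR   MAE: 7.35
```

The synthetic cohort plants a 10-FMAUE-points-per-σ effect of central
hemispheric delta asymmetry (visible to the pipeline as the central
directional pdBSI) on top of proportional recovery.  The nested-LOSO
model recovers part of that signal and roughly halves the median absolute
error of the PRR baseline; with `outcome="prr_only"` the two are
statistically indistinguishable, as they should be.

The clinical benchmark on the packaged cohort tables:

```bash
strokerecovnet prr --cohort fdg_table --exclusions baseline_ceiling,followup_ceiling
```

```json
{
  "median": 18.999999999999993,
  "iqr": 37.5,
  "n_tested": 13,
  "n_norec": 6
}
```

A median PRR error of 19 FMAUE points in the subacute cohort means the
proportional rule is a weak prognosis there — the room the EEG model is
meant to close.

## Command line

`simulate`, `extract-features`, `prr`, `train`, `consistency` and
`stats` subcommands cover the full pipeline; see
`strokerecovnet --help`.

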