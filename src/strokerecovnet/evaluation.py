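"""Nested leave-one-subject-out cross-validation and statistics.

For every outer test subject, an inner LOSO loop scores each
hyperparameter grid point (epoch overlap, feature-selection method,
feature subset of the fold's top four, layer configuration, batch size)
by the RMSE of subject-level (window-median) predictions on the inner
left-out subjects.  The RMSE-minimizing grid point is retrained on all
non-test subjects and produces one prediction for the test subject.

Ceiling subjects (baseline FMAUE = 66, optionally also follow-up = 66)
are excluded from testing and from inner validation but retained for
training throughout.

Leakage contract: rankings, standardization statistics and weights are
always computed on training rows only; no test-subject epoch can reach
them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .core import PatientRecord
from .features import CLINICAL_FEATURES, EEG_FEATURE_NAMES, feature_domain
from .recovnet import BATCH_SIZES, HIDDEN_CONFIGS, NetConfig, predict_subject, train
from .selection import RankedFeatures, mrmr_rank, positional_subsets, relieff_rank

__all__ = [
    "GridPoint",
    "make_grid",
    "FoldResult",
    "CVReport",
    "nested_loso",
    "median_abs_error",
    "selection_frequency",
    "paired_permutation_test",
    "group_feature_tests",
]

TOP_M = 4
FMAUE_MAX = 66


@dataclass(frozen=True)
class GridPoint:
    overlap: float
    selector: str                 # "relieff" | "mrmr"
    subset: Tuple[int, ...]       # positions within the fold's top-4 ranking
    hidden_layers: Tuple[int, ...]
    batch_size: object


def make_grid(
    overlaps: Sequence[float] = (0.0, 0.25, 0.5, 0.75),
    selectors: Sequence[str] = ("relieff", "mrmr"),
    subsets: Sequence[Tuple[int, ...]] | None = None,
    hidden_configs: Sequence[Tuple[int, ...]] = HIDDEN_CONFIGS,
    batch_sizes: Sequence[object] = BATCH_SIZES,
) -> List[GridPoint]:
    """The hyperparameter grid in canonical (tie-breaking) order:
    less overlap first, then selector, feature subset, smaller network,
    smaller batch."""
    subsets = list(subsets) if subsets is not None else positional_subsets(TOP_M)
    grid = []
    for ov in overlaps:
        for sel in selectors:
            for sub in subsets:
                for hid in hidden_configs:
                    for bs in batch_sizes:
                        grid.append(GridPoint(ov, sel, tuple(sub), tuple(hid), bs))
    if not grid:
        raise ValueError("empty hyperparameter grid")
    return grid


def reduced_grid() -> List[GridPoint]:
    """Desk-scale grid: no overlap, mRMR, all 15 top-4 subsets, one (8,)
    hidden layer, batch 64 (mini-batches converge within the fixed
    20-epoch budget; full batch does not)."""
    return make_grid(
        overlaps=(0.0,), selectors=("mrmr",),
        hidden_configs=((8,),), batch_sizes=(64,),
    )


@dataclass
class FoldResult:
    subject_id: str
    grid_point: GridPoint
    selected_features: Tuple[str, ...]   # EEG features of the final model
    inner_rmse: float
    prediction: float
    truth: float
    abs_error: float
    inner_rmse_by_grid: Dict[GridPoint, float] = field(default_factory=dict)


@dataclass
class CVReport:
    folds: List[FoldResult]
    median: float
    iqr: float

    @property
    def abs_errors(self) -> np.ndarray:
        return np.array([f.abs_error for f in self.folds])

    @property
    def subject_ids(self) -> List[str]:
        return [f.subject_id for f in self.folds]


class _OverlapData:
    """Column-indexed numpy view of one overlap's feature table."""

    def __init__(self, df: pd.DataFrame):
        self.ids = df["subject_id"].to_numpy()
        self.X = df[list(EEG_FEATURE_NAMES)].to_numpy(dtype=float)
        self.clin = df[list(CLINICAL_FEATURES)].to_numpy(dtype=float)
        self.y = df["fmaue_T1"].to_numpy(dtype=float)
        self.col = {name: j for j, name in enumerate(EEG_FEATURE_NAMES)}
        self.subject_rows = {
            sid: np.nonzero(self.ids == sid)[0] for sid in np.unique(self.ids)
        }

    def rows_for(self, subjects: Iterable[str]) -> np.ndarray:
        return np.concatenate([self.subject_rows[s] for s in subjects])

    def design(self, rows: np.ndarray, eeg_features: Sequence[str]) -> np.ndarray:
        cols = [self.col[f] for f in eeg_features]
        return np.column_stack([self.X[np.ix_(rows, cols)], self.clin[rows]])


def _rank(
    data: _OverlapData, train_subjects: Tuple[str, ...], selector: str, relieff_k: int
) -> RankedFeatures:
    rows = data.rows_for(train_subjects)
    X, y = data.X[rows], data.y[rows]
    if selector == "relieff":
        return relieff_rank(X, y, EEG_FEATURE_NAMES, k=relieff_k)
    if selector == "mrmr":
        return mrmr_rank(X, y, EEG_FEATURE_NAMES)
    raise ValueError(f"unknown selector {selector!r}")


def _net_seed(seed: int, *parts: int) -> int:
    return int(np.random.SeedSequence([seed, *parts]).generate_state(1)[0] % (2**31))


def nested_loso(
    cohort: Sequence[PatientRecord],
    features_by_overlap: Mapping[float, pd.DataFrame],
    grid: Sequence[GridPoint],
    exclusions: Iterable[str] = ("baseline_ceiling",),
    seed: int = 0,
    relieff_k: int = 10,
) -> CVReport:
    """Run the full nested LOSO evaluation and return per-subject results."""
    if not grid:
        raise ValueError("empty hyperparameter grid")
    exclusions = set(exclusions)
    records = {r.subject_id: r for r in cohort}
    all_ids = [r.subject_id for r in cohort]

    def testable(r: PatientRecord) -> bool:
        if "baseline_ceiling" in exclusions and r.fmaue_T0 == FMAUE_MAX:
            return False
        if "followup_ceiling" in exclusions and r.fmaue_T1 == FMAUE_MAX:
            return False
        return True

    test_ids = [sid for sid in all_ids if testable(records[sid])]
    if len(test_ids) < 3:
        raise ValueError(f"need >= 3 testable subjects, have {len(test_ids)}")

    data = {ov: _OverlapData(df) for ov, df in features_by_overlap.items()}
    for sid in all_ids:
        for ov, d in data.items():
            if sid not in d.subject_rows:
                raise ValueError(f"subject {sid} has no epochs at overlap {ov}")

    rank_cache: Dict[tuple, RankedFeatures] = {}

    def cached_rank(ov: float, selector: str, train_subjects: Tuple[str, ...]) -> RankedFeatures:
        key = (ov, selector, train_subjects)
        if key not in rank_cache:
            rank_cache[key] = _rank(data[ov], train_subjects, selector, relieff_k)
        return rank_cache[key]

    folds: List[FoldResult] = []
    for o_idx, test_id in enumerate(test_ids):
        inner_ids = tuple(s for s in all_ids if s != test_id)
        inner_val = [s for s in inner_ids if testable(records[s])]
        # score each grid point by subject-level RMSE over inner folds
        rmse_by_grid: Dict[GridPoint, float] = {}
        for g_idx, gp in enumerate(grid):
            d = data[gp.overlap]
            sq_errors = []
            for v_idx, v_id in enumerate(inner_val):
                train_subjects = tuple(s for s in inner_ids if s != v_id)
                ranking = cached_rank(gp.overlap, gp.selector, train_subjects)
                feats = tuple(ranking.names[i] for i in gp.subset)
                rows_tr = d.rows_for(train_subjects)
                cfg = NetConfig(
                    hidden_layers=gp.hidden_layers,
                    batch_size=gp.batch_size,
                    seed=_net_seed(seed, o_idx, v_idx, g_idx),
                )
                model = train(
                    d.design(rows_tr, feats), d.y[rows_tr], cfg,
                    feature_names=feats + CLINICAL_FEATURES,
                )
                rows_v = d.subject_rows[v_id]
                pred = predict_subject(model, d.design(rows_v, feats)).clipped
                sq_errors.append((pred - records[v_id].fmaue_T1) ** 2)
            rmse_by_grid[gp] = float(np.sqrt(np.mean(sq_errors)))

        best_idx = int(np.argmin([rmse_by_grid[gp] for gp in grid]))
        best = grid[best_idx]
        # final model: re-rank on all non-test subjects, retrain, predict test
        d = data[best.overlap]
        ranking = cached_rank(best.overlap, best.selector, inner_ids)
        feats = tuple(ranking.names[i] for i in best.subset)
        rows_tr = d.rows_for(inner_ids)
        cfg = NetConfig(
            hidden_layers=best.hidden_layers,
            batch_size=best.batch_size,
            seed=_net_seed(seed, o_idx, 9999, best_idx),
        )
        model = train(
            d.design(rows_tr, feats), d.y[rows_tr], cfg,
            feature_names=feats + CLINICAL_FEATURES,
        )
        pred = predict_subject(model, d.design(d.subject_rows[test_id], feats)).clipped
        truth = float(records[test_id].fmaue_T1)
        folds.append(
            FoldResult(
                subject_id=test_id,
                grid_point=best,
                selected_features=feats,
                inner_rmse=rmse_by_grid[best],
                prediction=pred,
                truth=truth,
                abs_error=abs(pred - truth),
                inner_rmse_by_grid=rmse_by_grid,
            )
        )

    med, iqr = median_abs_error(
        [f.prediction for f in folds], [f.truth for f in folds]
    )
    return CVReport(folds=folds, median=med, iqr=iqr)


def median_abs_error(
    predictions: Sequence[float], truths: Sequence[float]
) -> Tuple[float, float]:
    """Median and interquartile range of |prediction - truth|."""
    predictions = np.asarray(predictions, dtype=float)
    truths = np.asarray(truths, dtype=float)
    if predictions.size == 0 or predictions.shape != truths.shape:
        raise ValueError("predictions/truths must be equal-length and non-empty")
    err = np.abs(predictions - truths)
    return float(np.median(err)), float(
        np.percentile(err, 75) - np.percentile(err, 25)
    )


def selection_frequency(report: CVReport) -> Tuple[Dict[str, float], Dict[str, float]]:
    """Per-feature and per-domain selection frequencies across outer folds.

    The domain frequency is the fraction of folds whose final model
    included at least one feature of that domain."""
    if not report.folds:
        raise ValueError("empty report")
    n = len(report.folds)
    per_feature: Dict[str, float] = {}
    domains = ("spectral", "brain symmetry", "node connectivity", "network")
    per_domain = {d: 0.0 for d in domains}
    for fold in report.folds:
        for f in set(fold.selected_features):
            per_feature[f] = per_feature.get(f, 0.0) + 1.0
        fold_domains = {feature_domain(f) for f in fold.selected_features}
        for dmn in fold_domains & set(domains):
            per_domain[dmn] += 1.0
    per_feature = {k: v / n for k, v in sorted(per_feature.items())}
    per_domain = {k: v / n for k, v in per_domain.items()}
    return per_feature, per_domain


def paired_permutation_test(
    errors_A: Sequence[float],
    errors_B: Sequence[float],
    n_perm: int = 10000,
    seed: int = 0,
) -> Tuple[float, float]:
    """Paired sign-flip permutation test on the median error difference.

    Returns (two-sided p-value with +1 smoothing, observed median of
    A - B)."""
    a = np.asarray(errors_A, dtype=float)
    b = np.asarray(errors_B, dtype=float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need paired vectors of equal length >= 2")
    diff = a - b
    stat = float(np.median(diff))
    rng = np.random.default_rng(seed)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, diff.size))
    null = np.median(signs * diff, axis=1)
    p = (1.0 + np.sum(np.abs(null) >= abs(stat))) / (n_perm + 1.0)
    return float(p), stat


def group_feature_tests(
    feature_frame: pd.DataFrame,
    labels: Sequence[str],
    tested_features: Sequence[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Window-level Mann-Whitney U comparisons between recoverers and
    non-recoverers for each tested feature, with Bonferroni correction
    by the number of tested features and Cohen's d via pooled SD."""
    labels = np.asarray(labels)
    rec = labels == "REC"
    norec = labels == "NO-REC"
    if rec.sum() == 0 or norec.sum() == 0:
        raise ValueError("both REC and NO-REC groups must be non-empty")
    k = len(tested_features)
    rows = []
    for feat in tested_features:
        x = feature_frame.loc[rec, feat].to_numpy(dtype=float)
        y = feature_frame.loc[norec, feat].to_numpy(dtype=float)
        U, p = sstats.mannwhitneyu(x, y, alternative="two-sided")
        nx, ny = len(x), len(y)
        pooled = np.sqrt(
            ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
        )
        d = (x.mean() - y.mean()) / pooled if pooled > 0 else 0.0
        rows.append(
            {
                "feature": feat,
                "U": float(U),
                "p": float(p),
                "p_bonferroni": float(min(1.0, p * k)),
                "cohens_d": float(d),
                "significant": bool(p < alpha / k),
            }
        )
    return pd.DataFrame(rows)
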