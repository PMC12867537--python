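"""Proportional recovery rule (PRR) baseline.

Expected recovery after stroke is modelled as a fixed proportion of the
lost function: delta_FMAUE = beta * (66 - FMAUE_T0) + C with beta = 0.7
and C = 0.4.  Patients whose observed recovery deviates from this
prediction by less than 20 FMAUE points are recoverers (REC); the rest
are non-recoverers (NO-REC).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple

import numpy as np

from .core import PatientRecord

__all__ = ["PRRParams", "PRRResult", "PRRSummary", "prr_predict", "prr_evaluate"]

FMAUE_MAX = 66


@dataclass(frozen=True)
class PRRParams:
    beta: float = 0.7
    C: float = 0.4
    rec_threshold: float = 20.0

    def __post_init__(self) -> None:
        if not 0 < self.beta <= 1:
            raise ValueError(f"beta must be in (0, 1], got {self.beta}")
        if self.rec_threshold <= 0:
            raise ValueError("rec_threshold must be positive")


@dataclass(frozen=True)
class PRRResult:
    subject_id: str
    predicted_delta: float
    actual_delta: float
    abs_error: float
    label: str            # REC / NO-REC
    excluded: bool        # excluded from the error summary (ceiling rules)


@dataclass(frozen=True)
class PRRSummary:
    median: float
    iqr: float
    n_tested: int
    n_norec: int


def prr_predict(fmaue_T0: float, params: PRRParams = PRRParams()) -> float:
    """Predicted FMAUE gain: beta * (66 - FMAUE_T0) + C."""
    if not 0 <= fmaue_T0 <= FMAUE_MAX:
        raise ValueError(f"FMAUE_T0={fmaue_T0} outside [0, {FMAUE_MAX}]")
    return params.beta * (FMAUE_MAX - fmaue_T0) + params.C


def prr_evaluate(
    cohort: Sequence[PatientRecord],
    params: PRRParams = PRRParams(),
    exclusions: Iterable[str] = ("baseline_ceiling",),
) -> Tuple[List[PRRResult], PRRSummary]:
    """Per-patient PRR errors plus a median/IQR summary.

    ``exclusions`` controls which patients are removed from the error
    summary: ``baseline_ceiling`` drops FMAUE_T0 = 66, and
    ``followup_ceiling`` additionally drops FMAUE_T1 = 66.  REC/NO-REC
    labels and counts are computed over *all* patients (REC = strict
    abs_error < rec_threshold).
    """
    if not cohort:
        raise ValueError("empty cohort")
    exclusions = set(exclusions)
    unknown = exclusions - {"baseline_ceiling", "followup_ceiling"}
    if unknown:
        raise ValueError(f"unknown exclusion rules: {sorted(unknown)}")
    results: List[PRRResult] = []
    for p in cohort:
        pred = prr_predict(p.fmaue_T0, params)
        actual = float(p.fmaue_T1 - p.fmaue_T0)
        err = abs(pred - actual)
        excluded = ("baseline_ceiling" in exclusions and p.fmaue_T0 == FMAUE_MAX) or (
            "followup_ceiling" in exclusions and p.fmaue_T1 == FMAUE_MAX
        )
        results.append(
            PRRResult(
                subject_id=p.subject_id,
                predicted_delta=pred,
                actual_delta=actual,
                abs_error=err,
                label="REC" if err < params.rec_threshold else "NO-REC",
                excluded=excluded,
            )
        )
    tested = [r.abs_error for r in results if not r.excluded]
    if not tested:
        raise ValueError("all patients excluded by the ceiling rules")
    tested_arr = np.asarray(tested)
    summary = PRRSummary(
        median=float(np.median(tested_arr)),
        iqr=float(np.percentile(tested_arr, 75) - np.percentile(tested_arr, 25)),
        n_tested=len(tested),
        n_norec=sum(r.label == "NO-REC" for r in results),
    )
    return results, summary
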