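"""Feature registry and per-epoch feature-table assembly.

Each 10-s epoch yields 221 EEG features (141 spectral/symmetry + 80
connectivity/network) plus the three fixed clinical inputs (baseline
FMAUE, days since stroke at baseline, days at follow-up): 224 columns.

Domains used by the consistency analyses:

- ``spectral``          relative power, DAR, DTABR, IAF
- ``brain symmetry``    pdBSI, dirpdBSI
- ``node connectivity`` nodal graph metrics of the motor ROIs
- ``network``           global graph metrics
- ``clinical``          the three fixed inputs (never ranked/selected)
"""

from __future__ import annotations

from typing import Dict, List, Sequence

import pandas as pd

from .connectivity import CONNECTIVITY_FEATURE_NAMES, connectivity_block
from .core import EEGRecording, PatientRecord, ROILayout, extract_epochs, swap_hemispheres
from .spectral import SPECTRAL_FEATURE_NAMES, spectral_block, welch_psd

__all__ = [
    "CLINICAL_FEATURES",
    "EEG_FEATURE_NAMES",
    "ALL_FEATURE_NAMES",
    "feature_domain",
    "feature_registry",
    "epoch_features",
    "feature_table",
]

CLINICAL_FEATURES = ("fmaue_T0", "days_T0", "days_T1")
EEG_FEATURE_NAMES = SPECTRAL_FEATURE_NAMES + CONNECTIVITY_FEATURE_NAMES
ALL_FEATURE_NAMES = EEG_FEATURE_NAMES + CLINICAL_FEATURES
assert len(EEG_FEATURE_NAMES) == 221 and len(ALL_FEATURE_NAMES) == 224


def feature_domain(name: str) -> str:
    if name in CLINICAL_FEATURES:
        return "clinical"
    family = name.split("_", 1)[0]
    if family in ("pdbsi", "dirpdbsi"):
        return "brain symmetry"
    if family == "node":
        return "node connectivity"
    if family == "net":
        return "network"
    return "spectral"


def feature_registry() -> pd.DataFrame:
    """Inventory of the 224 features: name, family, band, scope, domain."""
    rows = []
    for name in ALL_FEATURE_NAMES:
        parts = name.split("_")
        family = parts[0]
        band = next((p for p in parts[1:] if p in
                     ("delta", "theta", "alpha", "beta", "gamma", "broadband")), "")
        scope = parts[-1] if parts[-1] not in ("T0", "T1") else ""
        rows.append(
            {"name": name, "family": family, "band": band,
             "scope": scope, "domain": feature_domain(name)}
        )
    return pd.DataFrame(rows)


def epoch_features(epoch, layout: ROILayout, seed: int = 0) -> Dict[str, float]:
    """221 EEG features of one (already hemisphere-swapped) epoch."""
    out = dict(spectral_block(welch_psd(epoch), layout))
    out.update(connectivity_block(epoch, layout, seed=seed))
    return out


def feature_table(
    records: Sequence[PatientRecord],
    recordings: Dict[str, EEGRecording],
    layout: ROILayout | None = None,
    overlap_fraction: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format table: one row per (subject, epoch) with the 224
    feature columns plus ``subject_id``, ``epoch_index`` and the
    regression target ``fmaue_T1``.

    The hemisphere swap is applied here, so downstream features always
    see the affected hemisphere on the right-side labels.
    """
    layout = layout or ROILayout()
    frames: List[dict] = []
    for rec in records:
        eeg = recordings[rec.subject_id]
        swapped = swap_hemispheres(eeg)
        for ep in extract_epochs(swapped, overlap_fraction=overlap_fraction):
            row = {"subject_id": rec.subject_id, "epoch_index": ep.epoch_index}
            row.update(epoch_features(ep, layout, seed=seed))
            row["fmaue_T0"] = float(rec.fmaue_T0)
            row["days_T0"] = float(rec.days_T0)
            row["days_T1"] = float(rec.days_T1)
            row["fmaue_T1"] = float(rec.fmaue_T1)
            frames.append(row)
    return pd.DataFrame(frames)
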