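"""Domain types, montage/ROI definitions, cohort and EEG I/O, and epoching.

The scalp montage follows the extended 10-10 system.  Fifty lateral
channels are grouped into six regions of interest (ROIs): frontal,
central and occipital, on each hemisphere.  After the hemisphere swap
(applied to left-lesion patients) the *right*-labelled channels always
carry the affected hemisphere, so "AH" (affected) maps onto the
right-side ROIs and "UH" (unaffected) onto the left-side ones.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "ROI_CHANNELS",
    "BANDS",
    "BAND_ORDER",
    "EEGRecording",
    "PatientRecord",
    "ROILayout",
    "Epoch",
    "MontageError",
    "CohortError",
    "swap_hemispheres",
    "extract_epochs",
    "read_cohort",
    "read_eeg",
]


class MontageError(ValueError):
    """Channel-layout problem (missing channels, missing homologues)."""


class CohortError(ValueError):
    """Invalid cohort table (range violations, missing columns, empty)."""


# ---------------------------------------------------------------------------
# Montage / ROI definitions
# ---------------------------------------------------------------------------

ROI_CHANNELS: Dict[str, Tuple[str, ...]] = {
    "FR": ("Fp2", "AF4", "AF8", "F2", "F4", "F6", "F8"),
    "FL": ("Fp1", "AF3", "AF7", "F1", "F3", "F5", "F7"),
    "CR": ("FC2", "FC4", "FC6", "FT8", "C2", "C4", "C6", "T4", "CP2", "CP4", "CP6"),
    "CL": ("FC1", "FC3", "FC5", "FT7", "C1", "C3", "C5", "T3", "CP1", "CP3", "CP5"),
    "OR": ("P2", "P4", "P6", "T6", "PO8", "PO4", "O2"),
    "OL": ("P1", "P3", "P5", "T5", "PO7", "PO3", "O1"),
}

#: canonical EEG bands in Hz; intervals are lower-closed / upper-open for
#: discrete bin membership, except that 48 Hz closes the gamma band.
BANDS: Dict[str, Tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 48.0),
    "broadband": (1.0, 48.0),
}

BAND_ORDER: Tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

# modern 10-10 names mapped onto the classical labels used by the ROI lists
_LABEL_ALIASES = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}

_ALL_LATERAL: Tuple[str, ...] = tuple(
    ch for roi in ("FR", "FL", "CR", "CL", "OR", "OL") for ch in ROI_CHANNELS[roi]
)

_CANON = {lab.upper(): lab for lab in _ALL_LATERAL}
_CANON.update({k.upper(): v for k, v in _LABEL_ALIASES.items()})

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(\d+)$")


def normalize_label(label: str) -> str:
    """Map a raw channel label onto its canonical montage spelling."""
    lab = label.strip()
    return _CANON.get(lab.upper(), lab)


def homologue(label: str) -> str | None:
    """Homologous channel across the midline, derived from 10-10 digit
    parity (odd = left, even = right).  Returns None for midline or
    non-numbered labels (Fz, Cz, Oz, ...)."""
    m = _LABEL_RE.match(label)
    if not m:
        return None
    prefix, num = m.group(1), int(m.group(2))
    other = num + 1 if num % 2 == 1 else num - 1
    return f"{prefix}{other}"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ROILayout:
    """Six lateral ROIs plus their merged and hemispheric unions."""

    rois: Dict[str, Tuple[str, ...]] = field(
        default_factory=lambda: dict(ROI_CHANNELS)
    )

    def __post_init__(self) -> None:
        sizes = {k: len(v) for k, v in self.rois.items()}
        if not (sizes["FR"] == sizes["FL"] and sizes["CR"] == sizes["CL"]
                and sizes["OR"] == sizes["OL"]):
            raise MontageError(f"unbalanced hemispheric ROIs: {sizes}")
        flat = [ch for v in self.rois.values() for ch in v]
        if len(flat) != len(set(flat)):
            raise MontageError("lateral ROIs are not pairwise disjoint")

    @property
    def merged(self) -> Dict[str, Tuple[str, ...]]:
        r = self.rois
        return {
            "F": r["FR"] + r["FL"],
            "C": r["CR"] + r["CL"],
            "O": r["OR"] + r["OL"],
        }

    @property
    def affected_hemisphere(self) -> Tuple[str, ...]:
        """Right-side channels: the affected hemisphere after the swap."""
        r = self.rois
        return r["FR"] + r["CR"] + r["OR"]

    @property
    def unaffected_hemisphere(self) -> Tuple[str, ...]:
        r = self.rois
        return r["FL"] + r["CL"] + r["OL"]

    @property
    def all_lateral(self) -> Tuple[str, ...]:
        return self.affected_hemisphere + self.unaffected_hemisphere

    def scope_channels(self, scope: str) -> Tuple[str, ...]:
        """Channels of a named scope: a lateral ROI, a merged ROI, 'AH',
        'UH' or 'avg' (all 50 lateral channels)."""
        if scope in self.rois:
            return self.rois[scope]
        if scope in ("F", "C", "O"):
            return self.merged[scope]
        if scope == "AH":
            return self.affected_hemisphere
        if scope == "UH":
            return self.unaffected_hemisphere
        if scope == "avg":
            return self.all_lateral
        raise KeyError(f"unknown scope {scope!r}")


@dataclass
class EEGRecording:
    """Multichannel resting-state EEG for one subject (µV)."""

    subject_id: str
    fs: float
    channel_labels: List[str]
    data: np.ndarray
    lesion_side: str  # {"left", "right"}

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if self.lesion_side not in ("left", "right"):
            raise ValueError(f"lesion_side must be left/right, got {self.lesion_side!r}")
        self.channel_labels = [normalize_label(l) for l in self.channel_labels]
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"data shape {self.data.shape} does not match "
                f"{len(self.channel_labels)} channel labels"
            )
        missing = [ch for ch in _ALL_LATERAL if ch not in self.channel_labels]
        if missing:
            raise MontageError(
                f"recording {self.subject_id!r} is missing required lateral "
                f"channels: {', '.join(missing)}"
            )
        if not np.isfinite(self.data).all():
            raise ValueError(f"recording {self.subject_id!r} has non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel(self, label: str) -> np.ndarray:
        return self.data[self.channel_labels.index(normalize_label(label))]


@dataclass(frozen=True)
class PatientRecord:
    """One row of a cohort table."""

    subject_id: str
    sex: str
    age: float
    affected_hemisphere: str  # {"L", "R"}
    days_T0: float
    days_T1: float
    fmaue_T0: int
    fmaue_T1: int

    def __post_init__(self) -> None:
        if self.affected_hemisphere not in ("L", "R"):
            raise CohortError(
                f"subject {self.subject_id}: unknown hemisphere code "
                f"{self.affected_hemisphere!r}"
            )
        for name in ("fmaue_T0", "fmaue_T1"):
            v = getattr(self, name)
            if not 0 <= v <= 66:
                raise CohortError(
                    f"subject {self.subject_id}: {name}={v} outside [0, 66]"
                )
        if self.days_T1 <= self.days_T0:
            raise CohortError(
                f"subject {self.subject_id}: follow-up day {self.days_T1} "
                f"not after baseline day {self.days_T0}"
            )

    @property
    def lesion_side(self) -> str:
        return "left" if self.affected_hemisphere == "L" else "right"


@dataclass
class Epoch:
    """A 10-s analysis window cut from the central 180 s."""

    subject_id: str
    epoch_index: int
    start_s: float
    fs: float
    channel_labels: List[str]
    data: np.ndarray

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] / self.fs

    def channel_rows(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self.channel_labels.index(normalize_label(l)) for l in labels]
        return self.data[idx]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def swap_hemispheres(recording: EEGRecording, force: bool = False) -> EEGRecording:
    """Exchange homologous left/right channel signals for left-lesion
    recordings so the right side always carries the affected hemisphere.

    Right-lesion recordings are returned unchanged (identity) unless
    ``force`` is set.  Midline and non-numbered channels are untouched.
    """
    if recording.lesion_side == "right" and not force:
        return recording
    labels = recording.channel_labels
    index = {lab: i for i, lab in enumerate(labels)}
    data = recording.data.copy()
    done = set()
    for lab in labels:
        if lab in done:
            continue
        hom = homologue(lab)
        if hom is None:
            continue
        if lab in _ALL_LATERAL and hom not in index:
            raise MontageError(
                f"cannot swap hemispheres: homologue {hom} of lateral channel "
                f"{lab} is absent"
            )
        if hom in index:
            i, j = index[lab], index[hom]
            data[[i, j]] = data[[j, i]]
            done.update((lab, hom))
    return replace(recording, data=data)


CENTRAL_WINDOW_S = 180.0
EPOCH_LEN_S = 10.0
OVERLAP_CHOICES = (0.0, 0.25, 0.5, 0.75)


def extract_epochs(
    recording: EEGRecording,
    epoch_len: float = EPOCH_LEN_S,
    overlap_fraction: float = 0.0,
) -> List[Epoch]:
    """Cut fixed-length epochs from the temporally central 180 s.

    The step between consecutive epochs is ``epoch_len * (1 - overlap)``;
    the number of epochs is ``floor((180 - epoch_len)/step) + 1``.
    """
    if overlap_fraction not in OVERLAP_CHOICES:
        raise ValueError(
            f"overlap_fraction must be one of {OVERLAP_CHOICES}, got {overlap_fraction}"
        )
    dur = recording.duration_s
    if dur < CENTRAL_WINDOW_S - 1e-9:
        raise ValueError(
            f"recording {recording.subject_id!r} lasts {dur:.1f} s; "
            f"{CENTRAL_WINDOW_S - dur:.1f} s short of the {CENTRAL_WINDOW_S:.0f} s "
            "analysis window"
        )
    fs = recording.fs
    central_start = (dur - CENTRAL_WINDOW_S) / 2.0
    step = epoch_len * (1.0 - overlap_fraction)
    n_epochs = int(np.floor((CENTRAL_WINDOW_S - epoch_len) / step + 1e-9)) + 1
    n_samp = int(round(epoch_len * fs))
    epochs = []
    for k in range(n_epochs):
        t0 = central_start + k * step
        i0 = int(round(t0 * fs))
        epochs.append(
            Epoch(
                subject_id=recording.subject_id,
                epoch_index=k,
                start_s=t0,
                fs=fs,
                channel_labels=list(recording.channel_labels),
                data=recording.data[:, i0 : i0 + n_samp],
            )
        )
    return epochs


_COHORT_COLUMNS = [
    "subject_id", "sex", "age", "affected_hemisphere",
    "days_T0", "days_T1", "fmaue_T0", "fmaue_T1",
]


def read_cohort(path: str | Path) -> List[PatientRecord]:
    """Read a cohort CSV into validated :class:`PatientRecord` rows."""
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in _COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise CohortError(f"cohort file {path} lacks columns: {missing}")
    if df.empty:
        raise CohortError(f"cohort file {path} contains no patients")
    return [
        PatientRecord(
            subject_id=str(r.subject_id),
            sex=str(r.sex),
            age=float(r.age),
            affected_hemisphere=str(r.affected_hemisphere).strip().upper(),
            days_T0=float(r.days_T0),
            days_T1=float(r.days_T1),
            fmaue_T0=int(r.fmaue_T0),
            fmaue_T1=int(r.fmaue_T1),
        )
        for r in df.itertuples(index=False)
    ]


def read_eeg(
    path: str | Path,
    format: str | None = None,
    lesion_side: str = "right",
    subject_id: str | None = None,
) -> EEGRecording:
    """Read one EEG recording from EDF or a delimited channel x sample
    matrix with a JSON sidecar ``{"labels": [...], "fs": <Hz>}``.

    EDF values are converted to µV; channel labels are normalized to the
    montage spelling.  Missing required channels are reported by name.
    """
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "csv-matrix"
    if format == "edf":
        import mne

        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        data = raw.get_data() * 1e6  # volts -> µV
        labels = list(raw.ch_names)
        fs = float(raw.info["sfreq"])
    elif format == "csv-matrix":
        sidecar = path.with_suffix(".json")
        if not sidecar.exists():
            raise FileNotFoundError(f"sidecar {sidecar} for matrix {path} not found")
        meta = json.loads(sidecar.read_text())
        labels = list(meta["labels"])
        fs = float(meta["fs"])
        data = np.loadtxt(path, delimiter=",", ndmin=2)
        if data.shape[0] != len(labels) and data.shape[1] == len(labels):
            data = data.T
    else:
        raise ValueError(f"unknown EEG format {format!r}")
    return EEGRecording(
        subject_id=subject_id or path.stem,
        fs=fs,
        channel_labels=labels,
        data=data,
        lesion_side=lesion_side,
    )
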