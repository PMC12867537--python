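"""Synthetic cohorts (EEG + clinical tables) and the reference clinical-table fixtures.

The generator emulates the statistical structure the pipeline assumes:

- band-limited oscillations shared between homologous ROIs (mirror
  symmetry), with a per-subject latent asymmetry factor scaling the
  affected hemisphere's delta amplitude — stroke-like slow-wave excess
  over the lesioned side, which the central directional pdBSI picks up;
- 1/f background noise, independent per channel;
- lagged inter-ROI coupling (a delayed, scaled copy of one ROI's band
  component injected into another ROI) producing non-zero imaginary
  coherency;
- follow-up FMAUE coupled to baseline FMAUE through the proportional
  recovery rule and, optionally, to the EEG asymmetry latent
  (``prr_plus_eeg``), plus observation noise.

Two published clinical cohort tables ship as in-memory fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .core import ROI_CHANNELS, EEGRecording, PatientRecord
from .prr import PRRParams, prr_predict

__all__ = ["SimConfig", "SyntheticCohort", "simulate_cohort", "fixtures"]

_BAND_CENTER = {  # oscillator frequency ranges per band (Hz)
    "delta": (1.5, 3.5),
    "theta": (4.5, 7.5),
    "alpha": (8.5, 12.5),
    "beta": (14.0, 28.0),
    "gamma": (31.0, 45.0),
}

_ROI_PAIRS = (("FR", "FL"), ("CR", "CL"), ("OR", "OL"))


@dataclass(frozen=True)
class Coupling:
    roi_src: str      # e.g. "CR"
    roi_dst: str      # e.g. "CL"
    band: str
    lag_samples: int  # > 0: guarantees non-zero imaginary coherency
    gain: float

    def __post_init__(self) -> None:
        if self.lag_samples <= 0:
            raise ValueError("coupling lag must be positive (in samples)")


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 20
    fs: float = 256.0
    duration_s: float = 190.0
    seed: int = 0
    #: base oscillation amplitudes (µV) per band; alpha-dominant rest EEG
    band_amplitudes: Dict[str, float] = field(
        default_factory=lambda: {
            "delta": 4.0, "theta": 3.0, "alpha": 6.0, "beta": 2.0, "gamma": 1.0,
        }
    )
    #: log-scale of the affected-hemisphere delta boost per latent sd
    asym_strength: float = 0.5
    couplings: Tuple[Coupling, ...] = (Coupling("CR", "CL", "alpha", 6, 0.8),)
    noise_exponent: float = 1.0   # 1/f^a background
    noise_sd_uv: float = 1.0      # per-channel background noise sd (µV)
    outcome: str = "prr_plus_eeg"  # or "prr_only"
    effect_size: float = 10.0     # FMAUE points per latent sd
    outcome_noise_sd: float = 3.0  # FMAUE points
    fmaue_t0_range: Tuple[int, int] = (5, 45)

    def __post_init__(self) -> None:
        if self.duration_s < 180:
            raise ValueError("duration must cover the 180 s analysis window")
        if self.outcome not in ("prr_only", "prr_plus_eeg"):
            raise ValueError(f"unknown outcome model {self.outcome!r}")
        if any(a < 0 for a in self.band_amplitudes.values()):
            raise ValueError("band amplitudes must be non-negative")


@dataclass
class SyntheticCohort:
    records: List[PatientRecord]
    recordings: Dict[str, EEGRecording]
    truth: Dict[str, Dict[str, float]]  # per subject: latent, delta_true, group
    config: SimConfig


def _pink_noise(rng: np.random.Generator, n: int, exponent: float, sd: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0)
    f[0] = f[1]
    spec *= f ** (-exponent / 2.0)
    x = np.fft.irfft(spec, n=n)
    s = x.std()
    return x * (sd / s if s > 0 else 1.0)


def _oscillator(
    rng: np.random.Generator, t: np.ndarray, band: str, n_components: int = 3
) -> np.ndarray:
    """Unit-variance band-limited oscillation: a few sinusoids at random
    frequencies within the band with random phases."""
    lo, hi = _BAND_CENTER[band]
    x = np.zeros_like(t)
    for _ in range(n_components):
        f = rng.uniform(lo, hi)
        phi = rng.uniform(0, 2 * np.pi)
        x += np.sin(2 * np.pi * f * t + phi)
    return x / x.std()


def simulate_recording(
    rng: np.random.Generator,
    cfg: SimConfig,
    subject_id: str,
    lesion_side: str,
    ah_delta_scale: float,
) -> EEGRecording:
    """One 50-channel recording.  ``ah_delta_scale`` multiplies the delta
    amplitude of the anatomically affected hemisphere's ROI sources."""
    n = int(round(cfg.duration_s * cfg.fs))
    t = np.arange(n) / cfg.fs
    # shared base component per ROI pair and band (mirror symmetry)
    components: Dict[Tuple[str, str], np.ndarray] = {}
    for right, left in _ROI_PAIRS:
        for band in _BAND_CENTER:
            components[(right[0] + "_pair", band)] = _oscillator(rng, t, band)

    affected_right = lesion_side == "right"

    def roi_source(roi: str) -> np.ndarray:
        pair_key = roi[0] + "_pair"
        is_right = roi.endswith("R")
        affected = is_right == affected_right
        sig = np.zeros(n)
        for band, amp in cfg.band_amplitudes.items():
            a = amp
            if band == "delta" and affected:
                a = amp * ah_delta_scale
            sig += a * components[(pair_key, band)]
        return sig

    sources = {roi: roi_source(roi) for roi in ROI_CHANNELS}
    for cpl in cfg.couplings:
        src_band = components[(cpl.roi_src[0] + "_pair", cpl.band)]
        amp = cfg.band_amplitudes[cpl.band]
        sources[cpl.roi_dst] = sources[cpl.roi_dst] + cpl.gain * amp * np.roll(
            src_band, cpl.lag_samples
        )

    labels: List[str] = []
    data = np.empty((50, n))
    i = 0
    for roi, chans in ROI_CHANNELS.items():
        for ch in chans:
            data[i] = sources[roi] + _pink_noise(
                rng, n, cfg.noise_exponent, cfg.noise_sd_uv
            )
            labels.append(ch)
            i += 1
    return EEGRecording(
        subject_id=subject_id,
        fs=cfg.fs,
        channel_labels=labels,
        data=data,
        lesion_side=lesion_side,
    )


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort; same seed, byte-identical output."""
    rng = np.random.default_rng(cfg.seed)
    params = PRRParams()
    records: List[PatientRecord] = []
    recordings: Dict[str, EEGRecording] = {}
    truth: Dict[str, Dict[str, float]] = {}
    for k in range(cfg.n_subjects):
        sid = f"sim{k:03d}"
        lesion = "left" if rng.random() < 0.5 else "right"
        t0 = int(rng.integers(cfg.fmaue_t0_range[0], cfg.fmaue_t0_range[1] + 1))
        days0 = float(rng.integers(2, 31))
        days1 = float(days0 + rng.integers(60, 121))
        latent = float(rng.standard_normal())
        pred = prr_predict(t0, params)
        delta = pred + rng.normal(0.0, cfg.outcome_noise_sd)
        if cfg.outcome == "prr_plus_eeg":
            delta -= cfg.effect_size * latent
        t1 = int(np.clip(round(t0 + delta), 0, 66))
        rec = PatientRecord(
            subject_id=sid,
            sex="F" if rng.random() < 0.5 else "M",
            age=float(rng.integers(45, 85)),
            affected_hemisphere="L" if lesion == "left" else "R",
            days_T0=days0,
            days_T1=days1,
            fmaue_T0=t0,
            fmaue_T1=t1,
        )
        records.append(rec)
        recordings[sid] = simulate_recording(
            rng, cfg, sid, lesion, ah_delta_scale=float(np.exp(cfg.asym_strength * latent))
        )
        actual = float(t1 - t0)
        truth[sid] = {
            "latent": latent,
            "delta_true": float(delta),
            "group": "REC" if abs(pred - actual) < params.rec_threshold else "NO-REC",
        }
    return SyntheticCohort(records=records, recordings=recordings, truth=truth, config=cfg)


# ---------------------------------------------------------------------------
# Clinical-table fixtures
# ---------------------------------------------------------------------------

# (id, sex, age, AH, days_T0, days_T1, fmaue_T0, fmaue_T1)
_AOUP_ROWS = (
    (2, "M", 53, "R", 4, 105, 0, 23),
    (3, "F", 71, "L", 3, 156, 66, 66),
    (4, "M", 77, "L", 3, 150, 57, 62),
    (5, "M", 58, "R", 2, 86, 21, 64),
    (6, "F", 79, "L", 2, 93, 66, 66),
    (7, "F", 75, "L", 3, 88, 4, 43),
    (11, "M", 73, "L", 3, 250, 55, 60),
    (12, "F", 78, "L", 2, 212, 0, 63),
    (14, "M", 50, "R", 4, 102, 4, 12),
    (15, "M", 50, "L", 2, 303, 59, 66),
    (16, "F", 72, "R", 2, 301, 64, 66),
    (17, "M", 52, "R", 2, 138, 52, 60),
    (18, "M", 64, "R", 3, 175, 2, 22),
    (20, "M", 79, "L", 2, 130, 66, 66),
    (22, "M", 82, "L", 1, 134, 12, 59),
    (24, "F", 53, "R", 4, 96, 31, 62),
    (25, "M", 52, "R", 3, 97, 6, 44),
    (26, "M", 64, "L", 3, 100, 0, 19),
    (27, "M", 64, "R", 2, 88, 24, 28),
    (30, "M", 64, "L", 8, 102, 32, 65),
    (32, "M", 53, "L", 3, 93, 66, 66),
    (37, "M", 60, "R", 1, 108, 57, 64),
    (38, "M", 69, "L", 3, 97, 8, 13),
)

_FDG_ROWS = (
    (1, "F", 64, "L", 13, 95, 8, 30),
    (2, "M", 59, "L", 15, 68, 61, 65),
    (3, "M", 78, "L", 15, 109, 55, 64),
    (9, "M", 51, "L", 26, 89, 4, 11),
    (10, "M", 58, "L", 22, 107, 65, 66),
    (12, "F", 76, "R", 28, 112, 60, 60),
    (13, "M", 78, "L", 26, 97, 63, 63),
    (15, "M", 80, "L", 19, 96, 6, 16),
    (16, "M", 77, "L", 19, 107, 49, 60),
    (17, "F", 70, "R", 22, 97, 62, 65),
    (19, "M", 60, "R", 33, 85, 4, 4),
    (20, "M", 72, "R", 45, 82, 4, 6),
    (24, "M", 52, "R", 32, 96, 4, 4),
    (27, "M", 51, "R", 21, 93, 66, 66),
    (28, "M", 81, "R", 24, 66, 4, 9),
    (29, "M", 76, "L", 34, 82, 66, 66),
    (30, "M", 79, "L", 31, 99, 63, 66),
)


def _rows_to_records(rows) -> List[PatientRecord]:
    return [
        PatientRecord(
            subject_id=str(r[0]), sex=r[1], age=float(r[2]),
            affected_hemisphere=r[3], days_T0=float(r[4]), days_T1=float(r[5]),
            fmaue_T0=int(r[6]), fmaue_T1=int(r[7]),
        )
        for r in rows
    ]


def fixtures() -> Dict[str, List[PatientRecord]]:
    """The two clinical cohort tables: ``aoup_table`` (23 acute patients)
    and ``fdg_table`` (17 subacute patients)."""
    return {
        "aoup_table": _rows_to_records(_AOUP_ROWS),
        "fdg_table": _rows_to_records(_FDG_ROWS),
    }
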