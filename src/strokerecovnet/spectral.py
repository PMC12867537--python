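"""Per-epoch Welch spectra and the 141 spectral / brain-symmetry features.

Feature families
----------------
relative band power  5 bands x (average + 9 ROIs + AH/UH)        = 60
DAR                  delta/alpha ratio, avg + 9 ROIs + AH/UH      = 12
DTABR                (delta+theta)/(alpha+beta), avg + 6 lateral
                     ROIs + AH/UH                                 = 9
pdBSI                6 bands x {F, C, O, avg}                     = 24
dirpdBSI             6 bands x {F, C, O, avg}                     = 24
IAF                  alpha centroid, avg + 9 ROIs + AH/UH         = 12
                                                            total = 141

Sign convention: after the hemisphere swap the left ROIs carry the
*unaffected* hemisphere, so dirpdBSI > 0 means unaffected-hemisphere
power excess and dirpdBSI < 0 means affected-side excess.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .core import BANDS, BAND_ORDER, Epoch, ROILayout

__all__ = [
    "EpochPSD",
    "FeatureError",
    "welch_psd",
    "relative_band_power",
    "dar",
    "dtabr",
    "pdbsi",
    "dir_pdbsi",
    "iaf",
    "spectral_block",
    "SPECTRAL_FEATURE_NAMES",
]

WELCH_SEGMENT_S = 2.0  # -> 0.5 Hz resolution, 5 segments per 10-s epoch

# scope inventories (order is the canonical feature order)
_ROI9 = ("FR", "FL", "CR", "CL", "OR", "OL", "F", "C", "O")
_SCOPES_12 = ("avg",) + _ROI9 + ("AH", "UH")            # relpower, DAR, IAF
_SCOPES_DTABR = ("avg", "FR", "FL", "CR", "CL", "OR", "OL", "AH", "UH")
_BSI_SCOPES = ("F", "C", "O", "avg")
_BSI_BANDS = ("broadband",) + BAND_ORDER


class FeatureError(ValueError):
    """Degenerate spectrum (zero power where a feature needs power)."""


@dataclass
class EpochPSD:
    """One-sided Welch power spectral density, channel x frequency bin."""

    freqs: np.ndarray            # bin centers, 0.5 Hz spacing
    psd: np.ndarray              # channel x bin, µV²/Hz, >= 0
    channel_labels: list

    def rows(self, labels: Sequence[str]) -> np.ndarray:
        idx = [self.channel_labels.index(l) for l in labels]
        return self.psd[idx]


def welch_psd(epoch: Epoch) -> EpochPSD:
    """Averaged periodogram on 2-s Hamming segments without overlap."""
    nperseg = int(round(WELCH_SEGMENT_S * epoch.fs))
    n = epoch.data.shape[1]
    if n % nperseg != 0:
        raise ValueError(
            f"epoch length {n} samples is not a multiple of the "
            f"{nperseg}-sample Welch segment"
        )
    freqs, psd = sps.welch(
        epoch.data, fs=epoch.fs, window="hamming",
        nperseg=nperseg, noverlap=0, detrend="constant",
    )
    return EpochPSD(freqs=freqs, psd=psd, channel_labels=list(epoch.channel_labels))


def band_mask(freqs: np.ndarray, band: str) -> np.ndarray:
    """Discrete bin membership: lower-closed / upper-open, except that
    48 Hz closes the gamma band (and the broadband span)."""
    lo, hi = BANDS[band]
    mask = (freqs >= lo) & (freqs < hi)
    if hi >= BANDS["gamma"][1]:
        mask |= np.isclose(freqs, hi)
    return mask


def _trapz_band(freqs: np.ndarray, p: np.ndarray, lo: float, hi: float) -> float:
    sel = (freqs >= lo) & (freqs <= hi)
    return float(np.trapezoid(p[sel], freqs[sel]))


def relative_band_power(psd: EpochPSD, scope_channels: Sequence[str], band: str) -> float:
    """Trapezoid band power of the scope-mean spectrum, normalized by the
    total 1-48 Hz power.  Contiguous band integrals share their edge bins,
    so the five band fractions tile [1, 48] and sum to 1."""
    if not scope_channels:
        raise ValueError("empty scope")
    p = psd.rows(scope_channels).mean(axis=0)
    total = _trapz_band(psd.freqs, p, *BANDS["broadband"])
    if total <= 0:
        raise FeatureError("zero total 1-48 Hz power (degenerate epoch)")
    lo, hi = BANDS[band]
    return _trapz_band(psd.freqs, p, lo, hi) / total


def dar(psd: EpochPSD, scope_channels: Sequence[str]) -> float:
    """Delta/alpha ratio of relative powers."""
    a = relative_band_power(psd, scope_channels, "alpha")
    if a <= 0:
        raise FeatureError("zero alpha power in DAR denominator")
    return relative_band_power(psd, scope_channels, "delta") / a


def dtabr(psd: EpochPSD, scope_channels: Sequence[str]) -> float:
    """(delta + theta) / (alpha + beta) ratio of relative powers."""
    denom = (relative_band_power(psd, scope_channels, "alpha")
             + relative_band_power(psd, scope_channels, "beta"))
    if denom <= 0:
        raise FeatureError("zero alpha+beta power in DTABR denominator")
    num = (relative_band_power(psd, scope_channels, "delta")
           + relative_band_power(psd, scope_channels, "theta"))
    return num / denom


def _bsi_terms(L: np.ndarray, R: np.ndarray) -> np.ndarray:
    """Per-bin (L-R)/(L+R) with zero-power bins dropped (K adjusted)."""
    L = np.asarray(L, dtype=float)
    R = np.asarray(R, dtype=float)
    tot = L + R
    keep = tot > 0
    if not keep.any():
        raise FeatureError("all bins have zero power; symmetry index undefined")
    return (L[keep] - R[keep]) / tot[keep]


def pdbsi(L: np.ndarray, R: np.ndarray) -> float:
    """Pairwise-derived brain symmetry index: mean |L_n - R_n|/(L_n + R_n)
    over band bins.  L_n/R_n are PSD sums over the left/right ROI channel
    sets.  In [0, 1]; 0 for perfect symmetry."""
    return float(np.mean(np.abs(_bsi_terms(L, R))))


def dir_pdbsi(L: np.ndarray, R: np.ndarray) -> float:
    """Directional pdBSI: signed mean of (L_n - R_n)/(L_n + R_n).
    Positive = left (unaffected-hemisphere) power excess."""
    return float(np.mean(_bsi_terms(L, R)))


def iaf(psd: EpochPSD, scope_channels: Sequence[str]) -> float:
    """Individual alpha frequency: centre-of-gravity of the scope-mean
    spectrum over the closed alpha interval [8, 13] Hz."""
    p = psd.rows(scope_channels).mean(axis=0)
    lo, hi = BANDS["alpha"]
    sel = (psd.freqs >= lo) & (psd.freqs <= hi)
    pw = p[sel]
    if pw.sum() <= 0:
        raise FeatureError("zero alpha power; IAF undefined")
    return float(np.sum(pw * psd.freqs[sel]) / pw.sum())


# ---------------------------------------------------------------------------
# Feature block
# ---------------------------------------------------------------------------


def _left_right_sets(layout: ROILayout, scope: str) -> Tuple[Tuple[str, ...], Tuple[str, ...]]:
    r = layout.rois
    if scope == "F":
        return r["FL"], r["FR"]
    if scope == "C":
        return r["CL"], r["CR"]
    if scope == "O":
        return r["OL"], r["OR"]
    if scope == "avg":
        return layout.unaffected_hemisphere, layout.affected_hemisphere
    raise KeyError(scope)


def _build_names() -> list:
    names = []
    for band in BAND_ORDER:
        for scope in _SCOPES_12:
            names.append(f"relpower_{band}_{scope}")
    names += [f"dar_{s}" for s in _SCOPES_12]
    names += [f"dtabr_{s}" for s in _SCOPES_DTABR]
    for family in ("pdbsi", "dirpdbsi"):
        for band in _BSI_BANDS:
            for scope in _BSI_SCOPES:
                names.append(f"{family}_{band}_{scope}")
    names += [f"iaf_{s}" for s in _SCOPES_12]
    return names


SPECTRAL_FEATURE_NAMES: Tuple[str, ...] = tuple(_build_names())
assert len(SPECTRAL_FEATURE_NAMES) == 141


def spectral_block(psd: EpochPSD, layout: ROILayout) -> Dict[str, float]:
    """All 141 spectral and brain-symmetry features of one epoch, keyed by
    stable canonical names in a fixed order."""
    out: Dict[str, float] = {}
    for band in BAND_ORDER:
        for scope in _SCOPES_12:
            out[f"relpower_{band}_{scope}"] = relative_band_power(
                psd, layout.scope_channels(scope), band
            )
    for scope in _SCOPES_12:
        out[f"dar_{scope}"] = dar(psd, layout.scope_channels(scope))
    for scope in _SCOPES_DTABR:
        out[f"dtabr_{scope}"] = dtabr(psd, layout.scope_channels(scope))
    for family, fn in (("pdbsi", pdbsi), ("dirpdbsi", dir_pdbsi)):
        for band in _BSI_BANDS:
            mask = band_mask(psd.freqs, band)
            for scope in _BSI_SCOPES:
                left, right = _left_right_sets(layout, scope)
                L = psd.rows(left).sum(axis=0)[mask]
                R = psd.rows(right).sum(axis=0)[mask]
                try:
                    out[f"{family}_{band}_{scope}"] = fn(L, R)
                except FeatureError as e:
                    raise FeatureError(f"{family}_{band}_{scope}: {e}") from e
    for scope in _SCOPES_12:
        out[f"iaf_{scope}"] = iaf(psd, layout.scope_channels(scope))
    assert tuple(out) == SPECTRAL_FEATURE_NAMES
    return out
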