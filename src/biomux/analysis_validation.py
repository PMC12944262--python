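"""Validation analyses: block PSD contrast, haemodynamic spectra, ECG-PPG lag.

These are the analyses used to establish that the emulated (or recorded)
data carry the intended physiology: increased posterior alpha power with
eyes closed, cardiac- and respiratory-band energy in the total-haemoglobin
spectrum, and a consistent pulse-transit offset between ECG R-peaks and the
optical pulse.  All analyses are pure functions of the decoded streams and
their configuration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .haemodynamics import HaemoSeries
from .signal_emulator import Block

__all__ = [
    "DEFAULT_BANDS",
    "AnalysisError",
    "SpectralResult",
    "AlphaContrast",
    "PttResult",
    "block_psd",
    "alpha_contrast",
    "haemo_spectrum",
    "pulse_transit_lag",
]

DEFAULT_BANDS = {
    "alpha": (8.0, 12.0),
    "alpha_narrow": (9.0, 11.0),
    "cardiac": (0.8, 1.2),
    "respiratory": (0.2, 0.4),
}


class AnalysisError(ValueError):
    """Input series too short or inconsistent for the requested analysis."""


@dataclass
class SpectralResult:
    """Welch PSD per channel plus named band-power summaries."""

    freqs: np.ndarray                 # Hz
    psd: np.ndarray                   # (n_channels, n_freqs), units^2/Hz
    channels: list = field(default_factory=list)
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))

    def band_power(self, band: str | tuple) -> np.ndarray:
        """Integral of the PSD over a band, per channel."""
        lo, hi = self.bands[band] if isinstance(band, str) else band
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        if not sel.any():
            raise AnalysisError(f"band {(lo, hi)} contains no frequency bins")
        return np.trapezoid(self.psd[:, sel], self.freqs[sel], axis=1)

    def peak_frequency(self, band: str | tuple) -> float:
        """Frequency of the maximum of the channel-mean PSD within a band."""
        lo, hi = self.bands[band] if isinstance(band, str) else band
        sel = (self.freqs >= lo) & (self.freqs <= hi)
        if not sel.any():
            raise AnalysisError(f"band {(lo, hi)} contains no frequency bins")
        mean_psd = self.psd.mean(axis=0)
        return float(self.freqs[sel][np.argmax(mean_psd[sel])])

    @property
    def bin_width(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def _welch(x: np.ndarray, fs: float, nperseg: int):
    return sps.welch(x, fs=fs, window="hann", nperseg=nperseg, noverlap=nperseg // 2)


def block_psd(
    eeg: dict | np.ndarray,
    fs_hz: float,
    blocks: Sequence[Block],
    window_s: float = 4.0,
    channels: Sequence[str] | None = None,
) -> dict:
    """Grand block-average Welch PSD per condition.

    Per condition, the PSD is the mean of per-block Welch estimates (4 s Hann
    windows, 50% overlap by default) across that condition's blocks,
    channel-resolved.  Blocks shorter than twice the window are skipped with
    a warning.  ``eeg`` is either a label->trace dict (demux output) or an
    (n_channels, n_frames) array.
    """
    if isinstance(eeg, dict):
        labels = list(eeg.keys())
        data = np.vstack([eeg[k] for k in labels])
    else:
        data = np.atleast_2d(np.asarray(eeg, dtype=float))
        labels = [f"ch{i}" for i in range(data.shape[0])]
    if channels is not None:
        keep = [i for i, lab in enumerate(labels) if lab in set(channels)]
        if not keep:
            raise AnalysisError("channel selection matches no channels")
        data = data[keep]
        labels = [labels[i] for i in keep]

    nperseg = int(round(window_s * fs_hz))
    per_condition: dict[str, list[np.ndarray]] = {}
    freqs = None
    for b in blocks:
        seg = data[:, b.start_frame : b.stop_frame]
        if seg.shape[1] < 2 * nperseg:
            warnings.warn(
                f"block [{b.start_frame}, {b.stop_frame}) shorter than twice the "
                f"{window_s:g} s window; skipped",
                stacklevel=2,
            )
            continue
        f, p = _welch(seg, fs_hz, nperseg)
        freqs = f
        per_condition.setdefault(b.condition, []).append(p)
    if freqs is None:
        raise AnalysisError("no block was long enough for the requested window")
    return {
        cond: SpectralResult(freqs=freqs, psd=np.mean(ps, axis=0), channels=labels)
        for cond, ps in per_condition.items()
    }


@dataclass
class AlphaContrast:
    band: tuple
    channels: list
    per_channel_ratio: np.ndarray     # closed / open band power
    pooled_ratio: float
    flagged: list = field(default_factory=list)  # channels with zero open power


def alpha_contrast(
    result_open: SpectralResult,
    result_closed: SpectralResult,
    band: tuple | str = "alpha",
) -> AlphaContrast:
    """Eyes-closed / eyes-open band-power ratio per channel and pooled."""
    if not np.array_equal(result_open.freqs, result_closed.freqs):
        raise AnalysisError("conditions were estimated on different frequency grids")
    p_open = result_open.band_power(band)
    p_closed = result_closed.band_power(band)
    flagged = [c for c, p in zip(result_open.channels, p_open) if p == 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = p_closed / p_open
    pooled = float(p_closed.mean() / p_open.mean()) if p_open.mean() > 0 else float("inf")
    lo, hi = DEFAULT_BANDS[band] if isinstance(band, str) else band
    return AlphaContrast(
        band=(lo, hi),
        channels=list(result_open.channels),
        per_channel_ratio=ratios,
        pooled_ratio=pooled,
        flagged=flagged,
    )


def haemo_spectrum(
    haemo: HaemoSeries,
    window_s: float | None = None,
    detrend: bool = True,
    bands: dict | None = None,
) -> tuple[SpectralResult, dict]:
    """Total-haemoglobin PSD with detected cardiac/respiratory peaks.

    Returns ``(SpectralResult for dHbT, {band: peak frequency})``.  The
    default window is 60 s (or the full series if shorter), long enough to
    separate respiratory frequencies at ~0.02 Hz resolution.  A series
    shorter than two cycles of the slowest respiratory frequency is an
    error.
    """
    bands = bands or {k: DEFAULT_BANDS[k] for k in ("cardiac", "respiratory")}
    x = np.asarray(haemo.hbt, dtype=float)
    fs = haemo.rate_hz
    min_duration = 2.0 / min(lo for lo, _ in bands.values())
    if x.size / fs < min_duration:
        raise AnalysisError(
            f"series of {x.size / fs:.1f} s is shorter than two cycles of the "
            f"slowest band ({min_duration:.1f} s)"
        )
    if detrend:
        x = sps.detrend(x, type="linear")
    nperseg = int(round((window_s or min(60.0, x.size / fs)) * fs))
    nperseg = min(nperseg, x.size)
    freqs, psd = _welch(x, fs, nperseg)
    result = SpectralResult(freqs=freqs, psd=psd[np.newaxis, :], channels=["HbT"])
    peaks = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        if not sel.any():
            continue
        band_psd = psd[sel]
        # a flat/empty band has no peak
        if band_psd.max() <= 0 or np.allclose(band_psd, band_psd[0]):
            peaks[name] = None
        else:
            peaks[name] = float(freqs[sel][np.argmax(band_psd)])
    return result, peaks


@dataclass
class PttResult:
    lag_s: float                        # median R-peak -> PPG-peak interval
    lags_s: np.ndarray
    r_peaks: np.ndarray                 # frame indices
    ppg_peaks: np.ndarray
    pairs: list                         # (r_frame, ppg_frame) matched pairs
    unmatched: int = 0


def _detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """Threshold detection on band-passed ECG with a refractory period.

    Adequate for template/clean ECG; not clinical-grade.
    """
    sos = sps.butter(4, [5.0, 25.0], btype="bandpass", fs=fs, output="sos")
    filt = sps.sosfiltfilt(sos, ecg)
    height = 0.5 * np.percentile(np.abs(filt), 99.9)
    peaks, _ = sps.find_peaks(filt, height=height, distance=int(0.3 * fs))
    # refine to the unfiltered local maximum (filter may shift the apex)
    half = int(0.04 * fs)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, ecg.size)
        refined.append(lo + int(np.argmax(ecg[lo:hi])))
    return np.array(sorted(set(refined)), dtype=int)


def pulse_transit_lag(
    ecg: np.ndarray,
    ppg: np.ndarray,
    fs_hz: float,
    max_lag_s: float = 0.6,
) -> PttResult:
    """Median R-peak to next optical-pulse-peak interval on a shared timeline.

    Every R-peak is matched to the first PPG peak within ``max_lag_s`` after
    it; R-peaks without a match within tolerance are counted and reported
    with a warning rather than silently dropped.
    """
    ecg = np.asarray(ecg, dtype=float)
    ppg = np.asarray(ppg, dtype=float)
    if ecg.shape != ppg.shape:
        raise AnalysisError("ECG and PPG must share the frame timeline")
    r_peaks = _detect_r_peaks(ecg, fs_hz)
    # polynomial smoothing rather than a low-pass: a zero-phase low-pass
    # skews the apex of the asymmetric pulse, biasing the lag estimate
    win = int(0.17 * fs_hz) | 1
    ppg_f = sps.savgol_filter(ppg, win, 3) if ppg.size > win else ppg
    prom = 0.25 * (np.percentile(ppg_f, 99) - np.percentile(ppg_f, 1))
    ppg_peaks, _ = sps.find_peaks(ppg_f, distance=int(0.3 * fs_hz), prominence=prom)

    pairs = []
    lags = []
    unmatched = 0
    max_lag = max_lag_s * fs_hz
    slack = 2  # a zero-delay pulse apex may land a sample early under noise
    for r in r_peaks:
        nxt = ppg_peaks[ppg_peaks >= r - slack]
        if nxt.size and (nxt[0] - r) <= max_lag:
            pairs.append((int(r), int(nxt[0])))
            lags.append((nxt[0] - r) / fs_hz)
        else:
            unmatched += 1
    if unmatched:
        warnings.warn(f"{unmatched} R-peak(s) had no optical pulse within tolerance",
                      stacklevel=2)
    if not lags:
        raise AnalysisError("no matched R-peak / pulse-peak pairs")
    return PttResult(
        lag_s=float(np.median(lags)),
        lags_s=np.array(lags),
        r_peaks=r_peaks,
        ppg_peaks=ppg_peaks,
        pairs=pairs,
        unmatched=unmatched,
    )
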