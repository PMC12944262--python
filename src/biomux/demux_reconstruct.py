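"""Stream demultiplexing: EEG at f_s, per-(source, wavelength) optics at f_state.

Optical samples are grouped purely by the state identifiers embedded in each
frame's status word — never by frame arithmetic, software timestamps or packet
ordering — so reconstruction is unambiguous and invariant to how the frame
sequence was chunked in transport.  Blanking-frame detector readings are
discarded (and counted) rather than used; an optional ambient-subtraction step
can instead use them as a dark reference.  Sample times are exact integer
frame multiples, so no drift accumulates over arbitrarily long logs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .frame_codec import ChannelMap, FrameBlock, SampleFrame
from .tdm_scheduler import IlluminationPlan

__all__ = [
    "IntegrityError",
    "OpticalSeries",
    "DemuxResult",
    "demux",
    "decimate",
]


class IntegrityError(ValueError):
    """Status word cites a state the plan does not define."""


@dataclass
class OpticalSeries:
    """Intensity series of one (source, wavelength) on one detector channel.

    ``frame_indices`` are the exact frames the samples were converted on
    (``times = frame_indices / fs``); after decimation the grid is uniform at
    ``effective_rate_hz`` from ``t0`` and ``frame_indices`` is None.
    """

    source: int
    wavelength: int
    detector: str
    values: np.ndarray
    fs_hz: float
    effective_rate_hz: float
    frame_indices: np.ndarray | None = None
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        if self.frame_indices is not None:
            return self.frame_indices / self.fs_hz
        return self.t0 + np.arange(self.values.size) / self.effective_rate_hz

    def __len__(self) -> int:
        return self.values.size


@dataclass
class DemuxResult:
    """EEG/aux passthrough plus reconstructed optical series and a QC report."""

    fs_hz: float
    n_frames: int
    eeg: dict = field(default_factory=dict)        # label -> volts at f_s
    aux: dict = field(default_factory=dict)
    optical: dict = field(default_factory=dict)    # (detector, source, wl) -> OpticalSeries
    blank_discards: int = 0                        # blanking frames dropped from optics

    def series(self, source: int, wavelength: int, detector: str | None = None) -> OpticalSeries:
        """Fetch one optical series; detector defaults to the only/first one."""
        keys = [
            k for k in self.optical if k[1] == source and k[2] == wavelength
            and (detector is None or k[0] == detector)
        ]
        if not keys:
            raise KeyError(f"no optical series for source {source} at {wavelength} nm")
        return self.optical[keys[0]]


def demux(
    frames: FrameBlock | Sequence[SampleFrame],
    cmap: ChannelMap,
    plan: IlluminationPlan,
    ambient_subtract: bool = False,
) -> DemuxResult:
    """Split a decoded frame sequence by embedded illumination state.

    Every non-blanking frame's optical samples are assigned to exactly one
    (source, wavelength) series per detector; blanking frames are discarded
    from optics and counted.  EEG and auxiliary channels pass through at
    ``f_s`` untouched.  A status word citing a state absent from the plan
    raises :class:`IntegrityError` with the offending frame index.

    With ``ambient_subtract`` the blank-state detector readings are used as a
    dark reference: their level, linearly interpolated onto each optical
    sample time, is subtracted.
    """
    if not isinstance(frames, FrameBlock):
        frames = FrameBlock.from_frames(list(frames), cmap)
    n = frames.n_frames
    state_ids = frames.state_ids
    bad = (state_ids < 0) | (state_ids >= plan.n_state)
    if bad.any():
        first = int(frames.frame_indices[bad][0])
        raise IntegrityError(
            f"frame {first} cites state {int(state_ids[bad][0])}, "
            f"but the plan defines states 0..{plan.n_state - 1}"
        )

    volts = frames.volts(cmap)
    result = DemuxResult(fs_hz=plan.fs_hz, n_frames=n)
    labels = cmap.labels
    for col in cmap.by_role("eeg"):
        result.eeg[labels[col]] = volts[:, col]
    for col in cmap.by_role("aux"):
        result.aux[labels[col]] = volts[:, col]

    opt_cols = cmap.by_role("optical")
    # assignment uses only the embedded identifiers, decoded per frame
    blank = frames.blanking | (frames.wavelength_codes == 0)
    result.blank_discards = int(blank.sum())
    if not opt_cols:
        return result

    sources = frames.source_indices
    wl_codes = frames.wavelength_codes
    wl_of_code = {1: 750, 2: 850}
    frame_idx = frames.frame_indices

    if ambient_subtract:
        blank_idx = frame_idx[blank]

    for code, wl in wl_of_code.items():
        for src in np.unique(sources[(~blank) & (wl_codes == code)]):
            mask = (~blank) & (wl_codes == code) & (sources == src)
            n_per_period = mask[: plan.period_frames].sum() if n >= plan.period_frames else mask.sum()
            eff = plan.fs_hz * float(np.count_nonzero(mask)) / n if n else plan.f_state_hz
            # exact per-plan rate when the log covers whole periods
            if n >= plan.period_frames:
                eff = plan.fs_hz * float(n_per_period) / plan.period_frames
            for col in opt_cols:
                vals = volts[mask, col]
                if ambient_subtract and blank.any():
                    dark = np.interp(frame_idx[mask], blank_idx, volts[blank, col])
                    vals = vals - dark
                result.optical[(labels[col], int(src), wl)] = OpticalSeries(
                    source=int(src),
                    wavelength=wl,
                    detector=labels[col],
                    values=vals,
                    fs_hz=plan.fs_hz,
                    effective_rate_hz=eff,
                    frame_indices=frame_idx[mask].copy(),
                )
    return result


def _antialias_fir(eff_rate: float, target_rate: float) -> np.ndarray:
    """Zero-phase-applied FIR low-pass at 0.4 x target rate, >=60 dB stopband
    by 0.5 x target (kaiser design)."""
    nyq = eff_rate / 2.0
    width = 0.1 * target_rate / nyq
    numtaps, beta = sps.kaiserord(65.0, width)
    numtaps |= 1  # odd length for symmetric zero-phase response
    return sps.firwin(numtaps, 0.4 * target_rate / nyq, window=("kaiser", beta))


def decimate(series: OpticalSeries, target_rate_hz: float) -> OpticalSeries:
    """Anti-alias low-pass, then down-sample to a conventional analysis rate.

    DC level is preserved (unity-DC FIR, zero-phase application).  Requesting
    a rate above the series' effective rate is a domain error.  Non-integer
    ratios are handled polyphase after the anti-alias filter.
    """
    eff = series.effective_rate_hz
    if target_rate_hz > eff:
        raise ValueError(
            f"target rate {target_rate_hz:g} Hz exceeds effective rate {eff:g} Hz"
        )
    x = np.asarray(series.values, dtype=float)
    taps = _antialias_fir(eff, target_rate_hz)
    if x.size <= 3 * len(taps):
        pad = min(x.size - 1, 3 * len(taps))
    else:
        pad = 3 * len(taps)
    y = sps.filtfilt(taps, [1.0], x, padlen=pad)
    ratio = eff / target_rate_hz
    if abs(ratio - round(ratio)) < 1e-9:
        step = int(round(ratio))
        out = y[::step]
        rate = eff / step
    else:
        frac = Fraction(target_rate_hz / eff).limit_denominator(1000)
        out = sps.resample_poly(y, frac.numerator, frac.denominator)
        rate = eff * frac.numerator / frac.denominator
    t0 = series.times[0] if series.values.size else 0.0
    return OpticalSeries(
        source=series.source,
        wavelength=series.wavelength,
        detector=series.detector,
        values=out,
        fs_hz=series.fs_hz,
        effective_rate_hz=rate,
        frame_indices=None,
        t0=float(t0),
    )
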