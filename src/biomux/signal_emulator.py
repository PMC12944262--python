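"""Ground-truth-known physiology and instrument-signal emulator.

Generates the validation scenarios the instrument is exercised with — the
converter's internal square-wave test signal, occipital-alpha-modulated EEG
in eyes-open/eyes-closed blocks, breath-hold fNIRS intensities with cardiac
and respiratory components, and concurrent ECG + finger-PPG with a
configurable pulse-transit offset — and digitises them through a channel map
and illumination plan into bit-exact conversion frames.  Every stochastic
draw is reproducible from the scenario seed, and the underlying ground truth
is retained alongside the frames so each downstream stage has a recovery
target.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .frame_codec import (
    ChannelConfig,
    ChannelMap,
    FrameBlock,
    StructuralError,
    volts_to_code,
)
from .haemodynamics import HaemoSeries, MbllParameters, mbll_forward
from .tdm_scheduler import IlluminationPlan, IlluminationState, default_plan

__all__ = [
    "ScenarioError",
    "PhysioScenario",
    "EmulatedSession",
    "Block",
    "gen_test_signal",
    "gen_alpha_eeg",
    "gen_breath_hold_optical",
    "gen_ecg_ppg",
    "digitise",
    "run_scenario",
    "default_channel_map",
    "default_scenario_plan",
    "ALPHA_MONTAGE",
    "POSTERIOR_CHANNELS",
]

SCENARIOS = ("test_signal", "alpha_blocks", "breath_hold", "ecg_ppg")

#: 12-channel resting-state montage used for the alpha demonstration.
ALPHA_MONTAGE = ("O1", "O2", "T3", "T5", "Pz", "Cz", "C4", "C3", "P4", "P3", "T4", "T6")
POSTERIOR_CHANNELS = ("O1", "O2", "Pz", "P3", "P4")


class ScenarioError(ValueError):
    """Scenario configuration inconsistent with the map/plan."""


@dataclass
class PhysioScenario:
    """Configuration of one emulated recording.

    Amplitudes are free parameters of the emulator (the corresponding real
    recordings are not tabulated); defaults are physiologically conventional
    scales.  EEG noise defaults to the converter's datasheet input-referred
    noise floor, detector noise to the photoreceiver's output noise.
    """

    scenario: str = "alpha_blocks"
    duration_s: float = 300.0
    fs_hz: float = 250.0
    seed: int = 0

    # test-signal parameters (emulator convention: ~1.9 mV square wave)
    test_amplitude_v: float = 1.875e-3
    test_period_frames: int = 128

    # alpha-block parameters
    block_s: float = 30.0
    alpha_freq_hz: float = 10.0            # within the 9-11 Hz posterior band
    alpha_amp_uv: float = 10.0
    alpha_open_attenuation: float = 0.25   # amplitude factor during eyes-open
    pink_amp_uv: float = 2.0               # 1/f background RMS
    pink_slope: float = 1.0

    # breath-hold haemodynamics (uM)
    cardiac_hz: float = 1.0
    cardiac_amp_hbo_um: float = 0.20
    cardiac_amp_hbr_um: float = 0.05
    resp_hz: float = 0.3
    resp_amp_hbo_um: float = 0.30
    resp_amp_hbr_um: float = 0.08
    breath_hold_onset_s: float = 90.0
    breath_hold_rise_s: float = 8.0
    breath_hold_amp_hbo_um: float = 1.5
    breath_hold_amp_hbr_um: float = -0.4
    baseline_intensity_v: float = 1.0

    # ECG / PPG
    heart_rate_bpm: float = 60.0
    ptt_delay_s: float = 0.25
    ecg_amp_v: float = 1.0e-3
    ppg_amp_v: float = 0.02

    # noise
    noise_rms_uv: float = 0.57             # EEG input-referred noise
    detector_noise_rms_v: float = 300e-6   # photoreceiver output noise
    mains_amp_uv: float = 0.0              # 50 Hz interference, default off
    mains_hz: float = 50.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ScenarioError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.fs_hz))

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Block:
    """One condition block on the frame timeline, [start, stop)."""

    start_frame: int
    stop_frame: int
    condition: str


# ---------------------------------------------------------------------------
# waveform generators

def gen_test_signal(
    fs_hz: float,
    duration_s: float,
    amplitude_v: float = 1.875e-3,
    period_frames: int = 128,
    n_channels: int = 32,
) -> np.ndarray:
    """Internal square-wave test signal, identical and phase-aligned on all
    channels (the multi-device synchronisation check).  Returns volts with
    shape (n_channels, n_frames); transitions fall at exact multiples of
    ``period_frames / 2``."""
    if period_frames < 2:
        raise ScenarioError("period_frames must be >= 2")
    n = int(round(duration_s * fs_hz))
    idx = np.arange(n)
    wave = np.where((idx % period_frames) < period_frames // 2, amplitude_v, -amplitude_v)
    return np.tile(wave, (n_channels, 1))


def _pink_noise(rng: np.random.Generator, n: int, rms: float, slope: float) -> np.ndarray:
    """1/f^slope background realised by spectrally shaping white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec /= f ** (slope / 2.0)
    x = np.fft.irfft(spec, n)
    sd = x.std()
    return x * (rms / sd) if sd > 0 else x


def gen_alpha_eeg(scn: PhysioScenario, rng: np.random.Generator | None = None):
    """Multichannel resting-state EEG with block-modulated posterior alpha.

    Eyes-closed blocks carry the alpha sinusoid at full amplitude on the
    posterior channels; eyes-open blocks attenuate it by the configured
    factor.  1/f background and white noise are added on every channel.
    Returns ``(data_volts [n_ch, n], blocks)`` where the blocks partition the
    timeline exactly.
    """
    rng = rng or np.random.default_rng(scn.seed)
    n = scn.n_frames
    fs = scn.fs_hz
    t = np.arange(n) / fs
    labels = list(ALPHA_MONTAGE)
    posterior = [i for i, lab in enumerate(labels) if lab in POSTERIOR_CHANNELS]

    block_frames = int(round(scn.block_s * fs))
    blocks: list[Block] = []
    cond = "open"
    start = 0
    while start < n:
        stop = min(start + block_frames, n)
        blocks.append(Block(start, stop, cond))
        cond = "closed" if cond == "open" else "open"
        start = stop

    envelope = np.empty(n)
    for b in blocks:
        envelope[b.start_frame : b.stop_frame] = (
            1.0 if b.condition == "closed" else scn.alpha_open_attenuation
        )

    data = np.zeros((len(labels), n))
    alpha = np.sin(2 * np.pi * scn.alpha_freq_hz * t + rng.uniform(0, 2 * np.pi))
    for i in range(len(labels)):
        if i in posterior:
            data[i] += scn.alpha_amp_uv * 1e-6 * envelope * alpha
        data[i] += _pink_noise(rng, n, scn.pink_amp_uv * 1e-6, scn.pink_slope)
        data[i] += rng.normal(0.0, scn.noise_rms_uv * 1e-6, n)
        if scn.mains_amp_uv > 0:
            data[i] += scn.mains_amp_uv * 1e-6 * np.sin(2 * np.pi * scn.mains_hz * t)
    return data, blocks


@dataclass
class OpticalGroundTruth:
    """Haemodynamic ground truth plus the intensities it forward-models to."""

    haemo: HaemoSeries                     # at f_s, uM
    dod: dict                              # (source, wl) -> dOD at f_s
    intensities: dict                      # (source, wl) -> detector volts at f_s
    params: MbllParameters


def gen_breath_hold_optical(
    scn: PhysioScenario,
    plan: IlluminationPlan,
    params: MbllParameters | None = None,
) -> OpticalGroundTruth:
    """Breath-hold haemodynamics forward-modelled to per-state intensities.

    Cardiac (~1 Hz) and respiratory (0.2-0.4 Hz band) oscillations ride on a
    smooth dHbO rise (dHbR dip) after the breath-hold onset; the same ground
    truth drives every source in the plan via the forward MBLL, with
    ``I = I0 * 10^-dOD``.
    """
    params = params or MbllParameters()
    sources = {s for s, _ in plan.emitters}
    for src in sources:
        wls = {w for s, w in plan.emitters if s == src}
        if wls != {750, 850}:
            raise ScenarioError(
                f"source {src} is missing a wavelength (has {sorted(wls)}); "
                "the scenario needs both 750 and 850 nm per source"
            )
    if not sources:
        raise ScenarioError("plan addresses no emitters")

    n = scn.n_frames
    t = np.arange(n) / scn.fs_hz
    rise = 1.0 / (1.0 + np.exp(-(t - scn.breath_hold_onset_s) / (scn.breath_hold_rise_s / 4)))
    hbo = (
        scn.cardiac_amp_hbo_um * np.sin(2 * np.pi * scn.cardiac_hz * t)
        + scn.resp_amp_hbo_um * np.sin(2 * np.pi * scn.resp_hz * t)
        + scn.breath_hold_amp_hbo_um * rise
    )
    hbr = (
        scn.cardiac_amp_hbr_um * np.sin(2 * np.pi * scn.cardiac_hz * t)
        + scn.resp_amp_hbr_um * np.sin(2 * np.pi * scn.resp_hz * t)
        + scn.breath_hold_amp_hbr_um * rise
    )
    haemo = HaemoSeries(hbo=hbo, hbr=hbr, rate_hz=scn.fs_hz)
    dod_750, dod_850 = mbll_forward(haemo, params)
    dod = {}
    intensities = {}
    for src in sorted(sources):
        dod[(src, 750)] = dod_750
        dod[(src, 850)] = dod_850
        intensities[(src, 750)] = scn.baseline_intensity_v * 10.0 ** (-dod_750)
        intensities[(src, 850)] = scn.baseline_intensity_v * 10.0 ** (-dod_850)
    return OpticalGroundTruth(haemo=haemo, dod=dod, intensities=intensities, params=params)


def gen_ecg_ppg(scn: PhysioScenario, rng: np.random.Generator | None = None):
    """ECG template train plus a delayed optical pulse channel.

    Each PPG pulse peak lags its R-peak by exactly the configured
    pulse-transit delay (in whole frames, before noise).  Returns
    ``(ecg_volts [n], ppg_volts [n], r_peak_frames)``.  The ECG is a simple
    R-dominant template train, adequate for lag and peak-count analyses, not
    a full electrophysiological model.
    """
    rng = rng or np.random.default_rng(scn.seed)
    if scn.ptt_delay_s < 0:
        raise ScenarioError("pulse-transit delay must be non-negative")
    n = scn.n_frames
    fs = scn.fs_hz
    beat_frames = 60.0 / scn.heart_rate_bpm * fs

    # R wave: narrow gaussian; small P and T humps for shape realism
    tt = np.arange(-int(0.3 * fs), int(0.4 * fs) + 1) / fs
    ecg_tmpl = (
        1.00 * np.exp(-0.5 * (tt / 0.012) ** 2)
        + 0.15 * np.exp(-0.5 * ((tt + 0.17) / 0.025) ** 2)
        + 0.25 * np.exp(-0.5 * ((tt - 0.22) / 0.045) ** 2)
    )
    ecg_tmpl_peak = int(np.argmax(ecg_tmpl))

    # PPG pulse: gamma-like rise/decay, unit peak
    tp = np.arange(0, int(0.8 * fs)) / fs
    ppg_tmpl = (tp / 0.12) ** 2 * np.exp(-tp / 0.12)
    ppg_tmpl /= ppg_tmpl.max()
    ppg_tmpl_peak = int(np.argmax(ppg_tmpl))

    delay_frames = int(round(scn.ptt_delay_s * fs))
    ecg = np.zeros(n)
    ppg = np.zeros(n)
    r_peaks = []
    k = 1
    while True:
        r = int(round(k * beat_frames))
        if r >= n - int(0.5 * fs):
            break
        r_peaks.append(r)
        lo = r - ecg_tmpl_peak
        seg = slice(max(lo, 0), min(lo + ecg_tmpl.size, n))
        ecg[seg] += scn.ecg_amp_v * ecg_tmpl[seg.start - lo : seg.stop - lo]
        p0 = r + delay_frames - ppg_tmpl_peak
        seg = slice(max(p0, 0), min(p0 + ppg_tmpl.size, n))
        ppg[seg] += scn.ppg_amp_v * ppg_tmpl[seg.start - p0 : seg.stop - p0]
        k += 1
    ecg += rng.normal(0.0, scn.noise_rms_uv * 1e-6, n)
    return ecg, ppg, np.array(r_peaks, dtype=int)


# ---------------------------------------------------------------------------
# digitisation

def digitise(
    cmap: ChannelMap,
    plan: IlluminationPlan,
    n_frames: int,
    eeg: np.ndarray | None = None,
    optical: dict | None = None,
    aux: np.ndarray | None = None,
    dark_v: float = 0.0,
    detector_noise_rms_v: float = 0.0,
    rng: np.random.Generator | None = None,
    start_frame: int = 0,
) -> FrameBlock:
    """Digitise continuous signals into a conversion-frame sequence.

    Every frame carries samples for all enabled channels.  Optical channels
    see the intensity of the currently active illumination state only (the
    detector observes the lit source); during blanking they read ``dark_v``.
    Status words follow the plan walk; samples are quantised to 24 bits at
    the per-channel (Vref/gain) full scale, clipping (and hence flagging
    saturation) beyond it.

    ``eeg``/``aux`` are (n_role_channels, n_frames) volts in map order;
    ``optical`` maps (source, wavelength) to a (n_frames,) intensity trace
    shared by all optical channels, or to (n_optical_channels, n_frames).
    """
    idx = start_frame + np.arange(n_frames)
    state_ids = plan.state_ids_for_frames(idx)
    status_row = plan.status_words_for_frames(idx)
    status = np.tile(status_row[:, np.newaxis], (1, cmap.n_devices))

    volts = np.zeros((n_frames, cmap.n_enabled))
    for role, sig in (("eeg", eeg), ("aux", aux)):
        cols = cmap.by_role(role)
        if sig is None:
            if cols:
                volts[:, cols] = 0.0
            continue
        sig = np.atleast_2d(np.asarray(sig, dtype=float))
        if sig.shape != (len(cols), n_frames):
            raise StructuralError(
                f"{role} signal shape {sig.shape} does not match "
                f"({len(cols)}, {n_frames}) from the channel map"
            )
        volts[:, cols] = sig.T

    opt_cols = cmap.by_role("optical")
    if opt_cols:
        opt_vals = np.full((n_frames, len(opt_cols)), dark_v)
        for sid, state in enumerate(plan.states):
            if state.is_blank:
                continue
            key = (state.source_index, state.wavelength)
            mask = state_ids == sid
            if not mask.any():
                continue
            if optical is None or key not in optical:
                raise StructuralError(f"no optical signal supplied for active state {key}")
            trace = np.asarray(optical[key], dtype=float)
            if trace.ndim == 1:
                opt_vals[mask, :] = trace[mask][:, np.newaxis]
            else:
                if trace.shape != (len(opt_cols), n_frames):
                    raise StructuralError(
                        f"optical trace for {key} has shape {trace.shape}, expected "
                        f"({len(opt_cols)}, {n_frames})"
                    )
                opt_vals[mask, :] = trace.T[mask]
        if detector_noise_rms_v > 0:
            rng = rng or np.random.default_rng(0)
            opt_vals = opt_vals + rng.normal(0.0, detector_noise_rms_v, opt_vals.shape)
        volts[:, opt_cols] = opt_vals

    lsb = (cmap.vrefs / cmap.gains) / float(1 << 23)
    codes = np.clip(
        np.rint(volts / lsb[np.newaxis, :]), -(1 << 23), (1 << 23) - 1
    ).astype(np.int32)
    return FrameBlock(status=status, codes=codes, first_frame_index=start_frame)


# ---------------------------------------------------------------------------
# scenario assembly

def default_channel_map(scenario: str) -> ChannelMap:
    if scenario == "test_signal":
        return ChannelMap.uniform(n_devices=4, n_channels=8, role="eeg")
    if scenario == "alpha_blocks":
        chans = [
            ChannelConfig(lab, role="eeg", posterior=lab in POSTERIOR_CHANNELS)
            for lab in ALPHA_MONTAGE
        ]
        return ChannelMap.from_channels(chans)
    if scenario == "breath_hold":
        chans = [ChannelConfig(f"EEG{i + 1}", role="eeg") for i in range(4)] + [
            ChannelConfig("DET1", role="optical", gain=1),
            ChannelConfig("DET2", role="optical", gain=1),
        ]
        return ChannelMap.from_channels(chans)
    if scenario == "ecg_ppg":
        return ChannelMap.from_channels(
            [
                ChannelConfig("ECG", role="aux", gain=12),
                ChannelConfig("PPG", role="optical", gain=1),
            ]
        )
    raise ScenarioError(f"unknown scenario {scenario!r}")


def default_scenario_plan(scenario: str, fs_hz: float) -> IlluminationPlan:
    if scenario in ("test_signal", "alpha_blocks"):
        # EEG-only: a single blanking state; N_state = 1 so f_state = f_s
        return IlluminationPlan([IlluminationState(state_id=0)], fs_hz=fs_hz)
    if scenario == "breath_hold":
        return default_plan(n_sources=1, fs_hz=fs_hz, drive_current_ma=50.0, blanking_frames=1)
    if scenario == "ecg_ppg":
        return IlluminationPlan(
            [IlluminationState(state_id=0, source_index=0, wavelength=850, drive_current_ma=25.0)],
            fs_hz=fs_hz,
        )
    raise ScenarioError(f"unknown scenario {scenario!r}")


@dataclass
class EmulatedSession:
    """Frames plus everything needed to decode and verify them."""

    scenario: PhysioScenario
    cmap: ChannelMap
    plan: IlluminationPlan
    frames: FrameBlock
    ground_truth: dict = field(default_factory=dict)

    def sidecar_extra(self) -> dict:
        return {"scenario": self.scenario.to_dict()}


def run_scenario(
    scn: PhysioScenario,
    cmap: ChannelMap | None = None,
    plan: IlluminationPlan | None = None,
    mbll_params: MbllParameters | None = None,
) -> EmulatedSession:
    """Generate one complete emulated session, bit-identical for a given seed."""
    cmap = cmap or default_channel_map(scn.scenario)
    plan = plan or default_scenario_plan(scn.scenario, scn.fs_hz)
    rng = np.random.default_rng(scn.seed)
    gt: dict = {}

    if scn.scenario == "test_signal":
        data = gen_test_signal(
            scn.fs_hz,
            scn.duration_s,
            amplitude_v=scn.test_amplitude_v,
            period_frames=scn.test_period_frames,
            n_channels=cmap.n_enabled,
        )
        frames = digitise(cmap, plan, data.shape[1], eeg=data)
        gt = {"signal": data, "period_frames": scn.test_period_frames}
    elif scn.scenario == "alpha_blocks":
        data, blocks = gen_alpha_eeg(scn, rng)
        frames = digitise(cmap, plan, data.shape[1], eeg=data)
        gt = {"eeg": data, "blocks": blocks}
    elif scn.scenario == "breath_hold":
        truth = gen_breath_hold_optical(scn, plan, mbll_params)
        n = scn.n_frames
        n_eeg = len(cmap.by_role("eeg"))
        eeg = rng.normal(0.0, scn.noise_rms_uv * 1e-6, (n_eeg, n)) if n_eeg else None
        frames = digitise(
            cmap,
            plan,
            n,
            eeg=eeg,
            optical=truth.intensities,
            detector_noise_rms_v=scn.detector_noise_rms_v,
            rng=rng,
        )
        gt = {"optical": truth}
    elif scn.scenario == "ecg_ppg":
        ecg, ppg, r_peaks = gen_ecg_ppg(scn, rng)
        key = next(iter(plan.emitters))
        frames = digitise(
            cmap,
            plan,
            ecg.size,
            aux=ecg[np.newaxis, :],
            optical={key: scn.baseline_intensity_v + ppg},
            detector_noise_rms_v=scn.detector_noise_rms_v,
            rng=rng,
        )
        gt = {"ecg": ecg, "ppg": ppg, "r_peaks": r_peaks, "delay_s": scn.ptt_delay_s}
    else:  # pragma: no cover - guarded in PhysioScenario
        raise ScenarioError(scn.scenario)

    return EmulatedSession(scenario=scn, cmap=cmap, plan=plan, frames=frames, ground_truth=gt)
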