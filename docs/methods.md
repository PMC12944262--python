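# Methods

This note documents the models implemented in `biomux`, the parameters that
matter, what the emulator does and does not reproduce, and the design choices
made where the instrument's public description leaves the details open.

## Acquisition model and frame dialect

The instrument digitises every enabled channel — EEG, optical detector, and
auxiliary — on each conversion instant of a shared-clock ensemble of up to
four 8-channel, 24-bit delta-sigma converters. A conversion frame is encoded
per device as a 24-bit status word followed by one 24-bit two's-complement
sample per enabled channel, MSB first (the converter's own byte order). Frame
size is therefore Σ(3 + 3·n<sub>ch</sub>) bytes over devices: 108 bytes for
the full 4 × 8 configuration.

The firmware overwrites the entire status word with an illumination-state
identifier. The bit layout is a convention of this implementation (the
hardware description names the content, not the packing):

| bits  | field          | range |
|-------|----------------|-------|
| 23–16 | state id       | 0–255 |
| 15–10 | source index   | 0–63  |
| 9–8   | wavelength     | 00 none/blank, 01 750 nm, 10 850 nm |
| 7     | blanking flag  | —     |
| 6–0   | reserved       | 0     |

This covers the driver bank's 64-emitter maximum with headroom. All native
status bits (sync nibble, lead-off flags) are treated as overwritten;
lead-off and register-level converter behaviour are out of scope.

Analogue scaling: code *c* maps to *c*·(V<sub>ref</sub>/gain)/2²³ volts;
defaults V<sub>ref</sub> = 4.5 V, PGA gain 24 (datasheet-typical), per-channel
configurable. Saturation is flagged when |code| comes within a configurable
margin (default 256) of full scale, the "near full-scale" criterion. The
frame index is a host-side counter, implicit in logs by position.

## Illumination scheduling

An illumination plan is an ordered list of states — (source, wavelength,
drive current, dwell in frames) or blanking — advanced only at frame
boundaries, so the schedule is a pure, periodic function of the frame index.
With all dwells equal to one frame, each state's series rate is exactly
f<sub>s</sub>/N<sub>state</sub>; general dwells are supported and the
effective per-state rate generalises to f<sub>s</sub>·(dwell/period).

Constraints enforced: one wavelength lit per state (mutual exclusion is
structural), drive current ≤ 60 mA per driver channel (the constant-current
sink limit at the 3.3 V supply), and emitter addressing within
16 × n<sub>drivers</sub> single-wavelength channels (dual-wavelength packages
occupy two channels, so four drivers give 64 emitters / 32 packages). The
current limit is checked by the plan validator rather than at state
construction so that an over-current plan can be constructed and rejected
with a report listing the offending states. Greyscale PWM and dot correction
are modelled only as stable current set-points; no PWM waveform or thermal
transient is simulated.

Default plan shape: round-robin over sources and wavelengths, one frame per
state, with one blanking frame inserted after each wavelength dwell
(configurable, 0 disables blanking). Dwell counts are not specified by the
instrument's description; one frame per state is the default.

Mean LED dissipation per emitter is I·V<sub>f</sub>·duty with
V<sub>f</sub> = 1.7 V by default (midpoint of the emitter's 1.55–1.85 V
typical range); under strict TDM the cycle total depends only on current and
lit duty, not emitter count — e.g. a 10-emitter single-frame cycle at 50 mA
dissipates 8.5 mW per emitter and 85 mW total.

## Signal emulator

The emulator generates ground-truth-known scenarios and digitises them
through a channel map and plan. All stochastic draws come from one
per-scenario seed, so frame logs are bit-identical across runs; the ground
truth is retained beside the frames so every downstream stage has a recovery
target. Scenario amplitudes are free parameters (the corresponding real
recordings are not tabulated), so validation rests on recovery and contrast
properties, not absolute reproduction.

- **test_signal** — a ±1.875 mV square wave (128-frame period; both are
  emulator conventions, configurable) identical and phase-aligned on all 32
  channels, the multi-device synchronisation check. No noise, so digitised
  channels are bitwise identical.
- **alpha_blocks** — a 12-channel montage (O1, O2, T3, T5, Pz, Cz, C4, C3,
  P4, P3, T4, T6) with alternating 30 s eyes-open/eyes-closed blocks over
  5 min. Posterior channels (O1, O2, Pz, P3, P4) carry a 10 Hz sinusoid
  (10 µV) at full amplitude when closed, attenuated ×0.25 when open, on a
  1/f background (2 µV RMS, slope 1) plus white noise at the converter's
  0.57 µV RMS input-referred floor. 50 Hz interference is available, off by
  default.
- **breath_hold** — haemodynamic ground truth in µM: cardiac (1.0 Hz;
  0.20/0.05 µM on HbO/HbR) and respiratory (0.3 Hz; 0.30/0.08 µM)
  oscillations plus a smooth breath-hold response (logistic rise over ~8 s at
  onset 90 s; +1.5 µM HbO, −0.4 µM HbR) — conventional magnitudes for a
  forehead breath-hold. Intensities follow the forward MBLL,
  I = I₀·10^(−ΔOD), I₀ = 1 V at the detector, with 300 µV RMS detector
  output noise (the photoreceiver's datasheet figure).
- **ecg_ppg** — an R-dominant ECG template train (not a full
  electrophysiological model) at 60 bpm plus a gamma-shaped optical pulse
  whose apex lags each R-peak by exactly the configured pulse-transit delay
  (default 250 ms, rounded to whole frames) before noise.

Digitisation quantises to 24 bits at the per-channel full scale (error
bounded by 1 LSB in range, clipping and flagging saturation beyond), writes
the plan's status word into every frame, and gives optical channels the
intensity of the currently active state only (dark level during blanking).

Not emulated: tissue photon transport, motion artefacts, electrode impedance,
ambient-light dynamics (a static dark offset is supported), receiver-side
timestamp jitter. Passing tests therefore demonstrate the correctness of the
data path and analyses under ideal-physics synthetic physiology, not
robustness to real-world artefact.

## Streaming protocol

The control channel is line-oriented ASCII — `SETUP key=value ...`, `START`,
`STOP`, `STATUS`, replies `OK [payload]` / `ERR reason` — with one control
and one data connection. The grammar, packet framing (4-byte little-endian
length prefix, whole frames only, default 25 frames/packet, zero-length
terminator) and flow-control window are this implementation's dialect; the
instrument's description fixes only the verbs and the halt-on-overrun
semantics. SETUP is rejected while streaming; parameters are immutable
within a session. The sender uses a bounded buffer (default 256 packets);
back-pressure beyond it halts the session with an overrun status rather than
growing without bound. Frame content is produced from the session
configuration and frame counter alone — socket readiness throttles
transmission but never alters acquisition content. The receiver derives
sample times purely from frame position and f<sub>s</sub>; arrival times are
transport metadata. Publication is a sink interface (in-memory, log-writer,
and an LSL outlet that requires the optional `pylsl`).

## Demultiplexing and decimation

Optical samples are grouped by the embedded (source, wavelength) identifiers
decoded from each frame's status word — never by frame arithmetic — so the
result is invariant to packet re-chunking and robust to missing frames, and
a state id absent from the plan raises an integrity error with the frame
index. Blanking-frame detector readings are discarded and counted (they
exist to reduce cross-coupling, not as measurements); optionally they serve
as a dark reference, linearly interpolated and subtracted (ambient
subtraction, off by default since it is not known whether the firmware
interleaves dedicated dark measurements). EEG and auxiliary channels pass
through at f<sub>s</sub> untouched. Detector-to-source association is a
channel-map matter; by default every optical input observes every source.

Decimation applies a zero-phase FIR low-pass with cutoff 0.4 × target rate
(Kaiser design, ≥ 60 dB stopband by 0.5 × target) and then downsamples,
polyphase for non-integer ratios. DC gain is unity, so baselines survive.

## Modified Beer–Lambert law

ΔOD(λ, t) = −log₁₀ I(t)/I₀ with I₀ the mean over a baseline window (default
first 30 s; optional linear detrend in the log domain). Non-positive
intensities raise a data error rather than being clipped. Concentrations
solve the 2 × 2 system ΔOD(λ) = [ε(λ,HbO)·ΔHbO + ε(λ,HbR)·ΔHbR]·d·DPF(λ);
the solver reports the matrix condition number and rejects singular
parameterisations. Forward and inverse are exact linear inverses, so the
noise-free round trip is identity to machine precision.

Defaults (all overridable): Gratzer/Prahl molar extinction coefficients —
ε(750) = 518.0 (HbO) / 1405.24 (HbR), ε(850) = 1058.0 / 691.32 cm⁻¹ M⁻¹ —
DPF 6.0 at both wavelengths, separation d = 3.0 cm (conventional adult
forehead values). The instrument's own analyses name the quantities but not
these parameters, so absolute µM scales here are parameterisation-dependent;
spectral shape and recovery properties are what the tests assert.

## Power model

Nominal energy is capacity × voltage (2500 mAh × 3.7 V = 9.25 Wh); usable
energy applies an efficiency factor (default 0.8 → 7.4 Wh) standing in for
regulator and conversion losses, since the derating is quoted as a practical
estimate without a component-level derivation. Runtime is usable energy over
mode power, reported to one decimal, half-up — matching the precision of the
bundled mode table, whose powers are measured end-to-end values rounded to
10 mW. The photoreceiver NEP is (output noise / transimpedance) /
(√bandwidth × responsivity); the datasheet inputs (300 µV RMS, 0.1 Hz–20 kHz,
1 MΩ, 0.45 A/W) give ≈ 4.7 × 10⁻¹² W/√Hz. Battery discharge curves and
component-level current decomposition are out of scope.

## Validation analyses

Welch PSDs use 4 s Hann windows with 50% overlap (unstated upstream; these
are conventional EEG choices). Block PSDs are grand averages of per-block
estimates per condition; blocks shorter than two windows are skipped with a
warning. The alpha contrast is the closed/open band-power ratio (8–12 Hz
band, with the 9–11 Hz sub-band also defined) on the posterior channel set.
The ΔHbT spectrum uses up to 60 s windows (≈ 0.017 Hz bins) after linear
detrending and reports argmax peaks in the cardiac (0.8–1.2 Hz) and
respiratory (0.2–0.4 Hz) bands. R-peaks are detected by thresholding
band-passed (5–25 Hz) ECG with a 0.3 s refractory period and refined to the
raw local maximum — adequate for template ECG, not clinical-grade. Optical
pulse peaks are located on a Savitzky–Golay-smoothed trace (a zero-phase
low-pass would skew the asymmetric pulse apex and bias the lag); each R-peak
is matched to the next pulse peak within 0.6 s and the lag is their median
interval.

## Problem sizes and numerical choices

The conservation/effective-rate law is exercised on a 10⁶-frame synthetic
log at 16 kSPS through the vectorised columnar frame path; transport
losslessness on a 10⁵-frame TCP loopback session; the emulated validation
analyses on their natural durations (5 min alpha, 3 min breath-hold, 1 min
ECG/PPG). Ties in quantisation round half away from zero via `np.rint`
conventions; runtime rounding is decimal half-up. Degenerate inputs (empty
plans, empty baselines, truncated logs, stalled clients, singular extinction
matrices) raise typed errors or warn-and-recover as documented per module.

## Known limitations

- The emulator's optical model is algebraic (forward MBLL on a shared ground
  truth per source); it does not model optode geometry, partial-volume
  effects or superficial contamination.
- The exact N<sub>state</sub>, blanking configuration and MBLL
  parameterisation behind the instrument's own validation recordings are not
  published, so those figures are reproduced as properties (peak locations,
  contrast directions, recovery errors), not absolute traces.
- Receiver-side timestamp jitter/drift characterisation is explicitly out of
  scope; the package treats arrival times as metadata only.
- The ASCII/TCP dialect (packet header, window sizes) is an implementation
  convention and is documented as such in the sidecar metadata.
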