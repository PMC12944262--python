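# biomux

Reference software implementation of the data path of a mobile, battery-powered
32-channel EEG/fNIRS instrument: a bit-exact conversion-frame codec with the
active illumination state embedded in each frame's status word, clock-locked
time-division-multiplexed (TDM) LED scheduling and receiver-side
demultiplexing, modified Beer–Lambert haemoglobin estimation, a TCP streaming
protocol with a physiologically realistic device emulator, and the
instrument's power/runtime budget model.

It is intended for researchers and engineers who work with hybrid EEG–fNIRS
acquisition: to prototype receivers and analysis pipelines against a
ground-truth-known emulator, to validate demultiplexing and synchronisation
logic, and to budget battery runtime for untethered recordings.

## The model

All channels — EEG electrodes and optical detectors alike — are digitised by
the same ensemble of 24-bit biopotential converters (up to four devices, eight
channels each) on every conversion instant, locked to one master clock.
Illumination is strictly time-multiplexed: exactly one LED wavelength is lit
per conversion frame, the state advancing only at frame boundaries. With ADC
output rate *f*<sub>s</sub> and an illumination cycle of *N*<sub>state</sub>
discrete states (blanking intervals included), each optical series is sampled
at the effective rate

&nbsp;&nbsp;&nbsp;&nbsp;*f*<sub>state</sub> = *f*<sub>s</sub> / *N*<sub>state</sub>.

Each frame is a 24-bit status word followed by 24-bit two's-complement samples
per enabled channel; the firmware overwrites the status word with the active
(source, wavelength, blanking) identifier, so optical demultiplexing uses only
embedded state ids — never packet ordering or software timestamps — and EEG
and fNIRS share a single hardware-defined timeline.

Dual-wavelength (750/850 nm) intensity series are converted to concentration
changes with the modified Beer–Lambert law: ΔOD(λ, t) = −log₁₀ I(t)/I₀, then
per time point

&nbsp;&nbsp;&nbsp;&nbsp;ΔOD(λ) = [ε(λ, HbO)·ΔHbO + ε(λ, HbR)·ΔHbR] · d · DPF(λ),

solved for ΔHbO/ΔHbR (µM), with ΔHbT = ΔHbO + ΔHbR. Battery runtime per
operating mode is usable energy divided by measured mode power; strict TDM
makes mean LED dissipation depend only on drive current and duty, not emitter
count.

## Worked example

Emulate a 20 s breath-hold fNIRS recording, demultiplex it, and run the
validation analyses:

```sh
$ biomux emulate --scenario breath_hold --duration 20 --seed 1 --out bh.frames
breath_hold: 5000 frames, 6 channels at 250 SPS (N_state=4, f_state=62.5 Hz)
wrote bh.frames (+.json sidecar)

$ biomux demux --log bh.frames --out-dir bh_demux
5000 frames -> 4 EEG, 0 aux, 4 optical series; 2500 blanking frames discarded

$ biomux validate --scenario breath_hold --seed 2 --duration 120
dHbT spectral peaks: cardiac 1.0 Hz, respiratory 0.3 Hz

$ biomux validate --scenario ecg_ppg --seed 2
pulse-transit lag: 248.0 ms over 59 beats (configured 250 ms)

$ biomux power
nominal 9.25 Wh, usable 7.40 Wh
mode                                        mW runtime h
EEG-only, local storage                    280      26.4
EEG-only, local storage                    400      18.5
EEG + fNIRS (nominal)                      470      15.7
EEG + fNIRS (high optical)                 530      14.0
...
```

Reading the output: the breath-hold plan cycles 750 nm → blank → 850 nm →
blank, so 5000 frames at 250 SPS yield four optical series of 1250 samples at
62.5 Hz each (the 2500 blanking frames are discarded from optics and counted
for QC). The ΔHbT spectrum of the demultiplexed, MBLL-inverted data peaks at
the emulator's cardiac (1.0 Hz) and respiratory (0.3 Hz) frequencies, and the
ECG-to-pulse lag recovers the configured 250 ms pulse-transit delay to within
one 4 ms sample. The power table divides 7.4 Wh usable energy by each mode's
measured draw.

The same functionality is available as a library:

```python
from biomux import PhysioScenario, run_scenario, demux

session = run_scenario(PhysioScenario(scenario="breath_hold", duration_s=120, seed=2))
result = demux(session.frames, session.cmap, session.plan)
series = result.series(0, 850)        # (source 0, 850 nm) intensity at f_state
```

## Layout

- `src/biomux/frame_codec.py` — 24-bit frame/status codec, channel maps, logs
- `src/biomux/tdm_scheduler.py` — illumination plans, capacity, LED duty power
- `src/biomux/signal_emulator.py` — scenario generators and the digitiser
- `src/biomux/stream_protocol.py` — ASCII control + TCP streaming, sinks
- `src/biomux/demux_reconstruct.py` — state-id demux, decimation
- `src/biomux/haemodynamics.py` — MBLL forward/inverse
- `src/biomux/power_model.py` — energy budget, runtimes, NEP
- `src/biomux/analysis_validation.py` — PSD contrast, spectra, PTT lag
- `docs/methods.md` — model assumptions, parameters, design choices
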