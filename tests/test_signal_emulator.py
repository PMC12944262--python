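"""Emulator: waveform construction, digitisation, reproducibility."""

import numpy as np
import pytest

from biomux.frame_codec import FULL_SCALE, ChannelConfig, ChannelMap, is_saturated
from biomux.signal_emulator import (
    PhysioScenario,
    ScenarioError,
    default_scenario_plan,
    digitise,
    gen_alpha_eeg,
    gen_breath_hold_optical,
    gen_ecg_ppg,
    gen_test_signal,
    run_scenario,
)
from biomux.tdm_scheduler import IlluminationPlan, IlluminationState, default_plan


# ---------------------------------------------------------------------------
# test signal

def test_square_wave_takes_two_values():
    sig = gen_test_signal(250, 4.0, amplitude_v=2e-3, period_frames=64)
    assert set(np.unique(sig)) == {-2e-3, 2e-3}


def test_square_wave_edges_at_half_period_multiples():
    period = 64
    sig = gen_test_signal(250, 4.0, period_frames=period)[0]
    edges = np.nonzero(np.diff(sig) != 0)[0] + 1  # edge-detection oracle
    assert edges.size > 0
    assert np.all(edges % (period // 2) == 0)


def test_all_32_channels_bitwise_identical_after_digitisation():
    session = run_scenario(PhysioScenario(scenario="test_signal", duration_s=2.0, seed=0))
    codes = session.frames.codes
    assert codes.shape[1] == 32
    assert np.all(codes == codes[:, [0]])  # every channel identical, frame by frame


def test_short_period_rejected():
    with pytest.raises(ScenarioError):
        gen_test_signal(250, 1.0, period_frames=1)


# ---------------------------------------------------------------------------
# alpha blocks

def test_alpha_blocks_partition_timeline():
    scn = PhysioScenario(scenario="alpha_blocks", duration_s=95.0, seed=1)
    data, blocks = gen_alpha_eeg(scn)
    assert blocks[0].start_frame == 0
    assert blocks[-1].stop_frame == data.shape[1]
    for a, b in zip(blocks, blocks[1:]):
        assert a.stop_frame == b.start_frame
        assert a.condition != b.condition


def test_zero_alpha_amplitude_equalises_conditions():
    from biomux.analysis_validation import alpha_contrast, block_psd
    from biomux.signal_emulator import POSTERIOR_CHANNELS, ALPHA_MONTAGE

    scn = PhysioScenario(scenario="alpha_blocks", duration_s=300.0, seed=2, alpha_amp_uv=0.0)
    data, blocks = gen_alpha_eeg(scn)
    per_cond = block_psd(
        dict(zip(ALPHA_MONTAGE, data)), scn.fs_hz, blocks, channels=POSTERIOR_CHANNELS
    )
    contrast = alpha_contrast(per_cond["open"], per_cond["closed"])
    assert 0.5 < contrast.pooled_ratio < 2.0  # equal within sampling error


# ---------------------------------------------------------------------------
# breath-hold optics

def test_zero_haemodynamics_give_constant_intensities(plan4):
    scn = PhysioScenario(
        scenario="breath_hold",
        duration_s=20.0,
        cardiac_amp_hbo_um=0.0,
        cardiac_amp_hbr_um=0.0,
        resp_amp_hbo_um=0.0,
        resp_amp_hbr_um=0.0,
        breath_hold_amp_hbo_um=0.0,
        breath_hold_amp_hbr_um=0.0,
    )
    truth = gen_breath_hold_optical(scn, plan4)
    for trace in truth.intensities.values():
        np.testing.assert_allclose(trace, scn.baseline_intensity_v, rtol=1e-12)


def test_ground_truth_has_configured_spectral_peaks(plan4):
    from scipy.signal import periodogram

    scn = PhysioScenario(scenario="breath_hold", duration_s=120.0, breath_hold_onset_s=300.0)
    truth = gen_breath_hold_optical(scn, plan4)
    f, p = periodogram(truth.haemo.hbt, fs=scn.fs_hz)
    sel = (f > 0.6) & (f < 1.4)
    assert abs(f[sel][np.argmax(p[sel])] - scn.cardiac_hz) < 0.02
    sel = (f > 0.15) & (f < 0.45)
    assert abs(f[sel][np.argmax(p[sel])] - scn.resp_hz) < 0.02


def test_plan_missing_wavelength_is_scenario_error():
    plan = IlluminationPlan(
        [IlluminationState(0, 0, 750, 30.0)], fs_hz=250
    )  # no 850 nm
    with pytest.raises(ScenarioError, match="wavelength"):
        gen_breath_hold_optical(PhysioScenario(scenario="breath_hold", duration_s=5.0), plan)


# ---------------------------------------------------------------------------
# ECG / PPG

def test_ppg_peak_lags_r_peak_by_exact_delay():
    scn = PhysioScenario(scenario="ecg_ppg", duration_s=30.0, ptt_delay_s=0.25, seed=3)
    ecg, ppg, r_peaks = gen_ecg_ppg(scn)
    delay = int(round(0.25 * scn.fs_hz))
    for r in r_peaks:
        seg = ppg[r : r + int(scn.fs_hz)]  # within this beat
        assert np.argmax(seg) == delay     # noise-free construction is exact


def test_zero_delay_aligns_peaks():
    scn = PhysioScenario(scenario="ecg_ppg", duration_s=20.0, ptt_delay_s=0.0, seed=3)
    _, ppg, r_peaks = gen_ecg_ppg(scn)
    for r in r_peaks:
        lo = max(r - 50, 0)
        assert lo + np.argmax(ppg[lo : r + 50]) == r


def test_r_peak_count_matches_heart_rate():
    scn = PhysioScenario(scenario="ecg_ppg", duration_s=120.0, heart_rate_bpm=60.0, seed=4)
    _, _, r_peaks = gen_ecg_ppg(scn)
    assert abs(len(r_peaks) - 2 * 60) <= 1


# ---------------------------------------------------------------------------
# digitisation

def test_dc_input_quantises_to_definition():
    cmap = ChannelMap.uniform(1, 2, gain=24, vref=4.5)
    plan = default_scenario_plan("test_signal", 250)
    v = 1.234e-3
    frames = digitise(cmap, plan, 10, eeg=np.full((2, 10), v))
    expected = round(v * 24 / 4.5 * FULL_SCALE)
    assert np.all(frames.codes == expected)


def test_over_range_input_clips_and_saturates():
    cmap = ChannelMap.uniform(1, 1, gain=24, vref=4.5)
    plan = default_scenario_plan("test_signal", 250)
    fs_v = 4.5 / 24
    frames = digitise(cmap, plan, 5, eeg=np.full((1, 5), 2 * fs_v))
    assert np.all(frames.codes == FULL_SCALE - 1)
    assert np.all(is_saturated(frames.codes))
    frames = digitise(cmap, plan, 5, eeg=np.full((1, 5), -2 * fs_v))
    assert np.all(frames.codes == -FULL_SCALE)


def test_quantisation_error_within_one_lsb():
    rng = np.random.default_rng(5)
    cmap = ChannelMap.uniform(1, 4, gain=24, vref=4.5)
    plan = default_scenario_plan("test_signal", 250)
    lsb = (4.5 / 24) / FULL_SCALE
    sig = rng.uniform(-0.9 * 4.5 / 24, 0.9 * 4.5 / 24, (4, 100))
    frames = digitise(cmap, plan, 100, eeg=sig)
    back = frames.volts(cmap)
    assert np.abs(back - sig.T).max() <= lsb


def test_status_sequence_equals_plan_walk(plan4, mixed_cmap):
    n = 1000
    optical = {k: np.ones(n) for k in plan4.emitters}
    frames = digitise(mixed_cmap, plan4, n, eeg=np.zeros((4, n)), optical=optical)
    np.testing.assert_array_equal(
        frames.state_ids, plan4.state_ids_for_frames(np.arange(n))
    )  # scheduler oracle
    for i in (0, 17, 999):
        s = plan4.state_for_frame(i)
        assert frames.source_indices[i] == s.source_index


def test_signal_map_mismatch_is_error(mixed_cmap, plan4):
    from biomux.frame_codec import StructuralError

    with pytest.raises(StructuralError):
        digitise(mixed_cmap, plan4, 10, eeg=np.zeros((3, 10)))  # map has 4 EEG


def test_missing_optical_trace_is_error(mixed_cmap, plan4):
    from biomux.frame_codec import StructuralError

    with pytest.raises(StructuralError):
        digitise(mixed_cmap, plan4, 10, eeg=np.zeros((4, 10)), optical={})


# ---------------------------------------------------------------------------
# reproducibility

@pytest.mark.parametrize("scenario,duration", [
    ("alpha_blocks", 35.0),
    ("breath_hold", 12.0),
    ("ecg_ppg", 10.0),
])
def test_identical_seed_gives_bit_identical_frames(scenario, duration):
    a = run_scenario(PhysioScenario(scenario=scenario, duration_s=duration, seed=11))
    b = run_scenario(PhysioScenario(scenario=scenario, duration_s=duration, seed=11))
    c = run_scenario(PhysioScenario(scenario=scenario, duration_s=duration, seed=12))
    assert a.frames == b.frames
    assert a.frames != c.frames
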