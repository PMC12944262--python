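"""Demultiplexing: state grouping, conservation, timeline, decimation."""

import numpy as np
import pytest

from biomux.demux_reconstruct import IntegrityError, OpticalSeries, decimate, demux
from biomux.frame_codec import FrameBlock, StatusWord
from biomux.signal_emulator import PhysioScenario, digitise, run_scenario
from biomux.tdm_scheduler import IlluminationPlan, IlluminationState, default_plan


def test_four_state_plan_splits_evenly(mixed_cmap, plan4):
    n = 1000
    optical = {k: np.full(n, 0.5 + 0.1 * i) for i, k in enumerate(plan4.emitters)}
    frames = digitise(mixed_cmap, plan4, n, eeg=np.zeros((4, n)), optical=optical)
    result = demux(frames, mixed_cmap, plan4)
    assert len(result.optical) == 4
    for series in result.optical.values():
        assert len(series) == 250                      # counting oracle: 1000 / 4
        assert series.effective_rate_hz == pytest.approx(250 / 4)
    assert result.blank_discards == 0


def test_all_blanking_plan_discards_everything(mixed_cmap):
    plan = IlluminationPlan([IlluminationState(0), IlluminationState(1)], fs_hz=250)
    frames = digitise(mixed_cmap, plan, 300, eeg=np.zeros((4, 300)))
    result = demux(frames, mixed_cmap, plan)
    assert result.optical == {}
    assert result.blank_discards == 300


def test_conservation_per_channel(mixed_cmap):
    plan = default_plan(1, 250, 50.0, blanking_frames=1)  # 750, blank, 850, blank
    n = 1001
    optical = {k: np.ones(n) for k in plan.emitters}
    frames = digitise(mixed_cmap, plan, n, eeg=np.zeros((4, n)), optical=optical)
    result = demux(frames, mixed_cmap, plan)
    for trace in result.eeg.values():
        assert trace.size == n                        # EEG passthrough at f_s
    n_optical = sum(len(s) for s in result.optical.values())
    assert n_optical + result.blank_discards == n     # optical partition


def test_ground_truth_recovered_per_series(mixed_cmap, plan4):
    # loopback against the emulator: each series must return exactly the
    # digitised intensity of its own state, in order
    rng = np.random.default_rng(6)
    n = 2000
    optical = {k: 0.8 + 0.05 * rng.standard_normal(n) for k in plan4.emitters}
    frames = digitise(mixed_cmap, plan4, n, eeg=np.zeros((4, n)), optical=optical)
    result = demux(frames, mixed_cmap, plan4)
    lsb = 4.5 / (1 << 23)  # optical channel gain 1
    for (det, src, wl), series in result.optical.items():
        truth = optical[(src, wl)][series.frame_indices]
        assert np.abs(series.values - truth).max() <= lsb


def test_assignment_uses_embedded_ids_not_frame_arithmetic(mixed_cmap, plan4):
    n = 40
    optical = {k: np.ones(n) for k in plan4.emitters}
    frames = digitise(mixed_cmap, plan4, n, eeg=np.zeros((4, n)), optical=optical)
    # drop a frame: a receiver relying on position would mis-assign the rest
    trimmed = FrameBlock(
        status=np.delete(frames.status, 5, axis=0),
        codes=np.delete(frames.codes, 5, axis=0),
    )
    result = demux(trimmed, mixed_cmap, plan4)
    lost_state = int(frames.state_ids[5])
    for (det, src, wl), series in result.optical.items():
        state = next(
            s for s in plan4.states
            if not s.is_blank and (s.source_index, s.wavelength) == (src, wl)
        )
        expected = 10 - (1 if state.state_id == lost_state else 0)
        assert len(series) == expected


def test_unknown_state_raises_integrity_error(mixed_cmap, plan4):
    n = 20
    optical = {k: np.ones(n) for k in plan4.emitters}
    frames = digitise(mixed_cmap, plan4, n, eeg=np.zeros((4, n)), optical=optical)
    frames.status[7, :] = StatusWord(state_id=9, source_index=0, wavelength=750).to_int()
    with pytest.raises(IntegrityError, match="frame 7"):
        demux(frames, mixed_cmap, plan4)


def test_rechunking_invariance(mixed_cmap, plan4):
    n = 500
    rng = np.random.default_rng(8)
    optical = {k: 1.0 + 0.1 * rng.standard_normal(n) for k in plan4.emitters}
    frames = digitise(mixed_cmap, plan4, n, eeg=rng.normal(0, 1e-5, (4, n)), optical=optical)
    # same frame sequence, arbitrary packet boundaries, then reassembled
    data = frames.to_bytes(mixed_cmap)
    cuts = np.sort(rng.choice(np.arange(1, n), 7, replace=False)) * mixed_cmap.frame_nbytes
    chunks = np.split(np.frombuffer(data, dtype=np.uint8), cuts)
    reassembled = FrameBlock.from_bytes(
        b"".join(c.tobytes() for c in chunks), mixed_cmap
    )
    a = demux(frames, mixed_cmap, plan4)
    b = demux(reassembled, mixed_cmap, plan4)
    for key in a.optical:
        np.testing.assert_array_equal(a.optical[key].values, b.optical[key].values)
    # and the object path (list of SampleFrame) agrees with the columnar path
    c = demux(frames.to_frames(mixed_cmap), mixed_cmap, plan4)
    for key in a.optical:
        np.testing.assert_array_equal(a.optical[key].values, c.optical[key].values)


def test_timeline_is_exact_integer_frames(mixed_cmap, plan4):
    n = 4000
    optical = {k: np.ones(n) for k in plan4.emitters}
    frames = digitise(mixed_cmap, plan4, n, eeg=np.zeros((4, n)), optical=optical)
    result = demux(frames, mixed_cmap, plan4)
    for series in result.optical.values():
        # no accumulated drift: integer frame grid with exact N_state spacing
        assert series.frame_indices.dtype.kind in "iu"
        assert np.unique(np.diff(series.frame_indices)).tolist() == [plan4.n_state]
        np.testing.assert_allclose(
            series.times, series.frame_indices / plan4.fs_hz, rtol=0, atol=0
        )


def test_ambient_subtraction_uses_blank_frames(mixed_cmap):
    plan = default_plan(1, 250, 50.0, blanking_frames=1)
    n = 800
    ambient = 0.2
    optical = {k: np.full(n, 0.9) + ambient for k in plan.emitters}
    frames = digitise(
        mixed_cmap, plan, n, eeg=np.zeros((4, n)), optical=optical, dark_v=ambient
    )
    result = demux(frames, mixed_cmap, plan, ambient_subtract=True)
    for series in result.optical.values():
        np.testing.assert_allclose(series.values, 0.9, atol=1e-6)


# ---------------------------------------------------------------------------
# decimation

def _series(values, eff_rate):
    return OpticalSeries(
        source=0, wavelength=750, detector="D1", values=np.asarray(values, float),
        fs_hz=250.0, effective_rate_hz=eff_rate,
        frame_indices=np.arange(len(values)) * int(250 / eff_rate),
    )


def test_decimate_preserves_dc():
    out = decimate(_series(np.full(500, 0.73), 25.0), 5.0)
    assert out.effective_rate_hz == pytest.approx(5.0)
    np.testing.assert_allclose(out.values, 0.73, rtol=1e-6)


def test_decimate_retains_in_band_amplitude():
    t = np.arange(2500) / 25.0
    x = np.sin(2 * np.pi * 1.0 * t)
    out = decimate(_series(x, 25.0), 10.0)
    mid = out.values[50:250]  # 20 whole cycles, away from filter edges
    amplitude = np.sqrt(2) * np.sqrt(np.mean(mid**2))
    assert abs(amplitude - 1.0) < 0.01  # 1 Hz amplitude within 1%


def test_decimate_identity_at_effective_rate():
    rng = np.random.default_rng(9)
    x = rng.normal(0, 1, 400).cumsum() / 50  # slow random walk, mostly in band
    out = decimate(_series(x, 25.0), 25.0)
    assert out.values.size == x.size


def test_decimate_above_effective_rate_is_domain_error():
    with pytest.raises(ValueError, match="exceeds"):
        decimate(_series(np.ones(100), 25.0), 26.0)
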