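"""Frame codec: bit-exact round trips, length law, saturation, log files."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from biomux.frame_codec import (
    CODE_MAX,
    CODE_MIN,
    ChannelConfig,
    ChannelMap,
    ChannelSample,
    FrameBlock,
    FrameBoundaryError,
    RangeError,
    EncodingError,
    SampleFrame,
    StatusWord,
    StructuralError,
    code_to_volts,
    decode_frame,
    decode_sample,
    decode_status,
    encode_frame,
    encode_sample,
    encode_status,
    export_csv,
    is_saturated,
    read_frame_log,
    write_frame_log,
)
from biomux.tdm_scheduler import default_plan


# ---------------------------------------------------------------------------
# samples

@pytest.mark.parametrize(
    "code,expected",
    [
        (0, b"\x00\x00\x00"),
        (8388607, b"\x7f\xff\xff"),   # positive full scale
        (-1, b"\xff\xff\xff"),        # two's complement identity
        (-8388608, b"\x80\x00\x00"),  # negative full scale
        (1, b"\x00\x00\x01"),
    ],
)
def test_sample_encoding_examples(code, expected):
    assert encode_sample(code) == expected
    assert decode_sample(expected) == code


@pytest.mark.parametrize("code", [CODE_MAX + 1, CODE_MIN - 1, 1 << 24])
def test_out_of_range_sample_rejected(code):
    with pytest.raises(RangeError):
        encode_sample(code)


@given(st.integers(min_value=CODE_MIN, max_value=CODE_MAX))
def test_sample_round_trip(code):
    assert decode_sample(encode_sample(code)) == code


# ---------------------------------------------------------------------------
# status words

def test_zero_status_is_zero_code():
    assert encode_status(StatusWord()) == b"\x00\x00\x00"


def test_every_plan_state_status_round_trips():
    plan = default_plan(3, 250, 30.0, blanking_frames=1)
    assert plan.n_state >= 10
    for s in plan.states:
        sw = StatusWord(
            state_id=s.state_id,
            source_index=s.source_index,
            wavelength=s.wavelength,
            blanking=s.is_blank,
        )
        assert decode_status(encode_status(sw)) == sw


def test_blanking_status_has_none_wavelength_code():
    sw = StatusWord(state_id=3, blanking=True)
    # wavelength bit-field is the reserved "none" code 00
    assert (sw.to_int() >> 8) & 0x3 == 0
    with pytest.raises(EncodingError):
        StatusWord(state_id=0, wavelength=750, blanking=True)


@pytest.mark.parametrize(
    "kwargs",
    [{"state_id": 256}, {"source_index": 64}, {"reserved": 128}],
)
def test_status_field_overflow(kwargs):
    with pytest.raises(EncodingError):
        StatusWord(**kwargs).to_int()


@given(
    st.integers(0, 255),
    st.integers(0, 63),
    st.sampled_from([None, 750, 850]),
    st.booleans(),
)
def test_status_round_trip(state_id, source, wl, blank):
    if blank:
        wl = None
    sw = StatusWord(state_id=state_id, source_index=source, wavelength=wl, blanking=blank)
    assert StatusWord.from_int(sw.to_int()) == sw


# ---------------------------------------------------------------------------
# frames

def _random_frame(rng, cmap, frame_index=0, state_id=1):
    records = []
    for d in range(cmap.n_devices):
        sw = StatusWord(state_id=state_id, source_index=2, wavelength=750)
        samples = [
            ChannelSample(int(rng.integers(CODE_MIN, CODE_MAX + 1)), gain=c.gain, vref=c.vref)
            for c in cmap.enabled(d)
        ]
        records.append((sw, samples))
    return SampleFrame(frame_index=frame_index, records=records)


@pytest.mark.parametrize("n_devices", [1, 2, 3, 4])
@pytest.mark.parametrize("n_channels", [1, 2, 4, 8])
def test_frame_length_law(n_devices, n_channels):
    cmap = ChannelMap.uniform(n_devices, n_channels)
    rng = np.random.default_rng(7)
    frame = _random_frame(rng, cmap)
    block = encode_frame(frame, cmap)
    assert len(block) == n_devices * (3 + 3 * n_channels) == cmap.frame_nbytes
    decoded = decode_frame(block, cmap)
    assert [s.raw_code for s in decoded.samples] == [s.raw_code for s in frame.samples]


def test_32_channel_frame_is_108_bytes(cmap32):
    assert cmap32.frame_nbytes == 4 * (3 + 24) == 108


def test_single_channel_frame_is_6_bytes():
    assert ChannelMap.uniform(1, 1).frame_nbytes == 6


def test_truncated_block_is_boundary_error(cmap32):
    rng = np.random.default_rng(0)
    block = encode_frame(_random_frame(rng, cmap32), cmap32)
    with pytest.raises(FrameBoundaryError):
        decode_frame(block[:-1], cmap32)


def test_frame_map_mismatch_is_structural_error(cmap32):
    rng = np.random.default_rng(0)
    frame = _random_frame(rng, ChannelMap.uniform(2, 8))
    with pytest.raises(StructuralError):
        encode_frame(frame, cmap32)


def test_devices_must_share_state_id():
    cmap = ChannelMap.uniform(2, 1)
    records = [
        (StatusWord(state_id=0), [ChannelSample(1)]),
        (StatusWord(state_id=1), [ChannelSample(2)]),
    ]
    with pytest.raises(StructuralError):
        encode_frame(SampleFrame(0, records), cmap)


@given(st.data())
def test_frame_round_trip_property(data):
    n_dev = data.draw(st.integers(1, 4))
    n_ch = data.draw(st.integers(1, 8))
    cmap = ChannelMap.uniform(n_dev, n_ch)
    codes = data.draw(
        st.lists(st.integers(CODE_MIN, CODE_MAX), min_size=n_dev * n_ch, max_size=n_dev * n_ch)
    )
    sid = data.draw(st.integers(0, 255))
    records = []
    it = iter(codes)
    for d in range(n_dev):
        sw = StatusWord(state_id=sid)
        records.append((sw, [ChannelSample(next(it)) for _ in range(n_ch)]))
    frame = SampleFrame(0, records)
    decoded = decode_frame(encode_frame(frame, cmap), cmap)
    assert [s.raw_code for s in decoded.samples] == codes
    assert all(sw.state_id == sid for sw, _ in decoded.records)


# ---------------------------------------------------------------------------
# scaling and saturation

def test_volts_conversion_at_rails():
    vref, gain = 4.5, 24
    fs = vref / gain
    assert ChannelSample(CODE_MAX, gain, vref).value_volts == pytest.approx(
        fs * (1 - 2.0**-23), rel=1e-12
    )
    assert ChannelSample(CODE_MIN, gain, vref).value_volts == pytest.approx(-fs, rel=1e-12)
    assert code_to_volts(0) == 0.0


def test_saturation_threshold_boundaries():
    margin = 256
    assert is_saturated((1 << 23) - margin, margin)
    assert not is_saturated((1 << 23) - margin - 1, margin)
    assert is_saturated(-(1 << 23), margin)
    assert ChannelSample(CODE_MAX).saturated()
    assert not ChannelSample(0).saturated()


# ---------------------------------------------------------------------------
# frame block and logs

def _random_block(rng, cmap, n):
    status = np.array(
        [[StatusWord(state_id=int(i % 7)).to_int()] * cmap.n_devices for i in range(n)],
        dtype=np.uint32,
    )
    codes = rng.integers(CODE_MIN, CODE_MAX + 1, size=(n, cmap.n_enabled), dtype=np.int64)
    return FrameBlock(status=status, codes=codes.astype(np.int32))


def test_block_bytes_round_trip(cmap32):
    block = _random_block(np.random.default_rng(3), cmap32, 200)
    assert FrameBlock.from_bytes(block.to_bytes(cmap32), cmap32) == block


def test_block_frame_interop_and_indices(cmap32):
    block = _random_block(np.random.default_rng(5), cmap32, 1000)
    frames = block.to_frames(cmap32)
    assert len(frames) == 1000
    idx = [f.frame_index for f in frames]
    assert idx == sorted(idx) and len(set(idx)) == 1000  # strictly increasing
    assert FrameBlock.from_frames(frames, cmap32) == block


def test_log_write_read_identity(tmp_path, mixed_cmap):
    plan = default_plan(1, 250, 50.0)
    block = _random_block(np.random.default_rng(11), mixed_cmap, 123)
    path = tmp_path / "session.frames"
    write_frame_log(path, block, mixed_cmap, plan=plan, extra={"seed": 42})
    back, cmap2, plan2, sidecar = read_frame_log(path)
    assert back == block
    assert cmap2 == mixed_cmap
    assert plan2 == plan
    assert sidecar["seed"] == 42


def test_empty_log_is_valid(tmp_path, mixed_cmap):
    block = FrameBlock(
        status=np.zeros((0, mixed_cmap.n_devices), dtype=np.uint32),
        codes=np.zeros((0, mixed_cmap.n_enabled), dtype=np.int32),
    )
    path = tmp_path / "empty.frames"
    write_frame_log(path, block, mixed_cmap)
    back, _, _, _ = read_frame_log(path)
    assert back.n_frames == 0


def test_truncated_log_recovers_whole_frames(tmp_path, mixed_cmap):
    block = _random_block(np.random.default_rng(2), mixed_cmap, 50)
    path = tmp_path / "cut.frames"
    write_frame_log(path, block, mixed_cmap)
    with open(path, "ab") as fh:
        fh.write(b"\x01\x02\x03\x04")  # interrupted write: half a frame
    with pytest.warns(UserWarning, match="truncated"):
        back, _, _, _ = read_frame_log(path)
    assert back == block


def test_csv_export(tmp_path, mixed_cmap):
    import pandas as pd

    block = _random_block(np.random.default_rng(4), mixed_cmap, 10)
    path = tmp_path / "out.csv"
    export_csv(path, block, mixed_cmap)
    df = pd.read_csv(path)
    assert list(df.columns) == ["frame_index", "state_id"] + mixed_cmap.labels
    assert len(df) == 10
    np.testing.assert_allclose(
        df[mixed_cmap.labels].to_numpy(), block.volts(mixed_cmap), atol=1e-12
    )
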