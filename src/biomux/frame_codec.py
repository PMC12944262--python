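"""Bit-exact conversion-frame codec for a multi-device ADS1299 ensemble.

Each conversion frame is, per device, a 24-bit status word followed by one
24-bit two's-complement sample per enabled channel, MSB first.  The acquisition
firmware overwrites the status word of every device with an identifier of the
currently active illumination state (source index, wavelength, blanking flag),
which is what makes receiver-side optical demultiplexing unambiguous.

Status-word dialect (24 bits, MSB first)::

    [23:16] state_id        index into the illumination plan (0..255)
    [15:10] source_index    emitter package index (0..63)
    [ 9: 8] wavelength      00 = none/blank, 01 = 750 nm, 10 = 850 nm
    [    7] blanking        all emitters off this frame
    [ 6: 0] reserved        zero

The layout covers 64 emitters (the driver-bank maximum) with headroom and is a
convention of this implementation; the on-wire byte order is big-endian,
matching the ADC's own output ordering.
"""

from __future__ import annotations

import io
import json
import os
import warnings
from dataclasses import dataclass, field, asdict
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "FULL_SCALE",
    "CODE_MIN",
    "CODE_MAX",
    "DEFAULT_SATURATION_MARGIN",
    "DEFAULT_VREF",
    "DEFAULT_GAIN",
    "CodecError",
    "RangeError",
    "EncodingError",
    "FrameBoundaryError",
    "StructuralError",
    "StatusWord",
    "ChannelConfig",
    "ChannelMap",
    "ChannelSample",
    "SampleFrame",
    "FrameBlock",
    "encode_sample",
    "decode_sample",
    "encode_status",
    "decode_status",
    "encode_frame",
    "decode_frame",
    "is_saturated",
    "code_to_volts",
    "volts_to_code",
    "write_frame_log",
    "read_frame_log",
    "export_csv",
]

FULL_SCALE = 1 << 23          # 8388608; codes span [-FULL_SCALE, FULL_SCALE - 1]
CODE_MIN = -FULL_SCALE
CODE_MAX = FULL_SCALE - 1

#: Codes within this margin of full scale are flagged saturated
#: (the converter reaching "near full-scale codes" 0x7FFFFF / 0x800000).
DEFAULT_SATURATION_MARGIN = 256

DEFAULT_VREF = 4.5   # V, internal reference
DEFAULT_GAIN = 24    # PGA gain (1-24)

_WL_TO_CODE = {None: 0, 750: 1, 850: 2}
_CODE_TO_WL = {0: None, 1: 750, 2: 850}


class CodecError(ValueError):
    """Base class for codec failures."""


class RangeError(CodecError):
    """Sample code outside the representable 24-bit range."""


class EncodingError(CodecError):
    """Status-word field does not fit its allotted bits."""


class FrameBoundaryError(CodecError):
    """Byte block is not a whole number of frames (caller may resynchronise)."""


class StructuralError(CodecError):
    """Frame content inconsistent with the channel map."""


# ---------------------------------------------------------------------------
# samples

def encode_sample(raw_code: int) -> bytes:
    """Encode one 24-bit two's-complement sample as 3 bytes, MSB first."""
    if not (CODE_MIN <= raw_code <= CODE_MAX):
        raise RangeError(f"sample code {raw_code} outside [{CODE_MIN}, {CODE_MAX}]")
    return (raw_code & 0xFFFFFF).to_bytes(3, "big")


def decode_sample(data: bytes) -> int:
    """Decode 3 big-endian bytes into a signed 24-bit sample code."""
    if len(data) != 3:
        raise FrameBoundaryError(f"expected 3 bytes, got {len(data)}")
    v = int.from_bytes(data, "big")
    return v - (1 << 24) if v & 0x800000 else v


def code_to_volts(raw_code, vref: float = DEFAULT_VREF, gain: float = DEFAULT_GAIN):
    """Input-referred voltage of a code: ``code * (Vref/gain) / 2^23``."""
    return np.asarray(raw_code, dtype=float) * (vref / gain) / FULL_SCALE


def volts_to_code(volts, vref: float = DEFAULT_VREF, gain: float = DEFAULT_GAIN):
    """Quantise an input-referred voltage; clips at the code rails.

    Full scale corresponds approximately to an input of +/-(Vref/gain).
    """
    lsb = (vref / gain) / FULL_SCALE
    codes = np.rint(np.asarray(volts, dtype=float) / lsb)
    return np.clip(codes, CODE_MIN, CODE_MAX).astype(np.int32)


def is_saturated(raw_code, margin: int = DEFAULT_SATURATION_MARGIN):
    """True iff ``|code|`` is within ``margin`` of full scale."""
    return np.abs(np.asarray(raw_code, dtype=np.int64)) >= FULL_SCALE - margin


# ---------------------------------------------------------------------------
# status words

@dataclass(frozen=True)
class StatusWord:
    """Illumination-state identifier embedded in the 24-bit status word."""

    state_id: int = 0
    source_index: int = 0
    wavelength: int | None = None   # 750, 850 or None
    blanking: bool = False
    reserved: int = 0

    def __post_init__(self) -> None:
        if self.wavelength not in _WL_TO_CODE:
            raise EncodingError(f"wavelength must be 750, 850 or None, got {self.wavelength}")
        if self.blanking and self.wavelength is not None:
            raise EncodingError("blanking status must carry wavelength=None")

    def to_int(self) -> int:
        if not 0 <= self.state_id < 256:
            raise EncodingError(f"state_id {self.state_id} does not fit 8 bits")
        if not 0 <= self.source_index < 64:
            raise EncodingError(f"source_index {self.source_index} does not fit 6 bits")
        if not 0 <= self.reserved < 128:
            raise EncodingError(f"reserved {self.reserved} does not fit 7 bits")
        return (
            (self.state_id << 16)
            | (self.source_index << 10)
            | (_WL_TO_CODE[self.wavelength] << 8)
            | (int(self.blanking) << 7)
            | self.reserved
        )

    @classmethod
    def from_int(cls, word: int) -> "StatusWord":
        wl_code = (word >> 8) & 0x3
        if wl_code not in _CODE_TO_WL:
            raise EncodingError(f"invalid wavelength code {wl_code}")
        return cls(
            state_id=(word >> 16) & 0xFF,
            source_index=(word >> 10) & 0x3F,
            wavelength=_CODE_TO_WL[wl_code],
            blanking=bool((word >> 7) & 0x1),
            reserved=word & 0x7F,
        )


def encode_status(word: StatusWord) -> bytes:
    """Encode a status word as 3 bytes, MSB first."""
    return word.to_int().to_bytes(3, "big")


def decode_status(data: bytes) -> StatusWord:
    if len(data) != 3:
        raise FrameBoundaryError(f"expected 3 bytes, got {len(data)}")
    return StatusWord.from_int(int.from_bytes(data, "big"))


# ---------------------------------------------------------------------------
# channel map

_ROLES = ("eeg", "optical", "aux", "off")


@dataclass
class ChannelConfig:
    """Role and analogue settings of one universal input channel."""

    label: str
    role: str = "eeg"
    gain: float = DEFAULT_GAIN
    vref: float = DEFAULT_VREF
    posterior: bool = False   # meaningful for EEG channels (alpha analyses)

    def __post_init__(self) -> None:
        if self.role not in _ROLES:
            raise StructuralError(f"unknown channel role {self.role!r}")
        if not 1 <= self.gain <= 24:
            raise StructuralError(f"PGA gain {self.gain} outside 1-24")


class ChannelMap:
    """Assignment of the 32 universal inputs to EEG/optical/auxiliary roles.

    Channels are organised as 1-4 eight-channel devices; disabled channels
    (role ``'off'``) occupy no bytes in a frame.  Channel order is
    device-major and fixed, which is what makes the byte layout unambiguous.
    """

    def __init__(self, devices: Sequence[Sequence[ChannelConfig]]):
        devices = [list(d) for d in devices]
        if not 1 <= len(devices) <= 4:
            raise StructuralError(f"device count must be 1-4, got {len(devices)}")
        for d in devices:
            if not 1 <= len(d) <= 8:
                raise StructuralError("each device carries 1-8 channels")
        self.devices = devices
        if self.n_enabled > 32:
            raise StructuralError("more than 32 enabled channels")

    # -- construction helpers -------------------------------------------------
    @classmethod
    def uniform(
        cls,
        n_devices: int = 4,
        n_channels: int = 8,
        role: str = "eeg",
        gain: float = DEFAULT_GAIN,
        vref: float = DEFAULT_VREF,
        prefix: str = "CH",
    ) -> "ChannelMap":
        devices = [
            [
                ChannelConfig(f"{prefix}{d * n_channels + c + 1}", role=role, gain=gain, vref=vref)
                for c in range(n_channels)
            ]
            for d in range(n_devices)
        ]
        return cls(devices)

    @classmethod
    def from_channels(cls, channels: Sequence[ChannelConfig]) -> "ChannelMap":
        """Pack a flat channel list into eight-channel devices."""
        chans = list(channels)
        if not chans:
            raise StructuralError("empty channel list")
        devices = [chans[i : i + 8] for i in range(0, len(chans), 8)]
        return cls(devices)

    # -- structure -------------------------------------------------------------
    @property
    def n_devices(self) -> int:
        return len(self.devices)

    def enabled(self, device: int) -> list[ChannelConfig]:
        return [c for c in self.devices[device] if c.role != "off"]

    @property
    def channels(self) -> list[ChannelConfig]:
        """Enabled channels in device-major frame order."""
        return [c for d in range(self.n_devices) for c in self.enabled(d)]

    @property
    def n_enabled(self) -> int:
        return len(self.channels)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def by_role(self, role: str) -> list[int]:
        """Indices (into frame channel order) of channels with the given role."""
        return [i for i, c in enumerate(self.channels) if c.role == role]

    @property
    def frame_nbytes(self) -> int:
        """Encoded frame size: sum over devices of 3 + 3 * enabled channels."""
        return sum(3 + 3 * len(self.enabled(d)) for d in range(self.n_devices))

    @property
    def gains(self) -> np.ndarray:
        return np.array([c.gain for c in self.channels], dtype=float)

    @property
    def vrefs(self) -> np.ndarray:
        return np.array([c.vref for c in self.channels], dtype=float)

    # -- serialisation ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {"devices": [[asdict(c) for c in dev] for dev in self.devices]}

    @classmethod
    def from_dict(cls, d: dict) -> "ChannelMap":
        return cls([[ChannelConfig(**c) for c in dev] for dev in d["devices"]])

    def __eq__(self, other) -> bool:
        return isinstance(other, ChannelMap) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return f"ChannelMap({self.n_devices} devices, {self.n_enabled} channels)"


# ---------------------------------------------------------------------------
# frames

@dataclass(frozen=True)
class ChannelSample:
    """One 24-bit conversion result with its analogue scaling."""

    raw_code: int
    gain: float = DEFAULT_GAIN
    vref: float = DEFAULT_VREF

    def __post_init__(self) -> None:
        if not (CODE_MIN <= self.raw_code <= CODE_MAX):
            raise RangeError(f"sample code {self.raw_code} outside 24-bit range")

    @property
    def value_volts(self) -> float:
        return float(self.raw_code * (self.vref / self.gain) / FULL_SCALE)

    def saturated(self, margin: int = DEFAULT_SATURATION_MARGIN) -> bool:
        return bool(is_saturated(self.raw_code, margin))


@dataclass
class SampleFrame:
    """One conversion instant: per-device (status word, samples) records.

    ``frame_index`` is a host-side counter (implicit in logs by position);
    all device records in one frame carry the same state_id because every
    device converts on the same shared-clock instant.
    """

    frame_index: int
    records: list[tuple[StatusWord, list[ChannelSample]]]

    @property
    def state_id(self) -> int:
        return self.records[0][0].state_id

    @property
    def samples(self) -> list[ChannelSample]:
        return [s for _, samples in self.records for s in samples]

    def validate(self, cmap: ChannelMap) -> None:
        if len(self.records) != cmap.n_devices:
            raise StructuralError(
                f"frame has {len(self.records)} device records, map expects {cmap.n_devices}"
            )
        state_ids = {sw.state_id for sw, _ in self.records}
        if len(state_ids) != 1:
            raise StructuralError(f"device records disagree on state_id: {sorted(state_ids)}")
        for d, (_, samples) in enumerate(self.records):
            want = len(cmap.enabled(d))
            if len(samples) != want:
                raise StructuralError(
                    f"device {d}: {len(samples)} samples, map enables {want} channels"
                )


def encode_frame(frame: SampleFrame, cmap: ChannelMap) -> bytes:
    """Encode one frame: per device, status word then enabled-channel samples."""
    frame.validate(cmap)
    out = bytearray()
    for status, samples in frame.records:
        out += encode_status(status)
        for s in samples:
            out += encode_sample(s.raw_code)
    return bytes(out)


def decode_frame(block: bytes, cmap: ChannelMap, frame_index: int = 0) -> SampleFrame:
    """Decode one encoded frame; the block length must match the map exactly."""
    if len(block) != cmap.frame_nbytes:
        raise FrameBoundaryError(
            f"block is {len(block)} bytes, map requires {cmap.frame_nbytes}"
        )
    records = []
    pos = 0
    for d in range(cmap.n_devices):
        status = decode_status(block[pos : pos + 3])
        pos += 3
        samples = []
        for ch in cmap.enabled(d):
            samples.append(
                ChannelSample(decode_sample(block[pos : pos + 3]), gain=ch.gain, vref=ch.vref)
            )
            pos += 3
        records.append((status, samples))
    return SampleFrame(frame_index=frame_index, records=records)


# ---------------------------------------------------------------------------
# columnar frame block (vectorised path for long logs)

def _bytes3_from_uint(words: np.ndarray) -> np.ndarray:
    """uint32 array [n] -> uint8 array [n, 3], big-endian 24-bit."""
    w = words.astype(np.uint32)
    return np.stack([(w >> 16) & 0xFF, (w >> 8) & 0xFF, w & 0xFF], axis=-1).astype(np.uint8)


def _uint_from_bytes3(b: np.ndarray) -> np.ndarray:
    """uint8 array [..., 3] -> uint32 array [...]."""
    b = b.astype(np.uint32)
    return (b[..., 0] << 16) | (b[..., 1] << 8) | b[..., 2]


@dataclass
class FrameBlock:
    """Columnar frame sequence: the fast in-memory form of a frame log.

    ``status`` holds the raw 24-bit status word per (frame, device) and
    ``codes`` the signed sample codes per (frame, enabled channel) in
    device-major channel order.  Converts losslessly to/from both the byte
    stream and a list of :class:`SampleFrame`.
    """

    status: np.ndarray          # uint32, shape (n_frames, n_devices)
    codes: np.ndarray           # int32, shape (n_frames, n_channels)
    first_frame_index: int = 0

    def __post_init__(self) -> None:
        self.status = np.atleast_2d(np.asarray(self.status, dtype=np.uint32))
        self.codes = np.atleast_2d(np.asarray(self.codes, dtype=np.int32))
        if self.status.shape[0] != self.codes.shape[0]:
            raise StructuralError("status and codes disagree on frame count")

    @property
    def n_frames(self) -> int:
        return self.status.shape[0]

    @property
    def frame_indices(self) -> np.ndarray:
        return self.first_frame_index + np.arange(self.n_frames)

    # decoded status fields (all devices share the state; device 0 is canonical)
    @property
    def state_ids(self) -> np.ndarray:
        return ((self.status[:, 0] >> 16) & 0xFF).astype(np.int64)

    @property
    def source_indices(self) -> np.ndarray:
        return ((self.status[:, 0] >> 10) & 0x3F).astype(np.int64)

    @property
    def wavelength_codes(self) -> np.ndarray:
        return ((self.status[:, 0] >> 8) & 0x3).astype(np.int64)

    @property
    def blanking(self) -> np.ndarray:
        return ((self.status[:, 0] >> 7) & 0x1).astype(bool)

    def volts(self, cmap: ChannelMap) -> np.ndarray:
        """Input-referred volts, shape (n_frames, n_channels)."""
        lsb = (cmap.vrefs / cmap.gains) / FULL_SCALE
        return self.codes.astype(float) * lsb[np.newaxis, :]

    # -- byte stream -----------------------------------------------------------
    def to_bytes(self, cmap: ChannelMap) -> bytes:
        n = self.n_frames
        if self.status.shape[1] != cmap.n_devices:
            raise StructuralError("device count mismatch with channel map")
        if self.codes.shape[1] != cmap.n_enabled:
            raise StructuralError("channel count mismatch with channel map")
        if np.any(self.codes > CODE_MAX) or np.any(self.codes < CODE_MIN):
            raise RangeError("sample codes outside 24-bit range")
        out = np.empty((n, cmap.frame_nbytes), dtype=np.uint8)
        pos = 0
        ch0 = 0
        for d in range(cmap.n_devices):
            out[:, pos : pos + 3] = _bytes3_from_uint(self.status[:, d])
            pos += 3
            nch = len(cmap.enabled(d))
            dev_codes = self.codes[:, ch0 : ch0 + nch].astype(np.int64) & 0xFFFFFF
            out[:, pos : pos + 3 * nch] = _bytes3_from_uint(
                dev_codes.astype(np.uint32)
            ).reshape(n, 3 * nch)
            pos += 3 * nch
            ch0 += nch
        return out.tobytes()

    @classmethod
    def from_bytes(
        cls, data: bytes, cmap: ChannelMap, first_frame_index: int = 0, strict: bool = True
    ) -> "FrameBlock":
        """Decode a concatenated frame stream.

        With ``strict`` a trailing partial frame raises
        :class:`FrameBoundaryError`; otherwise whole frames are recovered and a
        truncation warning is issued.
        """
        nbytes = cmap.frame_nbytes
        n, rem = divmod(len(data), nbytes)
        if rem:
            if strict:
                raise FrameBoundaryError(
                    f"{len(data)} bytes is not a whole number of {nbytes}-byte frames"
                )
            warnings.warn(
                f"frame log truncated: dropping {rem} trailing bytes", stacklevel=2
            )
            data = data[: n * nbytes]
        raw = np.frombuffer(data, dtype=np.uint8).reshape(n, nbytes)
        status = np.empty((n, cmap.n_devices), dtype=np.uint32)
        codes = np.empty((n, cmap.n_enabled), dtype=np.int32)
        pos = 0
        ch0 = 0
        for d in range(cmap.n_devices):
            status[:, d] = _uint_from_bytes3(raw[:, pos : pos + 3])
            pos += 3
            nch = len(cmap.enabled(d))
            u = _uint_from_bytes3(raw[:, pos : pos + 3 * nch].reshape(n, nch, 3))
            codes[:, ch0 : ch0 + nch] = (
                u.astype(np.int64) - ((u.astype(np.int64) & 0x800000) << 1)
            ).astype(np.int32)
            pos += 3 * nch
            ch0 += nch
        return cls(status=status, codes=codes, first_frame_index=first_frame_index)

    # -- SampleFrame interop ---------------------------------------------------
    def to_frames(self, cmap: ChannelMap) -> list[SampleFrame]:
        frames = []
        for i in range(self.n_frames):
            records = []
            ch0 = 0
            for d in range(cmap.n_devices):
                sw = StatusWord.from_int(int(self.status[i, d]))
                samples = [
                    ChannelSample(int(self.codes[i, ch0 + k]), gain=ch.gain, vref=ch.vref)
                    for k, ch in enumerate(cmap.enabled(d))
                ]
                records.append((sw, samples))
                ch0 += len(cmap.enabled(d))
            frames.append(SampleFrame(frame_index=self.first_frame_index + i, records=records))
        return frames

    @classmethod
    def from_frames(cls, frames: Sequence[SampleFrame], cmap: ChannelMap) -> "FrameBlock":
        if not frames:
            return cls(
                status=np.zeros((0, cmap.n_devices), dtype=np.uint32),
                codes=np.zeros((0, cmap.n_enabled), dtype=np.int32),
            )
        status = np.empty((len(frames), cmap.n_devices), dtype=np.uint32)
        codes = np.empty((len(frames), cmap.n_enabled), dtype=np.int32)
        for i, f in enumerate(frames):
            f.validate(cmap)
            status[i] = [sw.to_int() for sw, _ in f.records]
            codes[i] = [s.raw_code for s in f.samples]
        return cls(status=status, codes=codes, first_frame_index=frames[0].frame_index)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, FrameBlock)
            and np.array_equal(self.status, other.status)
            and np.array_equal(self.codes, other.codes)
        )


# ---------------------------------------------------------------------------
# frame-log files (raw byte stream + JSON sidecar)

def _sidecar_path(path: str | os.PathLike) -> str:
    return str(path) + ".json"


def write_frame_log(
    path: str | os.PathLike,
    block: FrameBlock,
    cmap: ChannelMap,
    plan=None,
    extra: dict | None = None,
) -> None:
    """Write the concatenated frame bytes plus a ``<path>.json`` sidecar.

    The sidecar round-trips everything needed to decode the log: device count,
    channel map (with gains/Vref), illumination plan and sampling rate, and any
    extra metadata (e.g. the emulator seed).
    """
    data = block.to_bytes(cmap)
    sidecar = {
        "format": "biomux-frame-log",
        "version": 1,
        "n_devices": cmap.n_devices,
        "n_frames": block.n_frames,
        "frame_nbytes": cmap.frame_nbytes,
        "channel_map": cmap.to_dict(),
        "plan": plan.to_dict() if plan is not None else None,
        "fs_hz": plan.fs_hz if plan is not None else None,
    }
    if extra:
        sidecar.update(extra)
    with open(path, "wb") as fh:
        fh.write(data)
    with open(_sidecar_path(path), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def read_frame_log(path: str | os.PathLike):
    """Read a frame log; returns ``(FrameBlock, ChannelMap, plan, sidecar)``.

    A trailing partial frame (interrupted write) is dropped with a warning;
    whole frames are always recovered.
    """
    from . import tdm_scheduler  # local import: avoid a cycle at module load

    with open(_sidecar_path(path)) as fh:
        sidecar = json.load(fh)
    cmap = ChannelMap.from_dict(sidecar["channel_map"])
    plan = (
        tdm_scheduler.IlluminationPlan.from_dict(sidecar["plan"])
        if sidecar.get("plan")
        else None
    )
    with open(path, "rb") as fh:
        data = fh.read()
    block = FrameBlock.from_bytes(data, cmap, strict=False)
    return block, cmap, plan, sidecar


def export_csv(path: str | os.PathLike, block: FrameBlock, cmap: ChannelMap) -> None:
    """One row per frame: frame_index, state_id, then per-channel volts."""
    import pandas as pd

    df = pd.DataFrame(block.volts(cmap), columns=cmap.labels)
    df.insert(0, "state_id", block.state_ids)
    df.insert(0, "frame_index", block.frame_indices)
    df.to_csv(path, index=False)
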