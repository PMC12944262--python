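"""ASCII control protocol, TCP packet streaming and receiver-side publication.

The emulator server mirrors the instrument's communication coprocessor: a
line-oriented ASCII control channel (``VERB key=value ...\\n`` with ``OK``/
``ERR <reason>`` replies) and a separate data channel carrying packets of
whole encoded frames, each prefixed by a 4-byte little-endian payload length
(a zero-length packet terminates the stream).  The protocol state machine is
idle -> configured -> streaming -> idle; SETUP is only accepted while not
streaming, and parameters are immutable during a session.

Acquisition content is never shaped by the transport: the frame generator is
driven by its own configuration and frame counter, and a stalled client only
ever causes a flow-control halt (bounded send buffer), never altered data.
Receiver-side publication goes through a sink interface so everything runs
without a network-streaming stack; an LSL-backed sink is provided for
installations that have ``pylsl``.
"""

from __future__ import annotations

import json
import queue
import socket
import threading
from dataclasses import dataclass, field

import numpy as np

from .frame_codec import ChannelMap, FrameBlock, write_frame_log
from .signal_emulator import EmulatedSession, PhysioScenario, run_scenario
from .tdm_scheduler import IlluminationPlan

__all__ = [
    "ProtocolError",
    "ControlCommand",
    "parse_command",
    "SessionRecord",
    "EmulatorServer",
    "ReceivedSession",
    "receive_stream",
    "record_log",
    "FrameSink",
    "ListSink",
    "LogWriterSink",
    "LslSink",
    "DEFAULT_FRAMES_PER_PACKET",
    "DEFAULT_MAX_BUFFER_PACKETS",
]

DEFAULT_FRAMES_PER_PACKET = 25
DEFAULT_MAX_BUFFER_PACKETS = 256
_VERBS = ("SETUP", "START", "STOP", "STATUS")


class ProtocolError(Exception):
    """Illegal command for the current protocol state."""


@dataclass(frozen=True)
class ControlCommand:
    verb: str
    arguments: dict


def parse_command(line: str) -> ControlCommand:
    """Parse ``VERB key=value ...`` (whitespace-separated)."""
    parts = line.strip().split()
    if not parts:
        raise ProtocolError("empty command")
    verb = parts[0].upper()
    if verb not in _VERBS:
        raise ProtocolError(f"unknown verb {parts[0]!r}")
    args = {}
    for tok in parts[1:]:
        if "=" not in tok:
            raise ProtocolError(f"malformed argument {tok!r} (expected key=value)")
        k, v = tok.split("=", 1)
        args[k] = v
    return ControlCommand(verb=verb, arguments=args)


@dataclass
class SessionRecord:
    """Outcome of one streaming session, kept by the server."""

    n_frames: int = 0
    packets_sent: int = 0
    frames_sent: int = 0
    overrun: bool = False
    completed: bool = False
    error: str | None = None


def _default_session_factory(args: dict) -> EmulatedSession:
    """Build an emulated session from SETUP key=value arguments."""
    kwargs: dict = {}
    casts = {
        "scenario": str,
        "duration": ("duration_s", float),
        "duration_s": ("duration_s", float),
        "fs": ("fs_hz", float),
        "fs_hz": ("fs_hz", float),
        "seed": ("seed", int),
    }
    for k, v in args.items():
        spec = casts.get(k)
        if spec is None:
            raise ProtocolError(f"unknown SETUP parameter {k!r}")
        if isinstance(spec, tuple):
            name, cast = spec
        else:
            name, cast = k, spec
        kwargs[name] = cast(v)
    return run_scenario(PhysioScenario(**kwargs))


class EmulatorServer:
    """TCP emulator: one control connection, one data connection.

    Either serves a fixed pre-built :class:`EmulatedSession` or builds one
    from SETUP arguments via ``session_factory``.  The streamed packets are
    produced from the session's frame counter alone; socket readiness only
    throttles (and, past the buffer bound, halts) transmission.
    """

    def __init__(
        self,
        session: EmulatedSession | None = None,
        session_factory=None,
        host: str = "127.0.0.1",
        frames_per_packet: int = DEFAULT_FRAMES_PER_PACKET,
        max_buffer_packets: int = DEFAULT_MAX_BUFFER_PACKETS,
        overrun_timeout_s: float = 2.0,
        data_sndbuf: int | None = None,
        accept_timeout_s: float = 10.0,
    ):
        self._fixed_session = session
        self._session_factory = session_factory or (
            (lambda args: session) if session is not None else _default_session_factory
        )
        self.host = host
        self.frames_per_packet = int(frames_per_packet)
        self.max_buffer_packets = int(max_buffer_packets)
        self.overrun_timeout_s = float(overrun_timeout_s)
        self.data_sndbuf = data_sndbuf
        self.accept_timeout_s = accept_timeout_s

        self.state = "idle"
        self.session: EmulatedSession | None = None
        self.record = SessionRecord()
        self._ctrl_sock: socket.socket | None = None
        self._data_sock: socket.socket | None = None
        self._threads: list[threading.Thread] = []
        self._abort = threading.Event()
        self._shutdown = threading.Event()
        self._lock = threading.Lock()

    # -- lifecycle -------------------------------------------------------------
    def start(self) -> None:
        self._ctrl_sock = socket.create_server((self.host, 0))
        self._data_sock = socket.create_server((self.host, 0))
        self._ctrl_sock.settimeout(0.2)
        self._data_sock.settimeout(self.accept_timeout_s)
        t = threading.Thread(target=self._control_loop, daemon=True)
        t.start()
        self._threads.append(t)

    @property
    def control_port(self) -> int:
        return self._ctrl_sock.getsockname()[1]

    @property
    def data_port(self) -> int:
        return self._data_sock.getsockname()[1]

    def close(self) -> None:
        self._shutdown.set()
        self._abort.set()
        for t in self._threads:
            t.join(timeout=5.0)
        for s in (self._ctrl_sock, self._data_sock):
            if s is not None:
                s.close()

    def __enter__(self) -> "EmulatorServer":
        self.start()
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- control channel -------------------------------------------------------
    def _control_loop(self) -> None:
        while not self._shutdown.is_set():
            try:
                conn, _ = self._ctrl_sock.accept()
            except socket.timeout:
                continue
            except OSError:
                return
            with conn:
                self._serve_control(conn)

    def _serve_control(self, conn: socket.socket) -> None:
        rfile = conn.makefile("r", encoding="ascii", newline="\n")
        while not self._shutdown.is_set():
            line = rfile.readline()
            if not line:
                return
            try:
                reply = self._handle(parse_command(line))
            except ProtocolError as exc:
                reply = f"ERR {exc}"
            try:
                conn.sendall((reply + "\n").encode("ascii"))
            except OSError:
                return

    def _handle(self, cmd: ControlCommand) -> str:
        with self._lock:
            if cmd.verb == "SETUP":
                if self.state == "streaming":
                    raise ProtocolError("SETUP rejected while streaming")
                self.session = self._session_factory(cmd.arguments)
                self.record = SessionRecord(n_frames=self.session.frames.n_frames)
                self.state = "configured"
                return "OK"
            if cmd.verb == "START":
                if self.state == "streaming":
                    raise ProtocolError("already streaming")
                if self.state != "configured" or self.session is None:
                    raise ProtocolError("SETUP required before START")
                self._abort.clear()
                self.record = SessionRecord(n_frames=self.session.frames.n_frames)
                self.state = "streaming"
                t = threading.Thread(target=self._stream_session, daemon=True)
                t.start()
                self._threads.append(t)
                return "OK " + json.dumps(self._metadata())
            if cmd.verb == "STOP":
                if self.state == "streaming":
                    self._abort.set()
                    self.state = "configured"
                    return "OK"
                if self.state == "configured":
                    self.state = "idle"
                    self.session = None
                    return "OK"
                raise ProtocolError("nothing to stop")
            if cmd.verb == "STATUS":
                return "OK " + json.dumps(
                    {
                        "state": self.state,
                        "frames_sent": self.record.frames_sent,
                        "packets_sent": self.record.packets_sent,
                        "overrun": self.record.overrun,
                        "completed": self.record.completed,
                    }
                )
        raise ProtocolError(f"unhandled verb {cmd.verb}")  # pragma: no cover

    def _metadata(self) -> dict:
        s = self.session
        labels = s.cmap.labels
        roles = [c.role for c in s.cmap.channels]
        return {
            "data_port": self.data_port,
            "n_frames": s.frames.n_frames,
            "frames_per_packet": self.frames_per_packet,
            "frame_nbytes": s.cmap.frame_nbytes,
            "fs_hz": s.plan.fs_hz,
            "n_channels": s.cmap.n_enabled,
            "channel_labels": labels,
            "channel_roles": roles,
            "channel_map": s.cmap.to_dict(),
            "plan": s.plan.to_dict(),
            "scenario": s.scenario.to_dict(),
        }

    # -- data channel ----------------------------------------------------------
    def _stream_session(self) -> None:
        session = self.session
        record = self.record
        try:
            conn, _ = self._data_sock.accept()
        except (socket.timeout, OSError):
            with self._lock:
                record.error = "no data connection"
                self.state = "configured"
            return
        if self.data_sndbuf:
            conn.setsockopt(socket.SOL_SOCKET, socket.SO_SNDBUF, self.data_sndbuf)

        send_q: queue.Queue[bytes | None] = queue.Queue(maxsize=self.max_buffer_packets)
        writer_done = threading.Event()

        def writer() -> None:
            try:
                while True:
                    pkt = send_q.get()
                    if pkt is None:
                        break
                    conn.sendall(pkt)
                    with self._lock:
                        record.packets_sent += 1
            except OSError as exc:
                with self._lock:
                    record.error = f"socket failure: {exc}"
                self._abort.set()
            finally:
                writer_done.set()

        wt = threading.Thread(target=writer, daemon=True)
        wt.start()

        data = session.frames.to_bytes(session.cmap)
        frame_nbytes = session.cmap.frame_nbytes
        per = self.frames_per_packet * frame_nbytes
        try:
            for off in range(0, len(data), per):
                if self._abort.is_set() or self._shutdown.is_set():
                    break
                payload = data[off : off + per]
                pkt = len(payload).to_bytes(4, "little") + payload
                try:
                    # the acquisition side tolerates back-pressure only up to
                    # the buffer bound; beyond it streaming halts with an error
                    send_q.put(pkt, timeout=self.overrun_timeout_s)
                except queue.Full:
                    with self._lock:
                        record.overrun = True
                        record.error = "flow-control overrun: client not draining"
                    break
                with self._lock:
                    record.frames_sent += len(payload) // frame_nbytes
            else:
                record.completed = True
            if record.completed:
                # end-of-stream marker
                try:
                    send_q.put((0).to_bytes(4, "little"), timeout=self.overrun_timeout_s)
                except queue.Full:
                    record.overrun = True
        finally:
            send_q.put(None)
            if record.overrun:
                # drop whatever the stalled client never drained
                conn.close()
            writer_done.wait(timeout=5.0)
            conn.close()
            with self._lock:
                if self.state == "streaming":
                    self.state = "configured"


# ---------------------------------------------------------------------------
# sinks

class FrameSink:
    """Receiver-side publication interface (LSL-style, transport-agnostic)."""

    def on_metadata(self, metadata: dict) -> None:  # pragma: no cover - interface
        pass

    def on_frames(self, block: FrameBlock, cmap: ChannelMap) -> None:  # pragma: no cover
        pass

    def close(self) -> None:  # pragma: no cover - interface
        pass


class ListSink(FrameSink):
    """Collects decoded frame blocks in memory (tests, offline use)."""

    def __init__(self) -> None:
        self.metadata: dict | None = None
        self.blocks: list[FrameBlock] = []

    def on_metadata(self, metadata: dict) -> None:
        self.metadata = metadata

    def on_frames(self, block: FrameBlock, cmap: ChannelMap) -> None:
        self.blocks.append(block)


class LogWriterSink(FrameSink):
    """Writes the received session to a frame log + sidecar on close."""

    def __init__(self, path):
        self.path = path
        self.metadata: dict | None = None
        self._blocks: list[FrameBlock] = []
        self._cmap: ChannelMap | None = None

    def on_metadata(self, metadata: dict) -> None:
        self.metadata = metadata

    def on_frames(self, block: FrameBlock, cmap: ChannelMap) -> None:
        self._blocks.append(block)
        self._cmap = cmap

    def close(self) -> None:
        if self._cmap is None:
            return
        status = np.concatenate([b.status for b in self._blocks])
        codes = np.concatenate([b.codes for b in self._blocks])
        block = FrameBlock(status=status, codes=codes)
        plan = None
        if self.metadata and self.metadata.get("plan"):
            plan = IlluminationPlan.from_dict(self.metadata["plan"])
        extra = {"received_metadata": self.metadata} if self.metadata else None
        write_frame_log(self.path, block, self._cmap, plan=plan, extra=extra)


class LslSink(FrameSink):
    """Publishes decoded samples through a Lab Streaming Layer outlet.

    Requires the optional ``pylsl`` package; construction fails with a clear
    message when it is absent.  Stream metadata carries channel count,
    nominal rate, channel labels and modality (role) labels.
    """

    def __init__(self, name: str = "biomux", stream_type: str = "EEG"):
        try:
            import pylsl
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "LslSink requires the optional 'pylsl' package (pip install pylsl)"
            ) from exc
        self._pylsl = pylsl
        self.name = name
        self.stream_type = stream_type
        self._outlet = None

    def on_metadata(self, metadata: dict) -> None:  # pragma: no cover - needs liblsl
        pylsl = self._pylsl
        info = pylsl.StreamInfo(
            self.name,
            self.stream_type,
            metadata["n_channels"],
            metadata["fs_hz"],
            "float32",
            f"{self.name}-{metadata.get('scenario', {}).get('seed', 0)}",
        )
        chans = info.desc().append_child("channels")
        for label, role in zip(metadata["channel_labels"], metadata["channel_roles"]):
            ch = chans.append_child("channel")
            ch.append_child_value("label", label)
            ch.append_child_value("modality", role)
        self._outlet = pylsl.StreamOutlet(info)

    def on_frames(self, block: FrameBlock, cmap: ChannelMap) -> None:  # pragma: no cover
        if self._outlet is not None:
            self._outlet.push_chunk(block.volts(cmap).tolist())


# ---------------------------------------------------------------------------
# receiver

@dataclass
class ReceivedSession:
    """Decoded frame sequence plus the session metadata that describes it."""

    frames: FrameBlock
    metadata: dict
    cmap: ChannelMap
    plan: IlluminationPlan | None
    complete: bool
    n_packets: int = 0

    @property
    def n_frames(self) -> int:
        return self.frames.n_frames


def _recv_exact(sock: socket.socket, n: int) -> bytes | None:
    buf = bytearray()
    while len(buf) < n:
        chunk = sock.recv(n - len(buf))
        if not chunk:
            return None
        buf += chunk
    return bytes(buf)


def receive_stream(
    host: str,
    control_port: int,
    setup_args: dict | None = None,
    sink: FrameSink | None = None,
    timeout_s: float = 30.0,
) -> ReceivedSession:
    """Run one full session against an emulator endpoint.

    Sends SETUP (with optional arguments) and START on the control channel,
    drains the data channel until the zero-length end-of-stream packet, then
    STOPs.  Decoded samples are byte-identical to the emulator's generated
    frames; on a mid-stream disconnect the session is preserved up to the
    last whole frame (``complete`` is False).  Sample timing is derived
    purely from frame position and ``f_s`` — arrival times are transport
    metadata only.
    """
    ctrl = socket.create_connection((host, control_port), timeout=timeout_s)
    rfile = ctrl.makefile("r", encoding="ascii", newline="\n")

    def command(line: str) -> str:
        ctrl.sendall((line + "\n").encode("ascii"))
        reply = rfile.readline().strip()
        if not reply.startswith("OK"):
            raise ProtocolError(reply or "connection closed")
        return reply[2:].strip()

    args = " ".join(f"{k}={v}" for k, v in (setup_args or {}).items())
    command(("SETUP " + args).strip())
    metadata = json.loads(command("START"))
    cmap = ChannelMap.from_dict(metadata["channel_map"])
    plan = IlluminationPlan.from_dict(metadata["plan"]) if metadata.get("plan") else None
    if sink is not None:
        sink.on_metadata(metadata)

    payload = bytearray()
    n_packets = 0
    complete = False
    data = socket.create_connection((host, metadata["data_port"]), timeout=timeout_s)
    try:
        while True:
            header = _recv_exact(data, 4)
            if header is None:
                break
            length = int.from_bytes(header, "little")
            if length == 0:
                complete = True
                break
            body = _recv_exact(data, length)
            if body is None:
                break
            payload += body
            n_packets += 1
            if sink is not None:
                sink.on_frames(FrameBlock.from_bytes(body, cmap, strict=False), cmap)
    finally:
        data.close()
        try:
            command("STOP")
        except (ProtocolError, OSError):
            pass
        ctrl.close()

    frames = FrameBlock.from_bytes(bytes(payload), cmap, strict=False)
    if sink is not None:
        sink.close()
    return ReceivedSession(
        frames=frames,
        metadata=metadata,
        cmap=cmap,
        plan=plan,
        complete=complete,
        n_packets=n_packets,
    )


def record_log(
    path,
    frames: FrameBlock,
    cmap: ChannelMap,
    plan: IlluminationPlan | None = None,
    extra: dict | None = None,
) -> None:
    """Write a session to the local frame-log format (bytes + JSON sidecar);
    the file re-reads to the identical frame sequence."""
    write_frame_log(path, frames, cmap, plan=plan, extra=extra)
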