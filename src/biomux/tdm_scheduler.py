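"""Phase-locked time-division-multiplexed illumination scheduling.

Illumination state advances only at ADC frame boundaries, so the optical
sampling grid is locked to the same clock as the electrode channels.  With an
ADC output rate ``f_s`` and an illumination cycle of ``N_state`` discrete
states (blanking intervals included), the effective per-state sample rate is

    f_state = f_s / N_state

The LED bank is driven by 16-channel constant-current sinks (up to four
devices: 64 single-wavelength emitters, i.e. 32 dual-wavelength packages),
limited to 60 mA per channel at the 3.3 V supply.  Greyscale/dot-correction
PWM is modelled only as a stable current set-point.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

__all__ = [
    "TLC5940_MAX_CURRENT_MA",
    "EMITTERS_PER_DRIVER",
    "MAX_DRIVERS",
    "ADS1299_DATA_RATES",
    "DEFAULT_FORWARD_VOLTAGE_V",
    "PlanError",
    "CapacityError",
    "IlluminationState",
    "IlluminationPlan",
    "CapacityReport",
    "LedPowerReport",
    "effective_rate",
    "validate_capacity",
    "state_for_frame",
    "mean_led_power",
    "default_plan",
    "load_plan",
    "save_plan",
]

TLC5940_MAX_CURRENT_MA = 60.0    # per sink channel at a 3.3 V LED supply
EMITTERS_PER_DRIVER = 16
MAX_DRIVERS = 4
ADS1299_DATA_RATES = (250, 500, 1000, 2000, 4000, 8000, 16000)  # SPS
DEFAULT_FORWARD_VOLTAGE_V = 1.7  # midpoint of the 1.55-1.85 V typical range


class PlanError(ValueError):
    """Illumination plan structurally invalid."""


class CapacityError(PlanError):
    """Plan exceeds driver-bank capacity or current limits."""

    def __init__(self, message: str, offending_states: list | None = None):
        super().__init__(message)
        self.offending_states = offending_states or []


@dataclass(frozen=True)
class IlluminationState:
    """One dwell of the illumination cycle.

    ``wavelength`` is 750 or 850 (nm), or None for a blanking state (all
    emitters off).  The 60 mA driver limit is checked at plan validation so
    that over-current plans can be constructed and then rejected with a
    report.
    """

    state_id: int
    source_index: int = 0
    wavelength: int | None = None
    drive_current_ma: float = 0.0
    duration_frames: int = 1

    def __post_init__(self) -> None:
        if self.wavelength not in (750, 850, None):
            raise PlanError(f"wavelength must be 750, 850 or None, got {self.wavelength}")
        if self.is_blank and self.drive_current_ma != 0.0:
            raise PlanError("blanking states must have zero drive current")
        if self.duration_frames < 1:
            raise PlanError("duration_frames must be a positive integer")
        if self.drive_current_ma < 0:
            raise PlanError("drive current must be non-negative")

    @property
    def is_blank(self) -> bool:
        return self.wavelength is None


class IlluminationPlan:
    """Ordered illumination states plus the ADC rate they are locked to.

    State ids must equal list positions (they are what the firmware embeds in
    the status word).  At most one non-blank wavelength is active per state by
    construction: a state carries a single (source, wavelength).
    """

    def __init__(self, states: Sequence[IlluminationState], fs_hz: float):
        states = list(states)
        if not states:
            raise PlanError("plan must contain at least one state")
        for i, s in enumerate(states):
            if s.state_id != i:
                raise PlanError(f"state at position {i} carries state_id {s.state_id}")
        if fs_hz not in ADS1299_DATA_RATES:
            raise PlanError(f"fs_hz must be one of {ADS1299_DATA_RATES}, got {fs_hz}")
        self.states = states
        self.fs_hz = float(fs_hz)
        durations = np.array([s.duration_frames for s in states], dtype=np.int64)
        self._cum = np.concatenate([[0], np.cumsum(durations)])

    @property
    def n_state(self) -> int:
        """Number of discrete states, blanking included."""
        return len(self.states)

    @property
    def f_state_hz(self) -> float:
        """Effective per-state sample rate, f_s / N_state."""
        return effective_rate(self.fs_hz, self.n_state)

    @property
    def period_frames(self) -> int:
        return int(self._cum[-1])

    @property
    def emitters(self) -> list[tuple[int, int]]:
        """Distinct (source_index, wavelength) pairs the plan addresses."""
        seen: dict[tuple[int, int], None] = {}
        for s in self.states:
            if not s.is_blank:
                seen.setdefault((s.source_index, s.wavelength), None)
        return list(seen)

    # -- scheduling ------------------------------------------------------------
    def state_for_frame(self, frame_index: int) -> IlluminationState:
        """The state active at a frame index; pure and periodic."""
        if frame_index < 0:
            raise PlanError("frame_index must be non-negative")
        pos = frame_index % self.period_frames
        idx = int(np.searchsorted(self._cum, pos, side="right")) - 1
        return self.states[idx]

    def state_ids_for_frames(self, frame_indices: np.ndarray) -> np.ndarray:
        """Vectorised plan walk: state index per frame."""
        pos = np.asarray(frame_indices, dtype=np.int64) % self.period_frames
        return np.searchsorted(self._cum, pos, side="right") - 1

    def status_words_for_frames(self, frame_indices: np.ndarray) -> np.ndarray:
        """Raw 24-bit status words for a frame-index vector (codec dialect)."""
        from .frame_codec import StatusWord

        per_state = np.array(
            [
                StatusWord(
                    state_id=s.state_id,
                    source_index=s.source_index,
                    wavelength=s.wavelength,
                    blanking=s.is_blank,
                ).to_int()
                for s in self.states
            ],
            dtype=np.uint32,
        )
        return per_state[self.state_ids_for_frames(frame_indices)]

    # -- serialisation ---------------------------------------------------------
    def to_dict(self) -> dict:
        return {"fs_hz": self.fs_hz, "states": [asdict(s) for s in self.states]}

    @classmethod
    def from_dict(cls, d: dict) -> "IlluminationPlan":
        return cls([IlluminationState(**s) for s in d["states"]], fs_hz=d["fs_hz"])

    def __eq__(self, other) -> bool:
        return isinstance(other, IlluminationPlan) and self.to_dict() == other.to_dict()

    def __repr__(self) -> str:
        return (
            f"IlluminationPlan({self.n_state} states, fs={self.fs_hz:g} Hz, "
            f"f_state={self.f_state_hz:g} Hz)"
        )


# ---------------------------------------------------------------------------
# operations

def effective_rate(fs_hz: float, n_state: int) -> float:
    """Effective per-state sample rate f_state = f_s / N_state."""
    if n_state < 1:
        raise PlanError(f"n_state must be >= 1, got {n_state}")
    if fs_hz <= 0:
        raise PlanError(f"fs_hz must be positive, got {fs_hz}")
    return fs_hz / n_state


@dataclass
class CapacityReport:
    n_drivers: int
    max_emitters: int            # single-wavelength emitter channels
    max_dual_packages: int       # dual-wavelength LED packages
    errors: list[str] = field(default_factory=list)
    offending_states: list[IlluminationState] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.errors


def validate_capacity(
    plan: IlluminationPlan, n_drivers: int, raise_on_error: bool = True
) -> CapacityReport:
    """Check a plan against the driver bank: emitter addressing and current.

    Each 16-channel driver sinks one single-wavelength emitter per channel;
    a dual-wavelength package occupies two channels.  Source ``s`` at
    wavelength ``w`` occupies emitter channel ``2*s`` (750 nm) or ``2*s + 1``
    (850 nm).
    """
    if not 1 <= n_drivers <= MAX_DRIVERS:
        raise CapacityError(f"n_drivers must be 1-{MAX_DRIVERS}, got {n_drivers}")
    max_emitters = EMITTERS_PER_DRIVER * n_drivers
    report = CapacityReport(
        n_drivers=n_drivers,
        max_emitters=max_emitters,
        max_dual_packages=max_emitters // 2,
    )
    for s in plan.states:
        if s.is_blank:
            continue
        emitter_channel = 2 * s.source_index + (0 if s.wavelength == 750 else 1)
        if emitter_channel >= max_emitters:
            report.errors.append(
                f"state {s.state_id}: emitter channel {emitter_channel} exceeds "
                f"capacity {max_emitters} of {n_drivers} driver(s)"
            )
            report.offending_states.append(s)
        if s.drive_current_ma > TLC5940_MAX_CURRENT_MA:
            report.errors.append(
                f"state {s.state_id}: {s.drive_current_ma:g} mA exceeds the "
                f"{TLC5940_MAX_CURRENT_MA:g} mA driver limit"
            )
            report.offending_states.append(s)
    if report.errors and raise_on_error:
        raise CapacityError("; ".join(report.errors), report.offending_states)
    return report


def state_for_frame(plan: IlluminationPlan, frame_index: int) -> IlluminationState:
    """Module-level alias of :meth:`IlluminationPlan.state_for_frame`."""
    return plan.state_for_frame(frame_index)


@dataclass
class LedPowerReport:
    forward_voltage_v: float
    per_emitter_mw: dict          # (source, wavelength) -> mean dissipation, mW
    duty: dict                    # (source, wavelength) -> fraction of cycle lit
    total_mean_mw: float


def mean_led_power(
    plan: IlluminationPlan, forward_voltage_v: float = DEFAULT_FORWARD_VOLTAGE_V
) -> LedPowerReport:
    """Mean LED dissipation under strict time multiplexing.

    Per emitter the mean is ``I * V_f * duty``; the cycle total depends only
    on drive current and overall lit duty, not on how many emitters share the
    cycle (one LED is on at any instant, so total mean power is that of a
    single continuously operating LED scaled by the non-blank duty).
    """
    period = plan.period_frames
    per_emitter: dict[tuple[int, int], float] = {}
    duty: dict[tuple[int, int], float] = {}
    total = 0.0
    for key in plan.emitters:
        frames_lit = sum(
            s.duration_frames
            for s in plan.states
            if not s.is_blank and (s.source_index, s.wavelength) == key
        )
        d = frames_lit / period
        # states for the same emitter may use different currents; average
        # instantaneous power over its lit frames
        mw = (
            sum(
                s.drive_current_ma * forward_voltage_v * s.duration_frames
                for s in plan.states
                if not s.is_blank and (s.source_index, s.wavelength) == key
            )
            / period
        )
        per_emitter[key] = mw
        duty[key] = d
        total += mw
    return LedPowerReport(
        forward_voltage_v=forward_voltage_v,
        per_emitter_mw=per_emitter,
        duty=duty,
        total_mean_mw=total,
    )


# ---------------------------------------------------------------------------
# plan construction and files

def default_plan(
    n_sources: int,
    fs_hz: float,
    drive_current_ma: float = 50.0,
    wavelengths: Sequence[int] = (750, 850),
    blanking_frames: int = 1,
    duration_frames: int = 1,
) -> IlluminationPlan:
    """Round-robin plan: each source at each wavelength, one frame per state,
    with a blanking state inserted between wavelength transitions (count
    configurable; 0 disables blanking)."""
    states: list[IlluminationState] = []

    def add(**kw) -> None:
        states.append(IlluminationState(state_id=len(states), **kw))

    for src in range(n_sources):
        for wl in wavelengths:
            add(
                source_index=src,
                wavelength=wl,
                drive_current_ma=drive_current_ma,
                duration_frames=duration_frames,
            )
            if blanking_frames > 0:
                add(duration_frames=blanking_frames)
    return IlluminationPlan(states, fs_hz=fs_hz)


def save_plan(path: str | os.PathLike, plan: IlluminationPlan) -> None:
    with open(path, "w") as fh:
        json.dump(plan.to_dict(), fh, indent=1)


def load_plan(path: str | os.PathLike) -> IlluminationPlan:
    """Load and structurally validate a plan definition file."""
    with open(path) as fh:
        return IlluminationPlan.from_dict(json.load(fh))
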