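"""Instrument energy budget: battery energy, mode runtimes, detector NEP.

The battery is a single-cell Li-ion pack (2500 mAh nominal at 3.7 V, i.e.
9.25 Wh); regulator and conversion losses derate this to a usable estimate —
modelled as an efficiency factor, default 0.8, giving 7.4 Wh.  Mode runtime
is simply usable energy divided by the measured steady-state mode power,
reported to one decimal (half-up), the precision the measurements support.

The bundled mode table holds the measured end-to-end powers (rounded to the
nearest 10 mW) for the eight operating modes spanning local logging versus
Wi-Fi streaming, 1 versus 4 ADC devices, and LED drive off / nominal
(25-30 mA) / high (50-60 mA).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "PowerError",
    "ModeMeasurement",
    "ModeResult",
    "PowerBudget",
    "MEASURED_MODES",
    "runtime_hours",
    "reproduce_mode_table",
    "nep_estimate",
]


class PowerError(ValueError):
    """Non-physical power-model input."""


@dataclass(frozen=True)
class ModeMeasurement:
    """One operating mode: measured end-to-end power and the runtime the
    instrument's characterisation reports for it."""

    mode: str
    mcu: str
    n_ads1299: int
    led_state: str
    power_mw: float
    reported_runtime_h: float


#: Measured operating modes (end-to-end power at the battery input).
MEASURED_MODES: tuple[ModeMeasurement, ...] = (
    ModeMeasurement("EEG-only, local storage", "STM32", 1, "none", 280, 26.4),
    ModeMeasurement("EEG-only, local storage", "STM32", 4, "none", 400, 18.5),
    ModeMeasurement("EEG + fNIRS (nominal)", "STM32", 4, "1 LED @ 25-30 mA", 470, 15.7),
    ModeMeasurement("EEG + fNIRS (high optical)", "STM32", 4, "1 LED @ 50-60 mA", 530, 14.0),
    ModeMeasurement("EEG-only streaming", "STM32 + ESP32", 1, "none", 590, 12.5),
    ModeMeasurement("EEG-only streaming", "STM32 + ESP32", 4, "none", 710, 10.4),
    ModeMeasurement("EEG + fNIRS streaming (nominal)", "STM32 + ESP32", 4, "1 LED @ 25-30 mA", 780, 9.5),
    ModeMeasurement("EEG + fNIRS streaming (high optical)", "STM32 + ESP32", 4, "1 LED @ 50-60 mA", 840, 8.8),
)


def runtime_hours(usable_wh: float, power_mw: float) -> float:
    """Estimated runtime ``usable_Wh / power_W``, one decimal, half-up."""
    if power_mw <= 0:
        raise PowerError(f"power must be positive, got {power_mw} mW")
    if usable_wh < 0:
        raise PowerError(f"usable energy must be non-negative, got {usable_wh} Wh")
    hours = Decimal(str(usable_wh)) / (Decimal(str(power_mw)) / Decimal(1000))
    return float(hours.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass
class ModeResult:
    measurement: ModeMeasurement
    computed_runtime_h: float

    @property
    def discrepancy_h(self) -> float:
        return self.computed_runtime_h - self.measurement.reported_runtime_h


@dataclass
class PowerBudget:
    """Battery capacity, derating and the resulting per-mode runtimes."""

    capacity_mah: float = 2500.0
    voltage_v: float = 3.7
    efficiency: float = 0.8
    modes: tuple = field(default_factory=lambda: MEASURED_MODES)

    def __post_init__(self) -> None:
        if self.capacity_mah <= 0 or self.voltage_v <= 0:
            raise PowerError("capacity and voltage must be positive")
        if not 0 < self.efficiency <= 1:
            raise PowerError("efficiency must be in (0, 1]")

    @property
    def nominal_wh(self) -> float:
        """Nominal energy = capacity x voltage."""
        return self.capacity_mah / 1000.0 * self.voltage_v

    @property
    def usable_wh(self) -> float:
        """Practical usable energy after regulator/conversion losses."""
        return self.efficiency * self.nominal_wh

    def runtime(self, power_mw: float) -> float:
        return runtime_hours(self.usable_wh, power_mw)


def reproduce_mode_table(budget: PowerBudget | None = None) -> list[ModeResult]:
    """Recompute every mode's runtime from the budget's usable energy and the
    measured mode powers, alongside the discrepancy against the reported
    values."""
    budget = budget or PowerBudget()
    return [
        ModeResult(measurement=m, computed_runtime_h=budget.runtime(m.power_mw))
        for m in budget.modes
    ]


def nep_estimate(
    output_noise_vrms: float = 300e-6,
    bandwidth_hz: float = 20e3 - 0.1,
    transimpedance_ohm: float = 1e6,
    responsivity_a_per_w: float = 0.45,
) -> float:
    """Noise-equivalent power of the photoreceiver, W/sqrt(Hz).

    NEP = (output noise / transimpedance) / (sqrt(bandwidth) x responsivity):
    the output noise referred to input current, whitened over the noise
    bandwidth, divided by the photodiode responsivity.  Defaults are the
    receiver's datasheet values (300 uVrms over 0.1 Hz-20 kHz at 1 Mohm,
    0.45 A/W).
    """
    for name, v in (
        ("output_noise_vrms", output_noise_vrms),
        ("bandwidth_hz", bandwidth_hz),
        ("transimpedance_ohm", transimpedance_ohm),
        ("responsivity_a_per_w", responsivity_a_per_w),
    ):
        if v <= 0:
            raise PowerError(f"{name} must be positive, got {v}")
    noise_current = output_noise_vrms / transimpedance_ohm
    return noise_current / (math.sqrt(bandwidth_hz) * responsivity_a_per_w)
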