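"""Modified Beer-Lambert haemoglobin estimation for dual-wavelength CW fNIRS.

Intensity changes at 750/850 nm are converted to optical-density changes,

    dOD(lambda, t) = -log10( I(lambda, t) / I_baseline(lambda) ),

and then to concentration changes by solving, per time point, the 2x2 system

    dOD(lambda) = [ eps(lambda, HbO) * dHbO + eps(lambda, HbR) * dHbR ]
                    * d * DPF(lambda)

where ``d`` is the source-detector separation (cm) and ``DPF`` the
differential pathlength factor.  Total haemoglobin is
``dHbT = dHbO + dHbR`` pointwise.  A forward model (concentrations -> dOD)
is provided for the signal emulator; forward followed by inverse is the
identity up to floating-point error.

Default extinction coefficients are the Gratzer/Prahl compilation values
(molar extinction, cm^-1 M^-1, base-10) at 750 and 850 nm; they, the DPF
(6.0) and the separation (3.0 cm, conventional adult forehead) are all
overridable — absolute concentration scales depend entirely on this choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EXTINCTION_GRATZER_CM_PER_M",
    "MbllParameters",
    "HaemoSeries",
    "MbllError",
    "DataError",
    "optical_density",
    "mbll_invert",
    "mbll_forward",
]

#: Molar (base-10) extinction coefficients, cm^-1 M^-1, from the
#: Gratzer/Prahl haemoglobin spectra compilation (omlc.org).
EXTINCTION_GRATZER_CM_PER_M = {
    (750, "HbO"): 518.0,
    (750, "HbR"): 1405.24,
    (850, "HbO"): 1058.0,
    (850, "HbR"): 691.32,
}


class MbllError(ValueError):
    """Invalid pathlength/extinction parameterisation."""


class DataError(ValueError):
    """Input series unusable (e.g. non-positive intensity)."""


@dataclass
class MbllParameters:
    """Pathlength and extinction parameterisation of the MBLL.

    ``extinction`` maps (wavelength_nm, chromophore) to the molar base-10
    extinction coefficient in cm^-1 M^-1; concentrations are reported in uM.
    """

    extinction: dict = field(default_factory=lambda: dict(EXTINCTION_GRATZER_CM_PER_M))
    dpf: dict = field(default_factory=lambda: {750: 6.0, 850: 6.0})
    separation_cm: float = 3.0
    baseline_window_s: tuple = (0.0, 30.0)
    wavelengths: tuple = (750, 850)

    def matrix(self) -> np.ndarray:
        """2x2 system matrix A with A[i, j] = eps(l_i, c_j) * d * DPF(l_i),
        in cm^-1 uM^-1 * cm so that dOD = A @ [dHbO_uM, dHbR_uM]."""
        rows = []
        for wl in self.wavelengths:
            rows.append(
                [
                    self.extinction[(wl, "HbO")] * 1e-6 * self.separation_cm * self.dpf[wl],
                    self.extinction[(wl, "HbR")] * 1e-6 * self.separation_cm * self.dpf[wl],
                ]
            )
        return np.asarray(rows, dtype=float)

    @property
    def condition_number(self) -> float:
        return float(np.linalg.cond(self.matrix()))

    def validate(self) -> None:
        a = self.matrix()
        if not np.all(np.isfinite(a)):
            raise MbllError("non-finite extinction/pathlength parameters")
        if np.linalg.matrix_rank(a) < 2:
            raise MbllError("extinction matrix is singular: wavelengths carry no contrast")


@dataclass
class HaemoSeries:
    """dHbO / dHbR concentration-change traces (uM) on a uniform time base."""

    hbo: np.ndarray
    hbr: np.ndarray
    rate_hz: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise DataError("dHbO and dHbR must share a shape")

    @property
    def hbt(self) -> np.ndarray:
        """Total haemoglobin change, dHbT = dHbO + dHbR pointwise."""
        return self.hbo + self.hbr

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.hbo.size) / self.rate_hz


def optical_density(
    intensity: np.ndarray,
    rate_hz: float,
    baseline_window_s: tuple = (0.0, 30.0),
    detrend: bool = False,
) -> np.ndarray:
    """Optical-density change relative to the mean over a baseline window.

    The mean of dOD over the baseline window is zero by construction (up to
    the log of the intensity spread).  Non-positive intensities are a data
    error, not silently clipped.  ``detrend`` removes a linear trend from the
    intensities (in log domain) before referencing.
    """
    i = np.asarray(intensity, dtype=float)
    if np.any(~np.isfinite(i)) or np.any(i <= 0):
        raise DataError("intensities must be finite and strictly positive")
    lo, hi = baseline_window_s
    sel = slice(int(round(lo * rate_hz)), int(round(hi * rate_hz)))
    log_i = np.log10(i)
    if detrend:
        t = np.arange(i.size, dtype=float)
        slope, intercept = np.polyfit(t, log_i, 1)
        log_i = log_i - slope * (t - t.mean())
    baseline = log_i[sel]
    if baseline.size == 0:
        raise DataError("baseline window selects no samples")
    return -(log_i - baseline.mean())


def mbll_invert(
    dod_750: np.ndarray,
    dod_850: np.ndarray,
    params: MbllParameters | None = None,
    rate_hz: float = 1.0,
    t0: float = 0.0,
) -> HaemoSeries:
    """Solve the two-wavelength MBLL system per time point.

    The two dOD series must be time-aligned (same source, same state grid).
    Linear in its inputs; a singular extinction matrix raises
    :class:`MbllError`.
    """
    params = params or MbllParameters()
    params.validate()
    dod_750 = np.asarray(dod_750, dtype=float)
    dod_850 = np.asarray(dod_850, dtype=float)
    if dod_750.shape != dod_850.shape:
        raise DataError("wavelength series must be time-aligned (equal lengths)")
    a = params.matrix()
    conc = np.linalg.solve(a, np.vstack([dod_750, dod_850]))
    return HaemoSeries(hbo=conc[0], hbr=conc[1], rate_hz=rate_hz, t0=t0)


def mbll_forward(
    series: HaemoSeries, params: MbllParameters | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Forward MBLL: concentration changes (uM) to (dOD_750, dOD_850)."""
    params = params or MbllParameters()
    params.validate()
    a = params.matrix()
    dod = a @ np.vstack([series.hbo, series.hbr])
    return dod[0], dod[1]
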