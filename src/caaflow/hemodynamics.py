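"""Wall-shear-stress metrics over a morphed lumen under pulsatile coronary flow.

The wall shear stress field is closed with a quasi-steady Poiseuille law: at
each axial station the instantaneous shear is that of fully developed laminar
flow through a rigid tube of the local radius,

    tau(s, t) = 4 mu Q(t) / (pi r(s)^3)      [dyn/cm^2, CGS]

signed by the instantaneous flow direction.  From the field the module derives
the standard thrombotic-risk surrogates: time-averaged WSS (TAWSS), the
percentage of aneurysm surface area below low-shear thresholds, the
oscillatory shear index (OSI), and a volume-turnover residence time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circulation import FluidProperties
from .geometry import VesselGeometry, lumen_volume, surface_area

__all__ = [
    "WSSField",
    "HemodynamicMetrics",
    "HemodynamicsError",
    "wss_field",
    "tawss",
    "tawss_mean",
    "low_wss_area_fraction",
    "osi",
    "residence_time",
    "summarize",
]


class HemodynamicsError(ValueError):
    """Invalid hemodynamic input (non-periodic flow, bad threshold, no flow)."""


@dataclass(frozen=True)
class WSSField:
    """Signed wall shear stress tau(s, t) on an (axial, time) grid, CGS units."""

    s: np.ndarray  # (ns,) axial positions, cm
    time: np.ndarray  # (nt,) one cycle, s
    tau: np.ndarray  # (ns, nt), dyn/cm^2

    def __post_init__(self) -> None:
        if self.tau.shape != (self.s.size, self.time.size):
            raise HemodynamicsError("tau must have shape (len(s), len(time))")

    @property
    def period(self) -> float:
        return float(self.time[-1] - self.time[0])


@dataclass(frozen=True)
class HemodynamicMetrics:
    """Aneurysm-level shear metrics; one output record per case."""

    case_id: str
    tawss_mean: float  # area-averaged TAWSS over the aneurysm, dyn/cm^2
    area_wss4: float  # % aneurysm surface with TAWSS < 4 dyn/cm^2
    area_wss1: float  # % aneurysm surface with TAWSS < 1 dyn/cm^2
    osi_max: float  # maximum OSI over the span
    residence_time: float  # volume-turnover time, s

    def __post_init__(self) -> None:
        if not (0.0 <= self.area_wss1 <= self.area_wss4 <= 100.0):
            raise HemodynamicsError("low-WSS area fractions must nest: 0 <= A1 <= A4 <= 100")
        if not (-1e-12 <= self.osi_max <= 0.5 + 1e-12):
            raise HemodynamicsError("OSI must lie in [0, 0.5]")
        if self.tawss_mean < 0:
            raise HemodynamicsError("TAWSS must be non-negative")


def _cycle_grid(geom: VesselGeometry, n_axial: int | None) -> np.ndarray:
    s0, s1 = geom.aneurysm_span
    n = geom.n_samples if n_axial is None else n_axial
    return np.linspace(s0, s1, n + 1)


def wss_field(
    geom: VesselGeometry,
    time: np.ndarray,
    flow: np.ndarray,
    fluid: FluidProperties = FluidProperties(),
    n_axial: int | None = None,
) -> WSSField:
    """Quasi-steady Poiseuille WSS over the aneurysm span.

    Parameters
    ----------
    time, flow
        One periodic cycle of coronary flow, time in s and flow in mL/s
        (= cm^3/s); the first and last flow samples must agree (periodicity).
    fluid
        Blood properties; defaults are density 1.06 g/cc, viscosity 0.04 P.
    n_axial
        Axial sample count across the span (defaults to the geometry's).
    """
    time = np.asarray(time, dtype=float)
    flow = np.asarray(flow, dtype=float)
    if time.ndim != 1 or time.size != flow.size or time.size < 2:
        raise HemodynamicsError("time and flow must be matching 1D arrays")
    # a cycle converged to periodic steady state closes on itself; a gross
    # endpoint mismatch means the input does not span one period
    scale = max(np.max(np.abs(flow)), 1e-30)
    if abs(flow[0] - flow[-1]) > 0.02 * scale:
        raise HemodynamicsError("flow waveform is not periodic over the given cycle")
    s = _cycle_grid(geom, n_axial)
    r = geom.radius(s)
    tau = 4.0 * fluid.viscosity * flow[None, :] / (np.pi * r[:, None] ** 3)
    return WSSField(s=s, time=time, tau=tau)


def tawss(field: WSSField) -> np.ndarray:
    """Per-position time-averaged WSS magnitude, ``(1/T) \\int |tau| dt``."""
    return np.trapezoid(np.abs(field.tau), field.time, axis=1) / field.period


def _area_weights(geom: VesselGeometry, s: np.ndarray) -> np.ndarray:
    return 2.0 * np.pi * geom.radius(s) * np.sqrt(1.0 + geom.radius_slope(s) ** 2)


def tawss_mean(geom: VesselGeometry, field: WSSField) -> float:
    """Surface-area-weighted mean TAWSS over the aneurysm span (dyn/cm^2)."""
    prof = tawss(field)
    w = _area_weights(geom, field.s)
    return float(np.trapezoid(prof * w, field.s) / np.trapezoid(w, field.s))


def low_wss_area_fraction(
    geom: VesselGeometry,
    s: np.ndarray,
    tawss_profile: np.ndarray,
    threshold: float,
) -> float:
    """Percentage of aneurysm surface area with TAWSS strictly below threshold.

    Contiguous sub-intervals of the sampling grid where the profile is below
    the threshold are measured with the surface-of-revolution quadrature and
    referred to the total span area.  Samples exactly at the threshold count
    as not-exposed (strict inequality).
    """
    if threshold <= 0:
        raise HemodynamicsError("threshold must be positive")
    s = np.asarray(s, dtype=float)
    prof = np.asarray(tawss_profile, dtype=float)
    below = prof < threshold
    if not below.any():
        return 0.0
    total = surface_area(geom, float(s[0]), float(s[-1]))
    if total == 0.0:
        return 0.0
    # contiguous runs of below-threshold samples -> sub-interval areas,
    # with run boundaries placed halfway to the neighbouring sample
    area = 0.0
    i = 0
    n = below.size
    while i < n:
        if below[i]:
            j = i
            while j + 1 < n and below[j + 1]:
                j += 1
            a = float(s[i]) if i == 0 else float(0.5 * (s[i - 1] + s[i]))
            b = float(s[j]) if j == n - 1 else float(0.5 * (s[j] + s[j + 1]))
            area += surface_area(geom, a, b)
            i = j + 1
        else:
            i += 1
    return min(100.0 * area / total, 100.0)


def osi(field: WSSField) -> np.ndarray:
    """Per-position oscillatory shear index.

    ``OSI = 0.5 (1 - |\\int tau dt| / \\int |tau| dt)``; zero for
    unidirectional shear, 0.5 for pure zero-mean oscillation, and defined as
    0 where the shear vanishes identically.
    """
    num = np.abs(np.trapezoid(field.tau, field.time, axis=1))
    den = np.trapezoid(np.abs(field.tau), field.time, axis=1)
    out = np.zeros_like(den)
    nz = den > 0
    out[nz] = 0.5 * (1.0 - num[nz] / den[nz])
    return np.clip(out, 0.0, 0.5)


def residence_time(
    geom: VesselGeometry, time: np.ndarray, flow: np.ndarray
) -> float:
    """Volume-turnover residence-time surrogate: span volume / cycle-mean flow.

    Raises
    ------
    HemodynamicsError
        If the cycle-mean flow is not positive.
    """
    time = np.asarray(time, dtype=float)
    flow = np.asarray(flow, dtype=float)
    qbar = float(np.trapezoid(flow, time) / (time[-1] - time[0]))
    if qbar <= 0:
        raise HemodynamicsError("cycle-mean flow must be positive for residence time")
    s0, s1 = geom.aneurysm_span
    return lumen_volume(geom, s0, s1) / qbar


def summarize(
    geom: VesselGeometry,
    field: WSSField,
    time: np.ndarray,
    flow: np.ndarray,
    thresholds: tuple[float, float] = (4.0, 1.0),
    case_id: str | None = None,
) -> HemodynamicMetrics:
    """All aneurysm metrics for one case; asserts the area-fraction nesting."""
    prof = tawss(field)
    hi, lo = max(thresholds), min(thresholds)
    a_hi = low_wss_area_fraction(geom, field.s, prof, hi)
    a_lo = low_wss_area_fraction(geom, field.s, prof, lo)
    return HemodynamicMetrics(
        case_id=geom.spec.case_id if case_id is None else case_id,
        tawss_mean=tawss_mean(geom, field),
        area_wss4=a_hi,
        area_wss1=a_lo,
        osi_max=float(np.max(osi(field))),
        residence_time=residence_time(geom, time, flow),
    )
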