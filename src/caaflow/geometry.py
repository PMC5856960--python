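"""Centerline-parameterized vessel lumens and parametric aneurysm morphing.

A vessel is represented by a 3D centerline (arclength-parameterized polyline)
and an axisymmetric radius profile ``r(s)``.  An aneurysm is imposed on a
healthy tube of radius ``r0`` by dilating the lumen over a prescribed axial
span up to a prescribed maximum diameter ``D_max``; surface area and lumen
volume of the morphed surface of revolution are obtained by quadrature.

Units: geometry is stored internally in CGS (cm).  Aneurysm specifications
are accepted in mm — the convention of clinical caliper measurements — and
converted on ingest.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CenterlinePath",
    "AneurysmSpec",
    "VesselGeometry",
    "GeometryError",
    "build_centerline",
    "morph_aneurysm",
    "aspect_ratio",
    "surface_area",
    "lumen_volume",
    "read_centerline",
    "write_centerline",
    "export_radius_profile",
]

#: default number of axial quadrature samples across a morph span
DEFAULT_AXIAL_SAMPLES = 400

#: default axial extent (cm) of each neck transition between the healthy
#: vessel and the fully dilated aneurysm body; capped at half the span so
#: short aneurysms degenerate to a single smooth bump
DEFAULT_NECK_LENGTH_CM = 1.0


class GeometryError(ValueError):
    """Invalid geometric input (degenerate centerline, bad spec, bad interval)."""


@dataclass(frozen=True)
class CenterlinePath:
    """An ordered 3D polyline with cumulative arclength, in cm.

    Attributes
    ----------
    points : (n, 3) ndarray
        Ordered centerline coordinates in cm.
    arclength : (n,) ndarray
        Cumulative Euclidean arclength per point, starting at 0.
    """

    points: np.ndarray
    arclength: np.ndarray

    def __post_init__(self) -> None:
        self.points.setflags(write=False)
        self.arclength.setflags(write=False)

    @property
    def total_length(self) -> float:
        return float(self.arclength[-1])


@dataclass(frozen=True)
class AneurysmSpec:
    """Geometric inputs of one aneurysm case.

    Diameters and length are in mm (clinical convention); the arclength
    position of the proximal neck is in cm, matching centerline units.
    """

    d_max: float  # maximum aneurysm diameter, mm
    length: float  # axial extent, mm
    s_start: float  # arclength position of the proximal neck, cm
    baseline_diameter: float  # healthy vessel diameter, mm
    case_id: str = ""

    def __post_init__(self) -> None:
        if not (self.baseline_diameter > 0):
            raise GeometryError("baseline_diameter must be positive")
        if self.d_max < self.baseline_diameter:
            raise GeometryError(
                f"d_max ({self.d_max} mm) must be >= baseline_diameter "
                f"({self.baseline_diameter} mm)"
            )
        if not (self.length > 0):
            raise GeometryError("length must be positive")
        if self.s_start < 0:
            raise GeometryError("s_start must be non-negative")

    # -- CGS accessors -------------------------------------------------
    @property
    def r0_cm(self) -> float:
        """Healthy lumen radius in cm."""
        return self.baseline_diameter / 20.0

    @property
    def r_max_cm(self) -> float:
        """Maximum aneurysm radius in cm."""
        return self.d_max / 20.0

    @property
    def length_cm(self) -> float:
        return self.length / 10.0

    @property
    def span(self) -> tuple[float, float]:
        """Aneurysm interval [s_start, s_start + length] in cm."""
        return (self.s_start, self.s_start + self.length_cm)


def build_centerline(points) -> CenterlinePath:
    """Build an arclength-parameterized centerline from ordered 3D points (cm).

    Raises
    ------
    GeometryError
        If fewer than 2 points are given or consecutive points coincide.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GeometryError("centerline points must be an (n, 3) array")
    if pts.shape[0] < 2:
        raise GeometryError("centerline needs at least 2 points")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    if np.any(seg == 0.0):
        raise GeometryError("consecutive centerline points coincide (degenerate segment)")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    return CenterlinePath(points=pts.copy(), arclength=s)


def _smoothstep(u: np.ndarray) -> np.ndarray:
    # cubic Hermite 0 -> 1 with zero slope at both ends
    return u * u * (3.0 - 2.0 * u)


@dataclass(frozen=True)
class VesselGeometry:
    """A morphed axisymmetric lumen: centerline + radius profile r(s) in cm."""

    path: CenterlinePath
    spec: AneurysmSpec
    neck_length: float = DEFAULT_NECK_LENGTH_CM
    n_samples: int = DEFAULT_AXIAL_SAMPLES

    @property
    def aneurysm_span(self) -> tuple[float, float]:
        return self.spec.span

    @property
    def _neck(self) -> float:
        # effective neck extent: never more than half the span
        return min(self.neck_length, self.spec.length_cm / 2.0)

    def radius(self, s) -> np.ndarray:
        """Lumen radius r(s) in cm; vectorized over s.

        Equals the baseline radius outside the aneurysm span.  Inside, the
        profile rises from r0 to D_max/2 through a zero-slope cubic smoothstep
        neck, holds the fully dilated radius across the body, and descends
        symmetrically; the whole profile is C1.
        """
        s = np.asarray(s, dtype=float)
        r0, rm = self.spec.r0_cm, self.spec.r_max_cm
        s0, s1 = self.spec.span
        ell = self._neck
        r = np.full(s.shape, r0)
        if rm > r0:
            up = (s > s0) & (s < s0 + ell)
            r[up] = r0 + (rm - r0) * _smoothstep((s[up] - s0) / ell)
            body = (s >= s0 + ell) & (s <= s1 - ell)
            r[body] = rm
            dn = (s > s1 - ell) & (s < s1)
            r[dn] = r0 + (rm - r0) * _smoothstep((s1 - s[dn]) / ell)
        return r

    def radius_slope(self, s) -> np.ndarray:
        """dr/ds, analytic derivative of the piecewise-cubic profile."""
        s = np.asarray(s, dtype=float)
        r0, rm = self.spec.r0_cm, self.spec.r_max_cm
        s0, s1 = self.spec.span
        ell = self._neck
        dr = np.zeros(s.shape)
        if rm > r0:
            up = (s > s0) & (s < s0 + ell)
            u = (s[up] - s0) / ell
            dr[up] = (rm - r0) * 6.0 * u * (1.0 - u) / ell
            dn = (s > s1 - ell) & (s < s1)
            u = (s1 - s[dn]) / ell
            dr[dn] = -(rm - r0) * 6.0 * u * (1.0 - u) / ell
        return dr


def morph_aneurysm(
    path: CenterlinePath,
    spec: AneurysmSpec,
    neck_length: float = DEFAULT_NECK_LENGTH_CM,
    n_samples: int = DEFAULT_AXIAL_SAMPLES,
) -> VesselGeometry:
    """Impose an aneurysm of prescribed D_max and length on a healthy tube.

    The radius profile interpolates (s_start, r0), (midpoint, D_max/2) and
    (s_start + length, r0) with zero slope at all three control points, never
    exceeds D_max/2 nor drops below r0 within the span, and is identically r0
    outside it.

    Raises
    ------
    GeometryError
        If the aneurysm span does not fit within the centerline extent.
    """
    s0, s1 = spec.span
    if s1 > path.total_length + 1e-12:
        raise GeometryError(
            f"aneurysm span [{s0:.3g}, {s1:.3g}] cm exceeds centerline length "
            f"{path.total_length:.3g} cm"
        )
    return VesselGeometry(path=path, spec=spec, neck_length=neck_length, n_samples=n_samples)


def aspect_ratio(spec: AneurysmSpec) -> float:
    """Aneurysm aspect ratio, length / D_max (both in mm, dimensionless)."""
    return spec.length / spec.d_max


def _quadrature_grid(geom: VesselGeometry, s_a: float, s_b: float, n: int | None):
    if s_b < s_a:
        raise GeometryError("inverted arclength interval")
    if n is None:
        # scale default sampling density with the interval length
        span = geom.spec.length_cm
        density = geom.n_samples / span if span > 0 else geom.n_samples
        n = max(int(np.ceil((s_b - s_a) * density)), 8)
    if n % 2:  # composite Simpson needs an even interval count
        n += 1
    return np.linspace(s_a, s_b, n + 1)


def surface_area(
    geom: VesselGeometry, s_a: float, s_b: float, n: int | None = None
) -> float:
    """Lateral surface area (cm^2) of the lumen between two arclength stations.

    Computes the surface-of-revolution integral
    ``A = \\int 2 pi r(s) sqrt(1 + (dr/ds)^2) ds``
    by composite Simpson quadrature (default ~400 samples per morph span,
    configurable through ``n``).
    """
    from scipy.integrate import simpson

    s = _quadrature_grid(geom, s_a, s_b, n)
    if s[-1] == s[0]:
        return 0.0
    integrand = 2.0 * np.pi * geom.radius(s) * np.sqrt(1.0 + geom.radius_slope(s) ** 2)
    return float(simpson(integrand, x=s))


def lumen_volume(
    geom: VesselGeometry, s_a: float, s_b: float, n: int | None = None
) -> float:
    """Lumen volume (cm^3) between two arclength stations: ``\\int pi r^2 ds``."""
    from scipy.integrate import simpson

    s = _quadrature_grid(geom, s_a, s_b, n)
    if s[-1] == s[0]:
        return 0.0
    return float(simpson(np.pi * geom.radius(s) ** 2, x=s))


# ---------------------------------------------------------------------------
# plain-text I/O


def read_centerline(source) -> CenterlinePath:
    """Read a centerline from a delimited text table with columns x, y, z (cm).

    Accepts a path or file-like object; an optional non-numeric header line is
    skipped.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        with open(source) as fh:
            text = fh.read()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if lines and any(c.isalpha() for c in lines[0]):
        lines = lines[1:]
    pts = np.loadtxt(io.StringIO("\n".join(lines)), ndmin=2)
    return build_centerline(pts)


def write_centerline(path: CenterlinePath, dest, header: bool = True) -> None:
    """Write a centerline as a whitespace-delimited x y z table in cm."""
    hdr = "x_cm y_cm z_cm" if header else ""
    np.savetxt(dest, path.points, fmt="%.9g", header=hdr, comments="")


def export_radius_profile(geom: VesselGeometry, dest, n: int = 200) -> None:
    """Write an (s, r) table in cm sampling the full centerline extent."""
    s = np.linspace(0.0, geom.path.total_length, n)
    np.savetxt(
        dest,
        np.column_stack([s, geom.radius(s)]),
        fmt="%.9g",
        header="s_cm r_cm",
        comments="",
    )
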