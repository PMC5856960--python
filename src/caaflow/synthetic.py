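"""Synthetic study inputs: centerlines, the virtual aneurysm cohort, patient
targets and fixture flow waveforms.

Patient-specific imaging-derived anatomy is not available to this package;
everything the pipeline consumes is generated here, deterministically per
seed, so every stage is testable end-to-end without external data.

The built-in virtual cohort holds the maximum aneurysm diameter fixed while
varying length — two 8 mm cases (20 and 40 mm long), two 7 mm cases (40 and
80 mm long) — plus an unmorphed control, all on a shared healthy baseline
diameter of 3.5 mm (typical adult LAD caliber; configurable).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .circulation import ClinicalTargets
from .geometry import AneurysmSpec, CenterlinePath, build_centerline

__all__ = [
    "CohortSpec",
    "table1_cohort",
    "generate_centerline",
    "generate_patient",
    "fixture_flow_waveform",
    "DEFAULT_BASELINE_DIAMETER_MM",
    "DEFAULT_S_START_CM",
]

DEFAULT_BASELINE_DIAMETER_MM = 3.5
#: morph onset: 1 cm of healthy inlet run-in
DEFAULT_S_START_CM = 1.0
#: healthy run-out distal of the longest morph, cm
RUNOUT_CM = 1.0

#: (case_id, D_max mm, length mm) of the fixed-D_max virtual cohort
COHORT_CASES = (
    ("a.1", 8.0, 20.0),
    ("a.2", 8.0, 40.0),
    ("b.1", 7.0, 40.0),
    ("b.2", 7.0, 80.0),
)

CONTROL_CASE_ID = "control"


@dataclass(frozen=True)
class CohortSpec:
    """A set of aneurysm cases sharing a baseline vessel and clinical targets."""

    specs: tuple[AneurysmSpec, ...]
    baseline_diameter: float  # mm
    targets: ClinicalTargets
    centerline: CenterlinePath
    seed: int

    def __post_init__(self) -> None:
        if not self.specs:
            raise ValueError("cohort must contain at least one case")

    @property
    def morph_specs(self) -> tuple[AneurysmSpec, ...]:
        return tuple(s for s in self.specs if s.case_id != CONTROL_CASE_ID)

    @property
    def control_spec(self) -> AneurysmSpec | None:
        for s in self.specs:
            if s.case_id == CONTROL_CASE_ID:
                return s
        return None


def generate_centerline(
    length_cm: float = 10.5, n_points: int = 120, curvature: float = 0.08, seed: int = 0
) -> CenterlinePath:
    """A gently curved 3D coronary-like centerline of the given arclength.

    The curve is a helical arc with mild seeded waviness; ``curvature``
    controls the transverse amplitude as a fraction of the length.
    """
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, n_points)
    amp = curvature * length_cm
    ph1, ph2 = rng.uniform(0.0, 2.0 * math.pi, size=2)
    x = u * length_cm
    y = amp * np.sin(1.5 * math.pi * u + ph1) * u
    z = 0.5 * amp * np.sin(2.5 * math.pi * u + ph2) * u
    pts = np.column_stack([x, y, z])
    path = build_centerline(pts)
    # rescale so the *arclength* (not the chord) matches the request
    pts *= length_cm / path.total_length
    return build_centerline(pts)


def generate_patient(seed: int) -> tuple[ClinicalTargets, CenterlinePath]:
    """Seeded, physiologically plausible patient targets and centerline.

    Heart rate is drawn uniformly on 60-100 beats/min, systolic pressure on
    90-130 mmHg, diastolic on 50-85 mmHg (re-drawn until at least 10 mmHg
    below systolic), body surface area on 0.6-1.6 m^2 with stroke volume
    scaled to it (stroke volume index 35-45 mL/m^2), and the coronary flow
    fraction on 0.03-0.05 of cardiac output.
    """
    rng = np.random.default_rng(seed)
    hr = rng.uniform(60.0, 100.0)
    sbp = rng.uniform(90.0, 130.0)
    dbp = rng.uniform(50.0, 85.0)
    while sbp - dbp < 10.0:
        dbp = rng.uniform(50.0, 85.0)
    bsa = rng.uniform(0.6, 1.6)
    sv = rng.uniform(35.0, 45.0) * bsa
    cff = rng.uniform(0.03, 0.05)
    targets = ClinicalTargets(
        heart_rate=hr,
        systolic_pressure=sbp,
        diastolic_pressure=dbp,
        stroke_volume=sv,
        body_surface_area=bsa,
        coronary_flow_fraction=cff,
    )
    centerline = generate_centerline(seed=seed)
    return targets, centerline


def table1_cohort(
    baseline_diameter: float = DEFAULT_BASELINE_DIAMETER_MM,
    s_start: float = DEFAULT_S_START_CM,
    seed: int = 0,
    targets: ClinicalTargets | None = None,
) -> CohortSpec:
    """The built-in fixed-D_max virtual cohort plus an unmorphed control.

    Four morph cases — (a.1: 8/20 mm), (a.2: 8/40 mm), (b.1: 7/40 mm),
    (b.2: 7/80 mm) — and a control tube at the baseline diameter, all sharing
    one centerline and one set of clinical targets (so every hemodynamic
    difference between cases is purely geometric).  Deterministic per seed.
    """
    max_len_cm = max(L for _, _, L in COHORT_CASES) / 10.0
    length_cm = s_start + max_len_cm + RUNOUT_CM
    if targets is None:
        targets, _ = generate_patient(seed)
    centerline = generate_centerline(length_cm=length_cm, seed=seed)
    specs = [
        AneurysmSpec(
            d_max=d, length=L, s_start=s_start,
            baseline_diameter=baseline_diameter, case_id=cid,
        )
        for cid, d, L in COHORT_CASES
    ]
    # the control is a degenerate morph: d_max = baseline => uniform tube
    specs.append(
        AneurysmSpec(
            d_max=baseline_diameter,
            length=max_len_cm * 10.0,
            s_start=s_start,
            baseline_diameter=baseline_diameter,
            case_id=CONTROL_CASE_ID,
        )
    )
    return CohortSpec(
        specs=tuple(specs),
        baseline_diameter=baseline_diameter,
        targets=targets,
        centerline=centerline,
        seed=seed,
    )


def fixture_flow_waveform(
    shape: str,
    params: dict | None = None,
    seed: int | None = None,
    period: float = 0.8,
    n: int = 512,
) -> tuple[np.ndarray, np.ndarray]:
    """One-cycle flow waveform fixtures for exercising the shear metrics.

    Shapes
    ------
    ``constant``
        ``q0`` everywhere (default 1.0 mL/s).
    ``sinusoid``
        ``mean + amp * sin(2 pi t / T + phase)``.
    ``biphasic-coronary``
        Two smooth half-sine lobes: a systolic lobe of peak ``q_sys`` over the
        first ``sys_frac`` of the cycle and a larger diastolic lobe of peak
        ``q_dia`` over the remainder, so by construction the diastolic lobe
        carries more than half the cycle flux.

    Returns ``(t, q)`` on a uniform grid of ``n + 1`` samples spanning one
    period (endpoints included; q is periodic).
    """
    p = dict(params or {})
    t = np.linspace(0.0, period, n + 1)
    if shape == "constant":
        q = np.full_like(t, float(p.get("q0", 1.0)))
    elif shape == "sinusoid":
        q = p.get("mean", 0.0) + p.get("amp", 1.0) * np.sin(
            2.0 * np.pi * t / period + p.get("phase", 0.0)
        )
    elif shape == "biphasic-coronary":
        sys_frac = float(p.get("sys_frac", 0.35))
        q_sys = float(p.get("q_sys", 1.0))
        q_dia = float(p.get("q_dia", 2.5))
        if not (0.0 < sys_frac < 1.0) or q_dia <= q_sys:
            raise ValueError("biphasic-coronary needs 0 < sys_frac < 1 and q_dia > q_sys")
        ts = sys_frac * period
        q = np.where(
            t < ts,
            q_sys * np.sin(np.pi * t / ts) ** 2,
            q_dia * np.sin(np.pi * (t - ts) / (period - ts)) ** 2,
        )
    else:
        raise ValueError(f"unknown waveform shape: {shape!r}")
    return t, q
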