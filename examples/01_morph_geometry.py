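"""Morph an aneurysm onto a healthy coronary centerline and measure it.

Builds a synthetic centerline, imposes an 8 mm x 20 mm fusiform aneurysm on a
3.5 mm vessel, and prints the aspect ratio, lumen surface area and volume of
the dilated span.
"""

from caaflow import (
    AneurysmSpec,
    aspect_ratio,
    lumen_volume,
    morph_aneurysm,
    surface_area,
)
from caaflow.synthetic import generate_centerline

centerline = generate_centerline(length_cm=10.5, seed=0)
spec = AneurysmSpec(d_max=8.0, length=20.0, s_start=1.0,
                    baseline_diameter=3.5, case_id="demo")
geom = morph_aneurysm(centerline, spec)

s0, s1 = geom.aneurysm_span
print(f"aspect ratio (length / D_max): {aspect_ratio(spec):.2f}")
print(f"max radius at span midpoint:   {geom.radius([(s0 + s1) / 2])[0]:.3f} cm")
print(f"aneurysm surface area:         {surface_area(geom, s0, s1):.3f} cm^2")
print(f"aneurysm lumen volume:         {lumen_volume(geom, s0, s1):.3f} cm^3")
# The aspect ratio is the shape parameter the cohort study varies; area and
# volume are the denominators of the low-WSS and residence-time metrics.
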