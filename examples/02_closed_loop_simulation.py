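"""Tune the closed-loop circulation to clinical targets and inspect waveforms.

Tunes the lumped-parameter network to a 120/80 mmHg, 70 mL stroke-volume
patient whose coronary bed draws 4% of cardiac output, then reports how well
the converged simulation matches the targets and how the intramyocardial
pressure shifts coronary perfusion into diastole.
"""

from dataclasses import replace

import numpy as np

from caaflow import ClinicalTargets, diastolic_flow_fraction, simulate, tune

targets = ClinicalTargets(
    heart_rate=75.0,
    systolic_pressure=120.0,
    diastolic_pressure=80.0,
    stroke_volume=70.0,
    body_surface_area=1.8,
    coronary_flow_fraction=0.04,
)

params = tune(targets)
wf = simulate(params, targets.heart_rate)

p_ao = wf["aortic_pressure"]
v = wf["ventricular_volume"]
q_cor = wf["coronary_flow"]
print(f"converged in {wf.n_cycles_run} cycles: {wf.converged}")
print(f"aortic pressure:   {p_ao.max():6.1f} / {p_ao.min():5.1f} mmHg "
      f"(target {targets.systolic_pressure:.0f}/{targets.diastolic_pressure:.0f})")
print(f"stroke volume:     {v.max() - v.min():6.1f} mL (target {targets.stroke_volume:.0f})")
print(f"mean coronary flow:{np.trapezoid(q_cor, wf.time) / wf.period:6.2f} mL/s")

frac_on = diastolic_flow_fraction(wf)
wf_off = simulate(replace(params, gamma=1e-12), targets.heart_rate)
print(f"diastolic share of coronary flux: {100 * frac_on:.1f}% "
      f"(vs {100 * diastolic_flow_fraction(wf_off):.1f}% without "
      f"intramyocardial coupling)")
# Left coronary flow is diastolic-dominant because myocardial contraction
# squeezes the intramural vessels during systole; removing that coupling
# (gamma -> 0) visibly lowers the diastolic share.
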