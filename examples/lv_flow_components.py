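"""Separate the end-diastolic LV blood pool into four flow components.

Builds the synthetic LV phantom (EDV 179 mL, EF 0.42, HR 61 bpm), traces
one pathline per end-diastolic voxel backward and forward to the adjacent
end systoles, runs quality control, and prints the component volumes,
their end-diastolic kinetic energy densities, and the early/late (E/A)
split of direct flow.
"""

import numpy as np

from cardioquant import analyze_components, qc_pathlines, trace_cycle
from cardioquant.phantoms import make_lv_phantom

field, geom, truth = make_lv_phantom()
pathlines = trace_cycle(field, geom)
pathlines, qc = qc_pathlines(pathlines, geom)
print(f"{qc['n_total']} pathlines traced; QC invalid fraction "
      f"{qc['fraction']:.3f} -> {qc['verdict']}")

result = analyze_components(pathlines, geom)
print(f"\nEDV {result.edv:.1f} mL  |  inflow {result.inflow:.1f} mL  |  "
      f"ejected {result.ejected:.1f} mL")
for comp, vol in result.volumes.items():
    ke = result.ke_timeseries.get(comp)
    if ke is None:
        print(f"  {comp:18s} {vol:6.1f} mL   (no pathlines, no KE)")
        continue
    j = int(np.argmax(ke))
    print(f"  {comp:18s} {vol:6.1f} mL   peak KE {ke[j] / vol:6.2f} uJ/mL "
          f"at t = {result.times_ms[j]:+7.1f} ms")
# The phantom's inflow ends exactly at end diastole, so KE at the ED frame
# itself is ~0; the peaks sit in the E wave (negative t, diastole) and in
# systolic ejection (positive t).

split = result.direct_flow_split
print(f"\ndirect flow entering early (E wave): {split['early']:.1f} mL, "
      f"late (A wave): {split['late']:.1f} mL")
recovery = np.mean([a == b for a, b in zip(pathlines.components, truth.components)])
print(f"component labels agree with the fine-step reference integrator for "
      f"{100 * recovery:.1f}% of pathlines")
# Direct flow is blood that both enters and leaves the LV within one cycle;
# residual volume recirculates for more than a cycle. On a periodic phantom
# inflow and ejected volumes must match, mirroring conservation in vivo.
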