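# cardioquant

Quantitative cardiac MRI analysis for two complementary questions about a
failing-but-compensated left ventricle: *where does the blood in the LV go
over one heart beat?* (4D flow MRI pathline analysis) and *how well is the
myocardium itself perfused?* (FAIR arterial spin labelling). The package is
aimed at cardiac-imaging methods researchers who want a tested, reusable
implementation of both analyses, driven by synthetic phantoms with known
ground truth in place of patient scans.

## What it computes

**LV flow components.** One pathline is seeded at the centre of every voxel
of the end-diastolic LV segmentation and traced backward and forward
through the time-resolved velocity field to the two adjacent end systoles
(fixed-step RK4, trilinear/linear interpolation). Its position relative to
the end-systolic segmentations assigns one of four functional components:

| entered during diastole | ejected during systole | component |
|---|---|---|
| yes | yes | direct flow |
| yes | no  | retained inflow |
| no  | yes | delayed ejection |
| no  | no  | residual volume |

Each pathline carries one voxel of blood, so component volumes are exact
partitions of the EDV; kinetic energy is KE = ½ ρ V v² (ρ = 1060 kg/m³),
summed per component and normalised per mL. Direct flow is further split
into early (E-wave) and late (A-wave) entry at mid-diastole, detected as
the diastolic frame with the fewest mitral-plane crossings (diastasis).
Quality control flags pathlines that cross the blood-pool surface anywhere
but the mitral or aortic orifice.

**Myocardial blood flow.** From six FAIR control/tag pairs, MBF follows the
single-TI form of Buxton's general kinetic model,

    MBF = λ (C − T) / (2 M0 · TI · e^(−TI/T1)) · 60000   [ml/g/min]

with TI equal to the R-R interval, T1 = 1650 ms, λ = 1 ml/g. The myocardium
is resampled to polar angle bins and smoothed with a wrapped angular
boxcar: one segment/2π filter (global), six segments/π/3 (regional), three
segments/2π/3 over the septal half (septal). The temporal noise of the
global estimate splits in quadrature into thermal noise (propagated from
signal-free noise images) and physiological noise (the motion-driven
remainder) — the quantity that parallel-imaging acceleration (SENSE 2,
halving the 307 ms acquisition window to 153 ms) is expected to suppress.

Both pipelines run on synthetic data generators that are first-class,
tested parts of the package: a deforming half-ellipsoid LV with
potential-flow interior and prescribed E/A filling (plus analytic duct and
rigid-rotation phantoms), and an ASL forward model that inverts exactly in
the noise-free case. See `docs/methods.md` for the models and their
assumptions.

## Worked example

`python examples/lv_flow_components.py` builds the default phantom
(EDV 179 mL, EF 0.42, HR 61 bpm, 3 mm voxels, 30 frames) and prints:

```
6629 pathlines traced; QC invalid fraction 0.000 -> PASS

EDV 179.0 mL  |  inflow 77.3 mL  |  ejected 77.3 mL
  direct               44.1 mL   peak KE  44.09 uJ/mL at t =  -393.4 ms
  retained_inflow      33.2 mL   peak KE  54.24 uJ/mL at t =  -393.4 ms
  delayed_ejection     33.2 mL   peak KE  54.24 uJ/mL at t =  +393.4 ms
  residual             68.5 mL   peak KE   7.40 uJ/mL at t =  +393.4 ms

direct flow entering early (E wave): 25.0 mL, late (A wave): 19.1 mL
component labels agree with the fine-step reference integrator for 100.0% of pathlines
```

The four component volumes partition the 179 mL EDV exactly; inflow and
ejected volume agree (the conservation a periodic beat must satisfy), and
the KE peaks sit in the E wave (negative times = diastole) and in ejection.
`examples/asl_mbf_quantification.py`, `examples/protocol_timing.py` and
`examples/cohort_summary.py` walk through the perfusion side the same way;
a thin CLI (`cardioquant --help`) wraps the same stages for shell use.

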