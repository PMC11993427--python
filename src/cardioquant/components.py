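"""Separation of the end-diastolic blood pool into four functional flow
components, with kinetic-energy accounting.

A pathline's component is determined purely by where it is at the two
adjacent end systoles, relative to the ES segmentations:

======================  =====================  ==================
outside at prev ES       outside at next ES     component
(entered in diastole)    (ejected in systole)
======================  =====================  ==================
yes                      yes                    direct
yes                      no                     retained_inflow
no                       yes                    delayed_ejection
no                       no                     residual
======================  =====================  ==================

Kinetic energy of a pathline at a timepoint is KE = 1/2 * rho * V * |v|^2
with rho the blood density, V the represented volume and v the sampled
velocity; component KE is the sum over its pathlines, and is additionally
normalised by the component's volume (KE/mL).  Direct flow is split into
early- and late-diastolic inflow at mid-diastole, detected as the diastolic
frame with the fewest pathline crossings of the mitral valve plane
(diastasis).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    COMPONENTS,
    BloodConstants,
    ComponentResult,
    DELAYED,
    DIRECT,
    LVGeometry,
    Pathline,
    PathlineSet,
    RESIDUAL,
    RETAINED,
)

__all__ = [
    "KERecord",
    "classify_pathline",
    "classify_pathlines",
    "component_volumes",
    "pathline_ke",
    "component_ke_timeseries",
    "find_mid_diastole",
    "split_direct_flow",
    "analyze_components",
]


@dataclass(frozen=True)
class KERecord:
    """Kinetic energy of one flow component at one timepoint."""

    component: str
    t: float  # ms
    ke_total: float  # uJ
    ke_per_ml: float  # uJ/mL

    def __post_init__(self) -> None:
        if self.ke_total < 0:
            raise ValueError("kinetic energy cannot be negative")


def _label_from_membership(inside_prev: bool, inside_next: bool) -> str:
    if not inside_prev and not inside_next:
        return DIRECT
    if not inside_prev and inside_next:
        return RETAINED
    if inside_prev and not inside_next:
        return DELAYED
    return RESIDUAL


def classify_pathline(p: Pathline, geom: LVGeometry):
    """Component of a single traced pathline (None if QC-invalid)."""
    if p.qc_status != "valid":
        return None
    inside_prev = bool(geom.points_in_mask(p.positions[0], geom.es_mask_prev)[0])
    inside_next = bool(geom.points_in_mask(p.positions[-1], geom.es_mask_next)[0])
    return _label_from_membership(inside_prev, inside_next)


def classify_pathlines(pathlines: PathlineSet, geom: LVGeometry) -> PathlineSet:
    """Assign a component to every QC-valid pathline (vectorised).

    Membership at each ES is evaluated against the corresponding ES mask
    with voxel-centre containment at the recorded ES position (the first
    and last samples of the shared time axis).
    """
    inside_prev = geom.points_in_mask(pathlines.positions[:, 0], geom.es_mask_prev)
    inside_next = geom.points_in_mask(pathlines.positions[:, -1], geom.es_mask_next)
    for i in range(len(pathlines)):
        if pathlines.qc_status[i] == "valid":
            pathlines.components[i] = _label_from_membership(
                bool(inside_prev[i]), bool(inside_next[i])
            )
        else:
            pathlines.components[i] = None
    return pathlines


def component_volumes(pathlines: PathlineSet) -> dict:
    """Volume (mL) per component plus the derived stroke volumes.

    Returns a dict with the four component volumes and ``edv`` (sum over
    classified pathlines), ``inflow`` (direct + retained_inflow) and
    ``ejected`` (direct + delayed_ejection).
    """
    if not any(c is not None for c in pathlines.components):
        raise ValueError("no classified pathlines; run classify_pathlines first")
    volumes = {}
    for comp in COMPONENTS:
        sel = pathlines.components == comp
        volumes[comp] = float(pathlines.volumes_mm3[sel].sum()) / 1000.0
    volumes["edv"] = sum(volumes[c] for c in COMPONENTS)
    volumes["inflow"] = volumes[DIRECT] + volumes[RETAINED]
    volumes["ejected"] = volumes[DIRECT] + volumes[DELAYED]
    return volumes


def pathline_ke(
    p: Pathline, t: float, constants: BloodConstants = BloodConstants()
) -> float:
    """Kinetic energy of one pathline at a recorded frame time, in uJ.

    KE = 1/2 * rho * V * |v|^2 with V in m^3 and v in m/s; for V in mm^3
    this reduces to ``0.5e-3 * rho * V_mm3 * |v|^2`` microjoules.
    """
    j = np.nonzero(np.isclose(p.times_ms, t, atol=1e-6))[0]
    if len(j) == 0:
        raise ValueError(f"t = {t} ms is not a recorded frame time of this pathline")
    v2 = float(np.sum(p.velocities[j[0]] ** 2))
    return 0.5e-3 * constants.rho * p.volume_mm3 * v2


def component_ke_timeseries(
    pathlines: PathlineSet, constants: BloodConstants = BloodConstants()
):
    """KE per component per recorded timepoint.

    Returns ``(records, ke_by_component)`` where ``records`` is a flat list
    of :class:`KERecord` and ``ke_by_component`` maps component name to a
    (K,) array of total KE in uJ.  Components with no pathlines are absent
    from both (no 0/0 normalisation).
    """
    v2 = np.sum(pathlines.velocities**2, axis=2)  # (N, K), (m/s)^2
    ke_per_pathline = 0.5e-3 * constants.rho * pathlines.volumes_mm3[:, None] * v2
    records = []
    ke_by_component = {}
    for comp in COMPONENTS:
        sel = pathlines.components == comp
        if not sel.any():
            continue
        ke = ke_per_pathline[sel].sum(axis=0)
        vol_ml = float(pathlines.volumes_mm3[sel].sum()) / 1000.0
        ke_by_component[comp] = ke
        for t, k in zip(pathlines.times_ms, ke):
            records.append(
                KERecord(component=comp, t=float(t), ke_total=float(k),
                         ke_per_ml=float(k) / vol_ml)
            )
    return records, ke_by_component


def _diastolic_intervals(times_ms: np.ndarray):
    """Indices j of frame intervals [t_j, t_{j+1}] within diastole (t <= 0).

    The shared pathline time axis runs from the preceding ES (negative
    times) through ED at t = 0; diastole is that negative-time span.
    """
    return [
        j
        for j in range(len(times_ms) - 1)
        if times_ms[j] < 1e-9 and times_ms[j + 1] <= 1e-9
    ]


def _mitral_crossing_times(pathlines: PathlineSet) -> list:
    """First diastolic mitral-plane crossing time per pathline (or None)."""
    out = []
    for i in range(len(pathlines)):
        t_hit = None
        for t, _p, lab in pathlines.crossings[i]:
            if lab == "mitral_orifice" and t <= 1e-9:
                t_hit = t if t_hit is None else min(t_hit, t)
        out.append(t_hit)
    return out


def find_mid_diastole(pathlines: PathlineSet, geom: LVGeometry) -> int:
    """Diastolic frame with the fewest mitral-plane pathline crossings.

    This is the diastasis detector: inflow pauses between the E and A
    waves, so the frame interval with the minimum number of mitral
    crossings marks mid-diastole.  Ties break toward the earlier frame.
    Returns an index j into the shared time axis; the interval
    ``[times_ms[j], times_ms[j+1]]`` is the detected frame.
    """
    intervals = _diastolic_intervals(pathlines.times_ms)
    if len(intervals) < 3:
        raise ValueError(
            f"only {len(intervals)} diastolic frames; mid-diastole detection "
            "needs at least 3"
        )
    times = pathlines.times_ms
    counts = np.zeros(len(intervals), dtype=int)
    for t_hit in _mitral_crossing_times(pathlines):
        if t_hit is None:
            continue
        for c, j in enumerate(intervals):
            if times[j] <= t_hit < times[j + 1]:
                counts[c] += 1
                break
    best = int(np.argmin(counts))  # argmin takes the first minimum: earlier frame
    return intervals[best]


def split_direct_flow(
    pathlines: PathlineSet, mid: int, geom: LVGeometry = None
) -> dict:
    """Split direct flow (and retained inflow) into early/late diastolic entry.

    Inflow pathlines crossing the mitral plane before the mid-diastole
    frame are labelled ``early`` (E wave), the rest ``late`` (A wave); the
    same mid-diastole frame is used for both inflow components.  Returns
    the direct-flow split ``{"early": mL, "late": mL}`` plus the early/late
    ratios to total inflow, which by construction sum to the direct-flow
    fraction of inflow.
    """
    t_mid = float(pathlines.times_ms[mid])
    crossing_times = _mitral_crossing_times(pathlines)
    early_ml = late_ml = 0.0
    inflow_ml = 0.0
    n_fallback = 0
    for i in range(len(pathlines)):
        comp = pathlines.components[i]
        if comp not in (DIRECT, RETAINED):
            if pathlines.components[i] is not None:
                pathlines.inflow_phase[i] = "none"
            continue
        inflow_ml += pathlines.volumes_mm3[i] / 1000.0
        t_hit = crossing_times[i]
        if t_hit is None:
            t_hit = _first_entry_time(pathlines, i, geom)
            n_fallback += 1
        phase = "early" if t_hit < t_mid else "late"
        pathlines.inflow_phase[i] = phase
        if comp == DIRECT:
            if phase == "early":
                early_ml += pathlines.volumes_mm3[i] / 1000.0
            else:
                late_ml += pathlines.volumes_mm3[i] / 1000.0
    if n_fallback:
        warnings.warn(
            f"{n_fallback} inflow pathlines have no recorded mitral crossing "
            "(wall-adjacent blood at mask resolution); phased by their first "
            "entry frame into the LV mask",
            stacklevel=2,
        )
    return {
        "early": early_ml,
        "late": late_ml,
        "early_over_inflow": early_ml / inflow_ml if inflow_ml else 0.0,
        "late_over_inflow": late_ml / inflow_ml if inflow_ml else 0.0,
    }


def _first_entry_time(pathlines: PathlineSet, i: int, geom: LVGeometry) -> float:
    """Fallback entry time: first diastolic frame inside the ED blood pool."""
    if geom is None:
        return -np.inf
    times = pathlines.times_ms
    dia = times <= 1e-9
    inside = geom.points_in_mask(pathlines.positions[i][dia], geom.ed_mask)
    hits = np.nonzero(inside)[0]
    return float(times[dia][hits[0]]) if len(hits) else -np.inf


def analyze_components(
    pathlines: PathlineSet,
    geom: LVGeometry,
    constants: BloodConstants = BloodConstants(),
) -> ComponentResult:
    """Full component analysis of a traced, QC'ed pathline set.

    Classifies, accumulates volumes and KE time series, detects
    mid-diastole and splits direct flow into E/A entry.  The reported EDV
    is the summed volume of the classified (QC-valid) pathlines.
    """
    classify_pathlines(pathlines, geom)
    volumes = component_volumes(pathlines)
    records, ke_by_comp = component_ke_timeseries(pathlines, constants)
    ed = pathlines.ed_index()
    ke_per_ml_at_ed = {}
    for comp, ke in ke_by_comp.items():
        if volumes[comp] > 0:
            ke_per_ml_at_ed[comp] = float(ke[ed]) / volumes[comp]
    mid = find_mid_diastole(pathlines, geom)
    split = split_direct_flow(pathlines, mid, geom)
    result = ComponentResult(
        volumes={c: volumes[c] for c in COMPONENTS},
        ke_timeseries=ke_by_comp,
        ke_per_ml_at_ed=ke_per_ml_at_ed,
        direct_flow_split={"early": split["early"], "late": split["late"]},
        edv=volumes["edv"],
        inflow=volumes["inflow"],
        ejected=volumes["ejected"],
        times_ms=pathlines.times_ms.copy(),
        mid_diastole_frame=mid,
    )
    voxel_ml = float(np.max(pathlines.volumes_mm3)) / 1000.0
    result.validate(voxel_volume_ml=voxel_ml)
    return result
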