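"""Pathline seeding, integration and quality control.

Pathlines are the trajectories of imagined massless particles advected
through the time-resolved velocity field.  One pathline is seeded at the
centre of every voxel of the end-diastolic LV segmentation, represents one
voxel of blood volume, and is traced backward to the preceding end systole
and forward to the following end systole.  Integration is fixed-step
classical RK4 with trilinear spatial and linear temporal velocity
interpolation; steps never straddle a frame boundary (the interpolated
field is only C0 there).

Quality control follows the principle that blood can only cross the
blood-pool surface through the mitral or aortic orifice: a pathline whose
trajectory crosses the ED blood-pool surface through a wall-labelled region
indicates corrupted data and is flagged ``exited_wall``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    LVGeometry,
    Pathline,
    PathlineSet,
    QC_EXITED_WALL,
    QC_LEFT_FOV,
    QC_VALID,
    VelocityField4D,
)

__all__ = [
    "TraceConfig",
    "sample_velocity",
    "seed_pathlines",
    "integrate_pathline",
    "trace_cycle",
    "qc_pathlines",
    "resample_mask",
]


@dataclass(frozen=True)
class TraceConfig:
    """Numerical settings for pathline tracing.

    ``substeps_per_frame`` RK4 steps are taken per frame interval
    (default 4).  A dataset is flagged FAIL when more than
    ``qc_invalid_fraction_max`` of its pathlines are QC-invalid; the
    threshold is this package's choice, exposed here because no standard
    value exists.
    """

    substeps_per_frame: int = 4
    qc_invalid_fraction_max: float = 0.05
    interpolation: str = "trilinear-space, linear-time"

    def __post_init__(self) -> None:
        if self.substeps_per_frame < 1:
            raise ValueError("substeps_per_frame must be >= 1")


# ---------------------------------------------------------------------------
# field sampling


def _frame_bracket(field: VelocityField4D, t_ms: float):
    """Frame pair (k, k_next) and interpolation weight for time ``t_ms``.

    Periodic fields wrap (the interval after the last frame leads back to
    the first); non-periodic fields require t within the sampled span.
    """
    ft = field.frame_times
    n = field.n_frames
    if field.periodic:
        T = field.cycle_length
        tau = (t_ms - ft[0]) % T + ft[0]
        k = int(np.searchsorted(ft, tau, side="right")) - 1
        k = max(k, 0)
        if k == n - 1:
            dt = T - ft[-1] + ft[0]
            alpha = (tau - ft[-1]) / dt
            return n - 1, 0, alpha
        alpha = (tau - ft[k]) / (ft[k + 1] - ft[k])
        return k, k + 1, alpha
    if t_ms < ft[0] - 1e-9 or t_ms > ft[-1] + 1e-9:
        raise ValueError(
            f"time {t_ms} ms outside the sampled span "
            f"[{ft[0]}, {ft[-1]}] of a non-periodic field"
        )
    tau = min(max(t_ms, ft[0]), ft[-1])
    k = int(np.searchsorted(ft, tau, side="right")) - 1
    k = min(max(k, 0), n - 2)
    alpha = (tau - ft[k]) / (ft[k + 1] - ft[k])
    return k, k + 1, alpha


def sample_velocity(
    field: VelocityField4D, points_mm: np.ndarray, t_ms: float
) -> np.ndarray:
    """Velocity (m/s) at physical points, trilinear in space, linear in time.

    Points outside the grid sample zero velocity (the caller is responsible
    for flagging them as having left the field of view).
    """
    pts = np.atleast_2d(np.asarray(points_mm, dtype=np.float64))
    k0, k1, alpha = _frame_bracket(field, t_ms)
    idx = ((pts - field.origin_mm) / field.spacing).T  # (3, N)
    out = np.empty((pts.shape[0], 3))
    v0 = field.velocities[k0]
    v1 = field.velocities[k1]
    for c in range(3):
        a = ndimage.map_coordinates(v0[..., c], idx, order=1, mode="constant", cval=0.0)
        if alpha > 0.0:
            b = ndimage.map_coordinates(
                v1[..., c], idx, order=1, mode="constant", cval=0.0
            )
            out[:, c] = (1.0 - alpha) * a + alpha * b
        else:
            out[:, c] = a
    return out


def _outside_fov(field: VelocityField4D, pts: np.ndarray) -> np.ndarray:
    # the field is defined by interpolation between voxel centres; beyond
    # the centre hull there is no velocity data, so that is the FOV bound
    lo = field.origin_mm
    hi = field.origin_mm + (np.asarray(field.grid_shape) - 1) * field.spacing
    return np.any((pts < lo) | (pts > hi), axis=1)


def _rk4_step(field, pts, t, dt):
    """One classical RK4 step; velocities in m/s equal mm/ms numerically."""
    k1 = sample_velocity(field, pts, t)
    k2 = sample_velocity(field, pts + 0.5 * dt * k1, t + 0.5 * dt)
    k3 = sample_velocity(field, pts + 0.5 * dt * k2, t + 0.5 * dt)
    k4 = sample_velocity(field, pts + dt * k3, t + dt)
    return pts + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


# ---------------------------------------------------------------------------
# seeding


def seed_pathlines(geom: LVGeometry, field: VelocityField4D):
    """One seed per ED voxel centre; each represents one voxel of blood.

    Returns ``(seeds_mm, volumes_mm3)``.  The total represented volume is
    the EDV by construction, and volumes are never rescaled afterwards.
    """
    if geom.ed_mask.shape != field.grid_shape:
        raise ValueError(
            "ED mask grid does not match the velocity field; resample the "
            "segmentation to the flow grid first (see resample_mask)"
        )
    idx = np.argwhere(geom.ed_mask)
    if len(idx) == 0:
        raise ValueError("ED mask is empty; nothing to seed")
    seeds = geom.origin_mm + idx * geom.spacing
    volumes = np.full(len(idx), geom.spacing**3)
    return seeds.astype(np.float64), volumes


def resample_mask(
    mask: np.ndarray,
    src_spacing,
    src_origin,
    dst_spacing: float,
    dst_shape,
    dst_origin,
) -> np.ndarray:
    """Nearest-neighbour resampling of a binary mask onto an isotropic grid.

    Each destination voxel centre is tested for membership of the source
    voxel that contains it.  Used to bring a (possibly anisotropic)
    segmentation onto the flow-data grid before seeding.
    """
    src_spacing = np.asarray(src_spacing, dtype=float)
    src_origin = np.asarray(src_origin, dtype=float)
    dst_origin = np.asarray(dst_origin, dtype=float)
    grids = np.meshgrid(*[np.arange(s) for s in dst_shape], indexing="ij")
    pts = np.stack([g.ravel() for g in grids], axis=1) * dst_spacing + dst_origin
    idx = np.rint((pts - src_origin) / src_spacing).astype(np.int64)
    ok = np.all((idx >= 0) & (idx < np.asarray(mask.shape)), axis=1)
    out = np.zeros(len(pts), dtype=bool)
    sel = idx[ok]
    out[ok] = mask[sel[:, 0], sel[:, 1], sel[:, 2]]
    return out.reshape(tuple(dst_shape))


# ---------------------------------------------------------------------------
# integration


def _bisect_crossing(geom, a, b, inside_a, iters=25):
    """Locate mask-surface crossings on segments a->b (vectorised bisection)."""
    lo = a.copy()
    hi = b.copy()
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        ins_mid = geom.points_in_mask(mid, geom.ed_mask)
        same_as_a = ins_mid == inside_a
        lo[same_as_a] = mid[same_as_a]
        hi[~same_as_a] = mid[~same_as_a]
    return 0.5 * (lo + hi)


def _advance(
    field: VelocityField4D,
    seeds: np.ndarray,
    record_times: np.ndarray,
    substeps: int,
    geom: LVGeometry = None,
):
    """March all particles through consecutive frame times, recording each.

    ``record_times`` is a monotone (increasing or decreasing) sequence of
    times starting at the seeds' time.  Returns recorded positions
    (N, K, 3), the left-FOV flag per particle, and per-particle crossing
    events ``(t_ms, point_mm, label)`` against the ED blood-pool surface.
    """
    pts = seeds.astype(np.float64).copy()
    n = len(pts)
    recorded = np.empty((n, len(record_times), 3))
    recorded[:, 0] = pts
    active = ~_outside_fov(field, pts)
    left_fov = ~active
    crossings = [[] for _ in range(n)]
    inside = (
        geom.points_in_mask(pts, geom.ed_mask)
        if geom is not None
        else np.zeros(n, dtype=bool)
    )
    for j in range(len(record_times) - 1):
        ta, tb = record_times[j], record_times[j + 1]
        dt = (tb - ta) / substeps
        for s in range(substeps):
            t = ta + s * dt
            prev = pts.copy()
            stepped = _rk4_step(field, pts, t, dt)
            pts[active] = stepped[active]
            out = _outside_fov(field, pts)
            newly_out = out & active
            if newly_out.any():
                pts[newly_out] = prev[newly_out]  # freeze at last valid position
                left_fov |= newly_out
                active &= ~newly_out
            if geom is not None:
                ins_new = geom.points_in_mask(pts, geom.ed_mask)
                flipped = (ins_new != inside) & active
                if flipped.any():
                    cross_pts = _bisect_crossing(
                        geom, prev[flipped], pts[flipped], inside[flipped]
                    )
                    labels = geom.classify_crossing(cross_pts)
                    t_cross = t + 0.5 * dt
                    for i, p, lab in zip(np.nonzero(flipped)[0], cross_pts, labels):
                        crossings[i].append((float(t_cross), p.copy(), str(lab)))
                inside = ins_new
        recorded[:, j + 1] = pts
    return recorded, left_fov, crossings


def _record_velocities(field, recorded, record_times):
    vel = np.empty_like(recorded)
    for j, t in enumerate(record_times):
        vel[:, j] = sample_velocity(field, recorded[:, j], t)
    return vel


def integrate_pathline(
    field: VelocityField4D,
    seed_mm,
    t_start: float,
    t_end: float,
    config: TraceConfig = TraceConfig(),
    volume_mm3: float = None,
) -> Pathline:
    """Trace a single seed from ``t_start`` to ``t_end`` (either direction).

    Positions are recorded at every frame time passed, plus the endpoints.
    RK4 is exact (to machine precision) for spatially and temporally
    uniform fields.
    """
    seed = np.asarray(seed_mm, dtype=float).reshape(1, 3)
    if _outside_fov(field, seed)[0]:
        raise ValueError(f"seed {seed_mm} lies outside the field domain")
    if t_end == t_start:
        raise ValueError("t_end must differ from t_start")
    span = abs(t_end - t_start)
    if span > field.cycle_length + 1e-9:
        raise ValueError("trace span exceeds one cardiac cycle")
    record_times = _frame_time_path(field, t_start, t_end)
    recorded, left_fov, crossings = _advance(
        field, seed, record_times, config.substeps_per_frame
    )
    vel = _record_velocities(field, recorded, record_times)
    return Pathline(
        positions=recorded[0],
        velocities=vel[0],
        times_ms=record_times,
        volume_mm3=volume_mm3 if volume_mm3 is not None else field.spacing**3,
        qc_status=QC_LEFT_FOV if left_fov[0] else QC_VALID,
        crossings=crossings[0],
    )


def _frame_time_path(field: VelocityField4D, t_start: float, t_end: float):
    """Frame times strictly between t_start and t_end, plus the endpoints.

    For periodic fields, times may run outside [0, cycle_length); they are
    mapped into the cycle when the field is sampled.
    """
    T = field.cycle_length
    ft = field.frame_times
    direction = 1.0 if t_end > t_start else -1.0
    if field.periodic:
        # all frame times of the unrolled (periodic) timeline within the span
        all_times = np.concatenate([ft + kk * T for kk in (-1, 0, 1)])
    else:
        all_times = ft
    lo, hi = min(t_start, t_end), max(t_start, t_end)
    inner = all_times[(all_times > lo + 1e-9) & (all_times < hi - 1e-9)]
    times = np.concatenate([[lo], np.sort(inner), [hi]])
    if direction < 0:
        times = times[::-1]
    return times


def trace_cycle(
    field: VelocityField4D, geom: LVGeometry, config: TraceConfig = TraceConfig()
) -> PathlineSet:
    """Trace every ED seed backward to the preceding and forward to the
    following end systole, covering the full end-diastolic volume.

    The returned set shares one time axis running from the preceding ES
    (negative times, the previous cycle's diastole) through ED (t = 0 by
    convention of the ED frame) to the following ES.  Surface-crossing
    events against the ED blood pool are recorded at substep resolution for
    quality control and inflow-phase timing.
    """
    if field.n_frames < 2:
        raise ValueError("pathline tracing needs at least 2 frames")
    if geom.es_frame_prev is None or geom.es_frame_next is None:
        raise ValueError("geometry must identify both adjacent ES frames")
    seeds, volumes = seed_pathlines(geom, field)
    t_ed = float(field.frame_times[geom.ed_frame])
    t_es_next = float(field.frame_times[geom.es_frame_next])
    if field.periodic:
        t_es_prev = float(field.frame_times[geom.es_frame_prev]) - field.cycle_length
    else:
        t_es_prev = float(field.frame_times[geom.es_frame_prev])
        if t_es_prev >= t_ed:
            raise ValueError("preceding ES must come before ED for measured data")
    if not t_es_next > t_ed:
        raise ValueError("following ES must come after ED")

    fwd_times = _frame_time_path(field, t_ed, t_es_next)
    bwd_times = _frame_time_path(field, t_ed, t_es_prev)
    rec_f, lf_f, cross_f = _advance(
        field, seeds, fwd_times, config.substeps_per_frame, geom
    )
    rec_b, lf_b, cross_b = _advance(
        field, seeds, bwd_times, config.substeps_per_frame, geom
    )
    # stitch: backward part reversed (ES_prev .. ED), then forward (ED .. ES_next)
    times = np.concatenate([bwd_times[::-1][:-1], fwd_times])
    positions = np.concatenate([rec_b[:, ::-1][:, :-1], rec_f], axis=1)
    left_fov = lf_f | lf_b
    crossings = [
        sorted(cb + cf, key=lambda c: c[0]) for cb, cf in zip(cross_b, cross_f)
    ]
    velocities = _record_velocities(field, positions, times)
    # re-shift times so that ED is exactly t = 0
    times = times - t_ed
    qc = np.where(left_fov, QC_LEFT_FOV, QC_VALID).astype(object)
    pathlines = PathlineSet(
        positions, velocities, times, volumes, qc, crossings=crossings
    )
    # shift crossing times to the same ED-centred axis
    for cl in pathlines.crossings:
        for i, (t, p, lab) in enumerate(cl):
            cl[i] = (t - t_ed, p, lab)
    return pathlines


def qc_pathlines(
    pathlines: PathlineSet, geom: LVGeometry, config: TraceConfig = TraceConfig()
):
    """Flag pathlines that crossed the blood-pool surface through the wall.

    Real blood can only leave the LV blood pool through the mitral or
    aortic orifice; wall crossings (including through the apex) indicate
    data errors.  QC reports rather than raises: the dataset verdict is
    FAIL when the invalid fraction exceeds ``config.qc_invalid_fraction_max``.
    """
    n = len(pathlines)
    for i in range(n):
        if pathlines.qc_status[i] == QC_LEFT_FOV:
            continue
        labels = [lab for (_, _, lab) in pathlines.crossings[i]]
        if any(lab == "wall" for lab in labels):
            pathlines.qc_status[i] = QC_EXITED_WALL
            pathlines.components[i] = None
        elif pathlines.qc_status[i] == QC_EXITED_WALL:
            pathlines.qc_status[i] = QC_VALID
    n_wall = int(np.sum(pathlines.qc_status == QC_EXITED_WALL))
    n_fov = int(np.sum(pathlines.qc_status == QC_LEFT_FOV))
    fraction = (n_wall + n_fov) / n if n else 0.0
    report = {
        "n_total": n,
        "n_exited_wall": n_wall,
        "n_left_fov": n_fov,
        "n_invalid": n_wall + n_fov,
        "fraction": fraction,
        "verdict": "PASS" if fraction <= config.qc_invalid_fraction_max else "FAIL",
    }
    return pathlines, report
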