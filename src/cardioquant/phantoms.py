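"""Synthetic left-ventricular velocity fields with known ground truth.

Three phantoms stand in for patient 4D-flow scans:

* **duct** -- a box "ventricle" in a spatially and temporally uniform field;
  pathlines have the closed form x(t) = x0 + v t and component labels are
  known analytically from the seed position.
* **rotation** -- solid-body rotation about the chamber axis; pathlines are
  circles of constant radius and speed, and every pathline is residual.
* **lv** -- a half-ellipsoid chamber whose cavity volume follows a
  prescribed cycle (systolic ejection to ESV = EDV*(1-EF), biphasic
  diastolic refill with E and A waves separated by a zero-flow diastasis).
  The interior velocity is a potential-flow solution consistent with the
  moving wall, with inflow confined to the mitral disk and outflow to the
  aortic disk; the myocardial shell around the cavity carries the wall
  (tissue) velocity, as tissue voxels do in measured phase-contrast data.

The LV phantom is built with a mirror/time-reversal symmetry: the chamber
and orifice disks are mirror images in the x = 0 plane, and the diastolic
half of the cycle is the exact mirrored time-reverse of the systolic half
(so ejection is the mirror of the biphasic filling and end systole falls at
half cycle).  The phantom makes no attempt at physiologic realism beyond
the features the analysis assumes -- a closed blood pool with exactly two
orifices and a known volume curve; the symmetry makes the conservation
structure (inflow volume = ejected volume) exact by construction rather
than approximate.

Ground-truth component labels come from a fine-step reference integrator
(RK4 at 1/20 of the frame interval) on the same field; no closed form
exists for the LV interior flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, sparse
from scipy.sparse.linalg import spsolve

from .components import classify_pathlines
from .core import DIRECT, LVGeometry, OrificeDisk, PathlineSet, RETAINED, VelocityField4D
from .tracing import TraceConfig, sample_velocity, trace_cycle

__all__ = [
    "PhantomParams",
    "GroundTruth",
    "make_duct_phantom",
    "make_rotation_phantom",
    "make_lv_phantom",
    "duct_true_components",
    "disk_flux",
    "volume_curve_from_flux",
    "save_ground_truth",
]

ORACLE_SUBSTEPS = 20  # reference integrator: RK4 at 1/20 of the frame interval


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of the synthetic LV, defaulting to the emulated cohort.

    Defaults: EDV 179 mL, EF 0.42, heart rate 61 bpm, 30 frames per cycle,
    3 mm isotropic voxels, VENC 100 cm/s.  ``e_a_ratio`` splits the
    diastolic refill volume between the early (E) and atrial (A) waves
    (E volume / A volume); 1.5 is a typical transmitral inflow split.
    Chamber and orifice dimensions are free geometry knobs sized so that
    default inflow velocities stay below the VENC.
    """

    edv: float = 179.0  # mL
    ef: float = 0.42
    heart_rate: float = 61.0  # bpm
    n_frames: int = 30
    spacing: float = 3.0  # mm
    venc: float = 100.0  # cm/s
    e_a_ratio: float = 1.5
    seed: int = 0
    chamber_radius_mm: float = 33.0
    orifice_radius_mm: float = 14.0
    orifice_offset_mm: float = 16.0
    tau_e_frac: float = 0.22  # E-wave duration as a fraction of the cycle
    tau_a_frac: float = 0.18  # A-wave duration as a fraction of the cycle
    column_height_mm: float = 18.0

    def __post_init__(self) -> None:
        if not 0 < self.ef < 1:
            raise ValueError("ef must lie in (0, 1)")
        if not self.edv > 0:
            raise ValueError("edv must be > 0")
        if self.n_frames < 8:
            raise ValueError("n_frames must be >= 8")
        if self.n_frames % 2:
            raise ValueError(
                "n_frames must be even (end systole falls at half cycle)"
            )
        if not self.e_a_ratio > 0:
            raise ValueError("e_a_ratio must be > 0 (may be inf)")
        if self.tau_e_frac + self.tau_a_frac >= 0.5:
            raise ValueError("E and A waves must fit within diastole (half cycle)")

    @property
    def cycle_length_ms(self) -> float:
        return 60000.0 / self.heart_rate

    @property
    def venc_m_s(self) -> float:
        return self.venc / 100.0


@dataclass
class GroundTruth:
    """Oracle labels and prescribed quantities of a synthetic phantom."""

    seeds_mm: np.ndarray
    components: np.ndarray  # (N,) true component per seed
    inflow_phase: np.ndarray  # (N,) early | late | none
    edv_ml: float
    esv_ml: float
    stroke_volume_ml: float
    e_volume_ml: float
    a_volume_ml: float
    frame_times: np.ndarray
    volume_curve_ml: np.ndarray  # prescribed cavity volume at frame times
    diastasis_ms: tuple  # (start, end) on the ED-centred axis (negative times)
    oracle: PathlineSet = None
    oracle_substeps: int = ORACLE_SUBSTEPS


def save_ground_truth(truth: GroundTruth, path) -> None:
    """Per-seed ground-truth labels as CSV."""
    pd.DataFrame(
        {
            "seed_index": np.arange(len(truth.components)),
            "true_component": truth.components,
            "true_inflow_phase": truth.inflow_phase,
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# duct phantom


def make_duct_phantom(v: float, extent_mm: float = 30.0, params: PhantomParams = None):
    """Uniform-velocity box 'ventricle' with inlet/outlet end faces.

    The field is ``(v, 0, 0)`` m/s everywhere on the grid at all times, so
    pathlines follow x(t) = x0 + v t exactly; the box mask is the blood
    pool, its x-min face the mitral and x-max face the aortic orifice.
    End systole falls at half cycle (frame n/2).
    """
    p = params or PhantomParams()
    if abs(v) > p.venc_m_s:
        raise ValueError(f"|v| = {abs(v)} m/s exceeds VENC = {p.venc_m_s} m/s")
    h = p.spacing
    T = p.cycle_length_ms
    n = p.n_frames
    nbox = max(2, int(round(extent_mm / h)))
    pad_x = int(math.ceil(abs(v) * (T / 2.0) / h)) + 2
    nx = nbox + 2 * pad_x
    ny = nz = nbox + 2
    vel = np.zeros((n, nx, ny, nz, 3))
    vel[..., 0] = v
    frame_times = np.arange(n) * T / n
    field = VelocityField4D(
        velocities=vel,
        spacing=h,
        frame_times=frame_times,
        cycle_length=T,
        venc=p.venc_m_s,
        origin_mm=np.zeros(3),
        periodic=True,
    )
    mask = np.zeros((nx, ny, nz), dtype=bool)
    mask[pad_x : pad_x + nbox, 1 : 1 + nbox, 1 : 1 + nbox] = True
    yc = (1 + (nbox - 1) / 2.0) * h
    zc = yc
    x_lo = (pad_x - 0.5) * h
    x_hi = (pad_x + nbox - 0.5) * h
    face_radius = math.sqrt(2.0) * nbox * h / 2.0 + h
    orifices = [
        OrificeDisk("mitral_orifice", (x_lo, yc, zc), (-1.0, 0.0, 0.0), face_radius),
        OrificeDisk("aortic_orifice", (x_hi, yc, zc), (1.0, 0.0, 0.0), face_radius),
    ]
    geom = LVGeometry(
        ed_mask=mask,
        es_mask_prev=mask.copy(),
        es_mask_next=mask.copy(),
        orifices=orifices,
        spacing=h,
        origin_mm=np.zeros(3),
        ed_frame=0,
        es_frame_prev=n // 2,
        es_frame_next=n // 2,
    )
    return field, geom


def duct_true_components(field: VelocityField4D, geom: LVGeometry, v: float):
    """Closed-form component labels for the duct phantom.

    The trajectory is x(t) = x0 + v t, so membership at the adjacent end
    systoles follows directly from the displaced seed positions (using the
    same voxel-centre containment rule as the classifier).
    """
    idx = np.argwhere(geom.ed_mask)
    seeds = geom.origin_mm + idx * geom.spacing
    t_es = float(field.frame_times[geom.es_frame_next])
    T = field.cycle_length
    fwd = seeds + np.array([v * t_es, 0.0, 0.0])
    bwd = seeds - np.array([v * (T - t_es), 0.0, 0.0])
    inside_prev = geom.points_in_mask(bwd, geom.es_mask_prev)
    inside_next = geom.points_in_mask(fwd, geom.es_mask_next)
    labels = np.where(
        ~inside_prev & ~inside_next,
        "direct",
        np.where(
            ~inside_prev & inside_next,
            "retained_inflow",
            np.where(inside_prev & ~inside_next, "delayed_ejection", "residual"),
        ),
    )
    return seeds, labels.astype(object)


# ---------------------------------------------------------------------------
# rotation phantom


def make_rotation_phantom(
    omega: float,
    params: PhantomParams = None,
    radius_mm: float = 24.0,
    height_mm: float = 36.0,
    snap_revolutions: bool = True,
):
    """Solid-body rotation about the chamber (z) axis.

    ``omega`` is in rad/s.  Every traced pathline is a circle of constant
    radius and speed |v| = omega * r, and all blood is residual (nothing
    crosses the chamber surface).  The stored field is zeroed where the
    rotational speed would exceed the VENC (outside the chamber).

    By default ``omega`` is snapped to the nearest whole number of
    revolutions per half cycle (at least one), so that every particle's
    position at end systole coincides with its seed voxel centre: the
    all-residual ground truth is then decided well away from the voxelised
    rim of the mask instead of depending on containment rounding there.
    Pass ``snap_revolutions=False`` for the literal rate.
    """
    p = params or PhantomParams()
    if snap_revolutions:
        half_s = p.cycle_length_ms / 2000.0  # half cycle in seconds
        revs = max(1, int(round(abs(omega) * half_s / (2.0 * math.pi))))
        omega = math.copysign(2.0 * math.pi * revs / half_s, omega if omega else 1.0)
    v_edge = abs(omega) * radius_mm / 1000.0  # m/s at the chamber edge
    if v_edge > p.venc_m_s:
        raise ValueError(
            f"omega * r_max = {v_edge} m/s exceeds VENC = {p.venc_m_s} m/s"
        )
    h = p.spacing
    T = p.cycle_length_ms
    n = p.n_frames
    half = int(math.ceil((radius_mm + 3 * h) / h))
    nx = ny = 2 * half + 1
    nz = int(round(height_mm / h)) + 4
    cx = half * h
    cy = half * h
    cz = (nz - 1) * h / 2.0
    x = np.arange(nx) * h
    y = np.arange(ny) * h
    z = np.arange(nz) * h
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    r2 = (X - cx) ** 2 + (Y - cy) ** 2
    w = omega / 1000.0  # rad/ms, so v = w x r is in mm/ms = m/s
    vx = -w * (Y - cy)
    vy = w * (X - cx)
    speed = np.sqrt(vx**2 + vy**2)
    keep = speed <= p.venc_m_s
    one = np.zeros((nx, ny, nz, 3))
    one[..., 0] = np.where(keep, vx, 0.0)
    one[..., 1] = np.where(keep, vy, 0.0)
    vel = np.broadcast_to(one, (n, nx, ny, nz, 3)).copy()
    frame_times = np.arange(n) * T / n
    field = VelocityField4D(
        velocities=vel,
        spacing=h,
        frame_times=frame_times,
        cycle_length=T,
        venc=p.venc_m_s,
        periodic=True,
    )
    mask = (r2 <= radius_mm**2) & (np.abs(Z - cz) <= height_mm / 2.0)
    top = cz + height_mm / 2.0
    orifices = [
        OrificeDisk("mitral_orifice", (cx - radius_mm / 2.0, cy, top), (0.0, 0.0, 1.0), 2 * h),
        OrificeDisk("aortic_orifice", (cx + radius_mm / 2.0, cy, top), (0.0, 0.0, 1.0), 2 * h),
    ]
    geom = LVGeometry(
        ed_mask=mask,
        es_mask_prev=mask.copy(),
        es_mask_next=mask.copy(),
        orifices=orifices,
        spacing=h,
        ed_frame=0,
        es_frame_prev=n // 2,
        es_frame_next=n // 2,
    )
    return field, geom


# ---------------------------------------------------------------------------
# LV phantom: volume curve


def _wave_fraction(u: np.ndarray) -> np.ndarray:
    """Integral of the raised-cosine pulse: fraction of wave volume by u."""
    u = np.clip(u, 0.0, 1.0)
    return u - np.sin(2.0 * np.pi * u) / (2.0 * np.pi)


def _wave_rate(u) -> np.ndarray:
    """Raised-cosine pulse shape (integrates to 1 over u in [0, 1])."""
    u = np.asarray(u, dtype=float)
    out = np.where((u >= 0.0) & (u <= 1.0), 1.0 - np.cos(2.0 * np.pi * u), 0.0)
    return out


class _VolumeCurve:
    """Prescribed cavity volume over one cycle, mm^3 / ms.

    Diastole (t in [T/2, T]): E wave over [T/2, T/2 + tau_e], zero-flow
    diastasis, A wave over [T - tau_a, T].  Systole (t in [0, T/2]) is the
    time-mirror: V(t) = V(T - t).
    """

    def __init__(self, edv_mm3, ef, T, tau_e, tau_a, e_a_ratio):
        self.edv = edv_mm3
        self.esv = (1.0 - ef) * edv_mm3
        self.sv = ef * edv_mm3
        if math.isinf(e_a_ratio):
            self.ve, self.va = self.sv, 0.0
        else:
            self.va = self.sv / (1.0 + e_a_ratio)
            self.ve = self.sv - self.va
        self.T = T
        self.tau_e = tau_e
        self.tau_a = tau_a

    def _dia_volume(self, t):
        """V on the diastolic half, t in [T/2, T]."""
        u_e = (t - self.T / 2.0) / self.tau_e
        u_a = (t - (self.T - self.tau_a)) / self.tau_a
        return self.esv + self.ve * _wave_fraction(u_e) + self.va * _wave_fraction(u_a)

    def _dia_rate(self, t):
        u_e = (t - self.T / 2.0) / self.tau_e
        u_a = (t - (self.T - self.tau_a)) / self.tau_a
        return (self.ve / self.tau_e) * _wave_rate(u_e) + (
            self.va / self.tau_a
        ) * _wave_rate(u_a)

    def volume(self, t):
        t = float(t) % self.T
        if t >= self.T / 2.0:
            return float(self._dia_volume(t))
        return float(self._dia_volume(self.T - t))

    def dvdt(self, t):
        t = float(t) % self.T
        if t >= self.T / 2.0:
            return float(self._dia_rate(t))
        return -float(self._dia_rate(self.T - t))

    @property
    def diastasis(self):
        """(start, end) of the zero-flow gap in absolute cycle time."""
        return (self.T / 2.0 + self.tau_e, self.T - self.tau_a)


# ---------------------------------------------------------------------------
# LV phantom: geometry and interior flow


def _chamber_mask(x, y, z, a, c, y_center):
    """Half-ellipsoid voxel-centre mask: semi-axes (a, a, c), base at z = 0."""
    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    inside = (X / a) ** 2 + ((Y - y_center) / a) ** 2 + (Z / c) ** 2 <= 1.0
    return inside & (Z < 0.0)


def _calibrate_depth(edv_mm3, a0, h, y_center, x, y, z):
    """Long-axis depth c such that the voxelised cavity volume hits the EDV.

    The voxel count is a step function of c; the y-centre of the chamber is
    deliberately offset from the voxel lattice so the steps are fine enough
    to land within one voxel of the target volume.
    """
    target = edv_mm3 / h**3
    c_est = 3.0 * edv_mm3 / (2.0 * math.pi * a0**2)
    lo, hi = 0.75 * c_est, 1.35 * c_est
    n_lo = _chamber_mask(x, y, z, a0, lo, y_center).sum()
    n_hi = _chamber_mask(x, y, z, a0, hi, y_center).sum()
    if not (n_lo <= target <= n_hi):
        raise ValueError("chamber calibration bracket failed; adjust chamber_radius")
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if _chamber_mask(x, y, z, a0, mid, y_center).sum() < target:
            lo = mid
        else:
            hi = mid
    best, best_err = None, np.inf
    for c in (lo, hi):
        n = _chamber_mask(x, y, z, a0, c, y_center).sum()
        err = abs(n * h**3 - edv_mm3)
        if err < best_err:
            best, best_err = c, err
    if best_err > h**3:
        raise ValueError(
            f"could not voxelise the chamber to within one voxel of the EDV "
            f"(residual {best_err:.0f} mm^3); adjust chamber_radius"
        )
    return best


def _potential_flow_frame(mask, x, y, z, h, rate, y_center, disk_center_xy, disk_r):
    """Incompressible interior velocity for one frame.

    Solves the Neumann problem div(grad phi) = 0 on the cavity voxels with
    wall-face fluxes matching the wall (scaling) motion and a uniform plug
    outflux over the active orifice faces, sized so the discrete fluxes
    balance exactly.  Returns the cell-centre velocity array (m/s) and the
    plug velocity.
    """
    nxg, nyg, nzg = mask.shape
    m = int(mask.sum())
    ids = np.full(mask.shape, -1, dtype=np.int64)
    ids[mask] = np.arange(m)
    coords = (x, y, z)
    center = (0.0, y_center, 0.0)
    b = np.zeros(m)
    diag = np.zeros(m)
    rows, cols, vals = [], [], []
    # face bookkeeping for centre-velocity reconstruction: normal velocity
    # (along +axis) at the low and high face of each cavity voxel
    face_lo = [np.zeros(m) for _ in range(3)]
    face_hi = [np.zeros(m) for _ in range(3)]
    int_pairs = []  # (axis, i_ids, j_ids) internal faces
    orifice_rows = []
    wall_flux_sum = 0.0

    for a in range(3):
        nb_hi = np.zeros_like(mask)
        sl_from = [slice(None)] * 3
        sl_to = [slice(None)] * 3
        sl_from[a] = slice(1, None)
        sl_to[a] = slice(0, -1)
        nb_hi[tuple(sl_to)] = mask[tuple(sl_from)]
        internal = mask & nb_hi
        ii = ids[internal]
        jj = np.full(mask.shape, -1, dtype=np.int64)
        jj[tuple(sl_to)] = ids[tuple(sl_from)]
        jn = jj[internal]
        rows.extend([ii, jn])
        cols.extend([jn, ii])
        vals.extend([np.full(len(ii), h), np.full(len(jn), h)])
        np.add.at(diag, ii, -h)
        np.add.at(diag, jn, -h)
        int_pairs.append((a, ii, jn))

        for sign in (+1, -1):
            if sign > 0:
                bnd = mask & ~nb_hi
            else:
                nb_lo = np.zeros_like(mask)
                nb_lo[tuple(sl_from)] = mask[tuple(sl_to)]
                bnd = mask & ~nb_lo
            vi = np.argwhere(bnd)
            if len(vi) == 0:
                continue
            rowids = ids[bnd]
            face = np.stack(
                [coords[0][vi[:, 0]], coords[1][vi[:, 1]], coords[2][vi[:, 2]]], axis=1
            )
            face[:, a] += sign * h / 2.0
            # outward flux density g = w . n with w the wall (scaling) velocity
            g = sign * rate * (face[:, a] - center[a])
            if a == 2 and sign > 0:
                on_plane = np.abs(face[:, 2]) < h / 4.0
                in_disk = (face[:, 0] - disk_center_xy[0]) ** 2 + (
                    face[:, 1] - disk_center_xy[1]
                ) ** 2 <= disk_r**2
                is_orifice = on_plane & in_disk
            else:
                is_orifice = np.zeros(len(vi), dtype=bool)
            wall = ~is_orifice
            np.add.at(b, rowids[wall], -g[wall] * h**2)
            wall_flux_sum += float(np.sum(g[wall])) * h**2
            if sign > 0:
                np.add.at(face_hi[a], rowids[wall], sign * g[wall])
            else:
                np.add.at(face_lo[a], rowids[wall], sign * g[wall])
            if is_orifice.any():
                orifice_rows.append(rowids[is_orifice])

    if not orifice_rows:
        raise ValueError("no orifice faces found on the base plane")
    orif = np.concatenate(orifice_rows)
    u_plug = -wall_flux_sum / (len(orif) * h**2)
    np.add.at(b, orif, -u_plug * h**2)
    np.add.at(face_hi[2], orif, u_plug)

    rows = np.concatenate(rows + [np.arange(m)])
    cols = np.concatenate(cols + [np.arange(m)])
    vals = np.concatenate(vals + [diag])
    # pin phi[0] = 0 (pure-Neumann problem; fluxes balance by construction)
    keep = rows != 0
    rows, cols, vals = rows[keep], cols[keep], vals[keep]
    rows = np.append(rows, 0)
    cols = np.append(cols, 0)
    vals = np.append(vals, 1.0)
    b[0] = 0.0
    A = sparse.csr_matrix((vals, (rows, cols)), shape=(m, m))
    phi = spsolve(A, b)

    for a, ii, jn in int_pairs:
        vf = (phi[jn] - phi[ii]) / h
        np.add.at(face_hi[a], ii, vf)
        np.add.at(face_lo[a], jn, vf)
    vel = np.zeros(mask.shape + (3,))
    for a in range(3):
        vel[mask, a] = 0.5 * (face_lo[a] + face_hi[a])
    return vel, u_plug


def make_lv_phantom(params: PhantomParams = None):
    """Build the LV phantom: velocity field, geometry and ground truth.

    Returns ``(field, geom, truth)``.  The chamber depth is calibrated so
    the voxelised cavity volume matches the requested EDV to within one
    voxel.  Systolic frames are solved by the potential-flow construction;
    diastolic frames are their exact mirrored time-reverse.  Ground-truth
    component labels and inflow phases come from the fine-step reference
    integrator on the finished field.

    Raises
    ------
    ValueError
        If the construction would exceed the VENC anywhere (advice: enlarge
        the orifice or lower the EF / EDV).
    """
    p = params or PhantomParams()
    h = p.spacing
    T = p.cycle_length_ms
    n = p.n_frames
    a0 = p.chamber_radius_mm
    y_center = 0.31 * h  # off-lattice so EDV calibration has fine steps

    rx = int(math.ceil((a0 + 2 * h) / h))
    nx = 2 * rx + 1
    x = (np.arange(nx) - rx) * h  # symmetric about x = 0 (mirror plane)
    ry = rx
    ny = 2 * ry + 1
    y = (np.arange(ny) - ry) * h

    c_est = 3.0 * (p.edv * 1000.0) / (2.0 * math.pi * a0**2)
    nzc = int(math.ceil(1.35 * c_est / h)) + 2
    ncol = int(round(p.column_height_mm / h)) + 3
    nz = nzc + ncol
    z = (np.arange(nz) - nzc + 0.5) * h  # base plane z = 0 between centres

    c0 = _calibrate_depth(p.edv * 1000.0, a0, h, y_center, x, y, z)
    ed_mask = _chamber_mask(x, y, z, a0, c0, y_center)
    edv_mm3 = float(ed_mask.sum()) * h**3

    curve = _VolumeCurve(
        edv_mm3, p.ef, T, p.tau_e_frac * T, p.tau_a_frac * T, p.e_a_ratio
    )
    frame_times = np.arange(n) * T / n
    s = np.array([(curve.volume(t) / edv_mm3) ** (1.0 / 3.0) for t in frame_times])

    d = p.orifice_offset_mm
    ro = p.orifice_radius_mm
    if d + ro >= a0:
        raise ValueError("orifice disks must fit inside the chamber base")
    if ro - d >= 0:
        raise ValueError("orifice disks must not straddle the mirror plane")

    X, Y, Z = np.meshgrid(x, y, z, indexing="ij")
    shell_source = ndimage.binary_dilation(ed_mask) & (Z < 0.0)
    col_aortic = (
        (Z > 0.0)
        & (Z <= p.column_height_mm)
        & ((X - d) ** 2 + (Y - y_center) ** 2 <= ro**2)
    )

    vel = np.zeros((n, nx, ny, nz, 3))
    es_mask = None
    for k in range(n // 2 + 1):
        t = frame_times[k]
        V = curve.volume(t)
        dV = curve.dvdt(t)
        mask_k = _chamber_mask(x, y, z, a0 * s[k], c0 * s[k], y_center)
        if k == n // 2:
            es_mask = mask_k
        rate = dV / (3.0 * V)  # 1/ms: wall velocity w = rate * (x - base centre)
        if abs(dV) < 1e-12:
            continue  # zero-flux frame (ED, ES, diastasis mirror): field is zero
        v_ch, u_plug = _potential_flow_frame(
            mask_k, x, y, z, h, rate, y_center, (d, y_center), ro
        )
        frame = v_ch
        shell = shell_source & ~mask_k
        frame[shell, 0] = rate * X[shell]
        frame[shell, 1] = rate * (Y[shell] - y_center)
        frame[shell, 2] = rate * Z[shell]
        # image (reflected) layer just above the base plane outside the
        # orifice: enforces zero normal velocity at the closed-valve wall,
        # which plain zero-padding would smear into a spurious leak
        top = nzc - 1  # top chamber layer (z = -h/2); ghost layer at z = +h/2
        ghost = mask_k[:, :, top] & ~col_aortic[:, :, nzc]
        frame[:, :, nzc, 0][ghost] = frame[:, :, top, 0][ghost]
        frame[:, :, nzc, 1][ghost] = frame[:, :, top, 1][ghost]
        frame[:, :, nzc, 2][ghost] = -frame[:, :, top, 2][ghost]
        frame[col_aortic, :] = 0.0
        frame[col_aortic, 2] = u_plug
        vel[k] = frame

    # diastole = exact mirrored time-reverse of systole:
    # v(x,y,z, T - t) = (vx, -vy, -vz)(-x, y, z, t)
    for k in range(n // 2 + 1, n):
        src = vel[n - k]
        flip = src[::-1, :, :, :]
        vel[k, ..., 0] = flip[..., 0]
        vel[k, ..., 1] = -flip[..., 1]
        vel[k, ..., 2] = -flip[..., 2]

    vmax = float(np.sqrt((vel**2).sum(axis=-1)).max())
    if vmax > p.venc_m_s:
        raise ValueError(
            f"phantom peak speed {vmax:.2f} m/s exceeds VENC {p.venc_m_s} m/s; "
            "enlarge orifice_radius_mm or lower ef/edv"
        )

    origin = np.array([x[0], y[0], z[0]])
    field = VelocityField4D(
        velocities=vel,
        spacing=h,
        frame_times=frame_times,
        cycle_length=T,
        venc=p.venc_m_s,
        origin_mm=origin,
        periodic=True,
    )
    orifices = [
        OrificeDisk("mitral_orifice", (-d, y_center, 0.0), (0.0, 0.0, 1.0), ro),
        OrificeDisk("aortic_orifice", (d, y_center, 0.0), (0.0, 0.0, 1.0), ro),
    ]
    geom = LVGeometry(
        ed_mask=ed_mask,
        es_mask_prev=es_mask.copy(),
        es_mask_next=es_mask.copy(),
        orifices=orifices,
        spacing=h,
        origin_mm=origin,
        ed_frame=0,
        es_frame_prev=n // 2,
        es_frame_next=n // 2,
    )
    truth = _ground_truth(field, geom, p, curve, frame_times)
    return field, geom, truth


def _ground_truth(field, geom, p, curve, frame_times):
    """Oracle labels via the fine-step reference integrator."""
    oracle = trace_cycle(
        field, geom, TraceConfig(substeps_per_frame=ORACLE_SUBSTEPS)
    )
    classify_pathlines(oracle, geom)
    gap_lo, gap_hi = curve.diastasis
    gap_center_rel = 0.5 * (gap_lo + gap_hi) - curve.T  # on the ED-centred axis
    phases = np.full(len(oracle), "none", dtype=object)
    for i in range(len(oracle)):
        if oracle.components[i] in (DIRECT, RETAINED):
            t_hit = None
            for t, _pt, lab in oracle.crossings[i]:
                if lab == "mitral_orifice" and t <= 1e-9:
                    t_hit = t if t_hit is None else min(t_hit, t)
            if t_hit is None:
                phases[i] = "early"
            else:
                phases[i] = "early" if t_hit < gap_center_rel else "late"
        oracle.inflow_phase[i] = phases[i]
    seeds = oracle.positions[:, oracle.ed_index(), :].copy()
    return GroundTruth(
        seeds_mm=seeds,
        components=oracle.components.copy(),
        inflow_phase=phases,
        edv_ml=geom.edv_ml(),
        esv_ml=geom.esv_ml(),
        stroke_volume_ml=curve.sv / 1000.0,
        e_volume_ml=curve.ve / 1000.0,
        a_volume_ml=curve.va / 1000.0,
        frame_times=frame_times.copy(),
        volume_curve_ml=np.array([curve.volume(t) for t in frame_times]) / 1000.0,
        diastasis_ms=(gap_lo - curve.T, gap_hi - curve.T),
        oracle=oracle,
    )


# ---------------------------------------------------------------------------
# flux bookkeeping


def disk_flux(field: VelocityField4D, disk: OrificeDisk, t_ms: float) -> float:
    """Volumetric flux (mm^3/ms) through an orifice disk, outward positive.

    For axis-aligned disks the flux is evaluated on the voxel-centre plane
    half a voxel outside the disk (where the interpolated through-valve
    plug profile is exact on the lattice); otherwise the disk is
    supersampled in-plane.
    """
    h = field.spacing
    r = disk.radius_mm
    nrm = np.asarray(disk.normal, dtype=float)
    center = np.asarray(disk.center_mm, dtype=float)
    axis = int(np.argmax(np.abs(nrm)))
    if abs(abs(nrm[axis]) - 1.0) < 1e-12:
        # lattice of voxel centres on the plane half a voxel outside
        plane_pt = center + 0.5 * h * nrm
        others = [a for a in range(3) if a != axis]
        k = int(round((plane_pt[axis] - field.origin_mm[axis]) / h))
        coords = []
        for a in others:
            n_a = field.grid_shape[a]
            coords.append(field.origin_mm[a] + np.arange(n_a) * h)
        A, B = np.meshgrid(coords[0], coords[1], indexing="ij")
        keep = (A - center[others[0]]) ** 2 + (B - center[others[1]]) ** 2 <= r**2
        pts = np.empty((int(keep.sum()), 3))
        pts[:, axis] = field.origin_mm[axis] + k * h
        pts[:, others[0]] = A[keep]
        pts[:, others[1]] = B[keep]
        v = sample_velocity(field, pts, t_ms)
        return float(np.sum(v @ nrm)) * h * h
    sub = h / 4.0
    ref = np.array([1.0, 0.0, 0.0])
    if abs(nrm @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = np.cross(nrm, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(nrm, e1)
    m = int(math.ceil(r / sub))
    u = (np.arange(-m, m + 1) + 0.5) * sub
    U, W = np.meshgrid(u, u, indexing="ij")
    keep = (U**2 + W**2) <= r**2
    pts = center + U[keep][:, None] * e1 + W[keep][:, None] * e2
    v = sample_velocity(field, pts, t_ms)
    return float(np.sum(v @ nrm)) * sub * sub


def volume_curve_from_flux(field: VelocityField4D, geom: LVGeometry) -> np.ndarray:
    """Cavity volume (mL) at frame times, integrated from orifice fluxes.

    dV/dt equals the net inward flux through the two orifices (the wall is
    impermeable); trapezoidal integration from the ED frame.  Used to audit
    the phantom construction against its prescribed volume curve.
    """
    times = field.frame_times
    net_in = np.empty(len(times))
    mv = geom.orifice("mitral_orifice")
    ao = geom.orifice("aortic_orifice")
    for j, t in enumerate(times):
        net_in[j] = -(disk_flux(field, mv, t) + disk_flux(field, ao, t))
    v0 = geom.edv_ml() * 1000.0
    out = np.empty(len(times))
    out[0] = v0
    for j in range(1, len(times)):
        dt = times[j] - times[j - 1]
        out[j] = out[j - 1] + 0.5 * (net_in[j] + net_in[j - 1]) * dt
    return out / 1000.0
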