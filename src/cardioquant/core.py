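"""Domain types and unit conventions.

Conventions used throughout the package
---------------------------------------
* Coordinates are physical millimetres, voxel-centre convention, 0-based
  indices internally; masks and velocity fields share one affine
  (``origin_mm + index * spacing_mm``).
* Velocities are metres per second internally; the velocity-encoding limit
  (VENC) is given in cm/s at the interface, as printed on scanner consoles.
* Time is milliseconds from the R-wave (cycle start).  A periodic time axis
  (frame after the last = the first) is used only by the synthetic phantoms,
  never assumed for measured data.
* Kinetic energy is reported in microjoules (a 1 mL parcel at 1 m/s carries
  ~10^-5 J, so uJ is the natural magnitude).
* Myocardial blood flow is reported in ml/g/min.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "BloodConstants",
    "ComponentResult",
    "LVGeometry",
    "OrificeDisk",
    "Pathline",
    "PathlineSet",
    "VelocityField4D",
    "COMPONENTS",
    "DIRECT",
    "RETAINED",
    "DELAYED",
    "RESIDUAL",
    "QC_VALID",
    "QC_EXITED_WALL",
    "QC_LEFT_FOV",
]

# Functional flow components of the end-diastolic blood pool.
DIRECT = "direct"
RETAINED = "retained_inflow"
DELAYED = "delayed_ejection"
RESIDUAL = "residual"
COMPONENTS = (DIRECT, RETAINED, DELAYED, RESIDUAL)

# Pathline quality-control states.
QC_VALID = "valid"
QC_EXITED_WALL = "exited_wall"
QC_LEFT_FOV = "left_fov"


@dataclass(frozen=True)
class BloodConstants:
    """Physical constants of blood used by the analyses.

    Attributes
    ----------
    rho : float
        Blood density in kg/m^3 (default 1060).
    t1_blood : float
        Longitudinal relaxation time of blood in ms (default 1650).
    partition_coefficient : float
        Blood--tissue partition coefficient in ml/g (default 1).
    """

    rho: float = 1060.0
    t1_blood: float = 1650.0
    partition_coefficient: float = 1.0

    def __post_init__(self) -> None:
        for name in ("rho", "t1_blood", "partition_coefficient"):
            if not getattr(self, name) > 0:
                raise ValueError(f"BloodConstants.{name} must be strictly positive")


@dataclass
class VelocityField4D:
    """Time-resolved three-directional velocity field on a voxel grid.

    Attributes
    ----------
    velocities : ndarray, shape (T, X, Y, Z, 3)
        Velocity in m/s at every voxel centre and timeframe.
    spacing : float
        Isotropic voxel edge length in mm.
    origin_mm : ndarray, shape (3,)
        Physical coordinates (mm) of the centre of voxel (0, 0, 0).
    frame_times : ndarray, shape (T,)
        Frame times in ms from cycle start; strictly increasing,
        all <= ``cycle_length``.
    cycle_length : float
        Cardiac cycle (R-R) length in ms.
    venc : float
        Velocity-encoding limit in m/s.  Synthetic fields satisfy
        ``|v| <= venc`` everywhere.
    periodic : bool
        Whether the time axis wraps (synthetic phantoms only).
    """

    velocities: np.ndarray
    spacing: float
    frame_times: np.ndarray
    cycle_length: float
    venc: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    periodic: bool = False

    def __post_init__(self) -> None:
        self.velocities = np.asarray(self.velocities, dtype=np.float64)
        self.frame_times = np.asarray(self.frame_times, dtype=np.float64)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        self.validate()

    def validate(self) -> None:
        if self.velocities.ndim != 5 or self.velocities.shape[-1] != 3:
            raise ValueError(
                "velocities must have shape (T, X, Y, Z, 3); got "
                f"{self.velocities.shape}"
            )
        if not np.all(np.isfinite(self.velocities)):
            raise ValueError("velocity field contains non-finite values")
        if not self.spacing > 0:
            raise ValueError("spacing must be > 0")
        n_frames = self.velocities.shape[0]
        if n_frames < 2:
            raise ValueError(
                "velocity field must have at least 2 frames (pathline tracing "
                "interpolates between frames)"
            )
        if self.frame_times.shape != (n_frames,):
            raise ValueError(
                f"frame_times has length {self.frame_times.shape}, expected "
                f"({n_frames},)"
            )
        if not np.all(np.diff(self.frame_times) > 0):
            raise ValueError("frame_times must be strictly increasing")
        if self.frame_times[-1] > self.cycle_length:
            raise ValueError("frame_times must not exceed cycle_length")
        if not self.venc > 0:
            raise ValueError("venc must be > 0")

    @property
    def n_frames(self) -> int:
        return self.velocities.shape[0]

    @property
    def grid_shape(self) -> tuple:
        return self.velocities.shape[1:4]

    def max_speed(self) -> float:
        """Largest velocity magnitude anywhere in the field, m/s."""
        return float(np.sqrt((self.velocities**2).sum(axis=-1)).max())


@dataclass(frozen=True)
class OrificeDisk:
    """A circular orifice on the blood-pool surface (mitral or aortic).

    The disk lies in the plane through ``center_mm`` with unit normal
    ``normal`` (pointing out of the blood pool); a surface crossing within
    ``radius_mm`` of the centre (in-plane) is attributed to this orifice.
    """

    name: str
    center_mm: tuple
    normal: tuple
    radius_mm: float

    def __post_init__(self) -> None:
        n = np.asarray(self.normal, dtype=float)
        if not np.isclose(np.linalg.norm(n), 1.0, atol=1e-9):
            raise ValueError("orifice normal must be unit length")
        if not self.radius_mm > 0:
            raise ValueError("orifice radius must be > 0")

    def contains(self, points_mm: np.ndarray, slab_mm: float = np.inf) -> np.ndarray:
        """Whether points fall inside the orifice cylinder.

        A point is attributed to the orifice when its in-plane distance to
        the disk centre is within the radius and it lies within ``slab_mm``
        of the disk plane on either side.
        """
        p = np.atleast_2d(np.asarray(points_mm, dtype=float)) - np.asarray(
            self.center_mm, dtype=float
        )
        n = np.asarray(self.normal, dtype=float)
        along = p @ n
        in_plane = p - np.outer(along, n)
        r = np.linalg.norm(in_plane, axis=1)
        return (r <= self.radius_mm) & (np.abs(along) <= slab_mm)


@dataclass
class LVGeometry:
    """LV blood-pool masks with labelled orifice regions.

    ``ed_mask`` is the blood pool at end diastole (the seeding region);
    ``es_mask_prev`` / ``es_mask_next`` are the pools at the preceding and
    following end systole.  Surface crossings of the ED blood pool are
    labelled ``mitral_orifice`` / ``aortic_orifice`` when they fall inside
    the corresponding :class:`OrificeDisk`, and ``wall`` otherwise.
    """

    ed_mask: np.ndarray
    es_mask_prev: np.ndarray
    es_mask_next: np.ndarray
    orifices: Sequence[OrificeDisk]
    spacing: float
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    ed_frame: int = 0
    es_frame_prev: Optional[int] = None
    es_frame_next: Optional[int] = None

    def __post_init__(self) -> None:
        self.ed_mask = np.asarray(self.ed_mask, dtype=bool)
        self.es_mask_prev = np.asarray(self.es_mask_prev, dtype=bool)
        self.es_mask_next = np.asarray(self.es_mask_next, dtype=bool)
        self.origin_mm = np.asarray(self.origin_mm, dtype=np.float64)
        for name in ("ed_mask", "es_mask_prev", "es_mask_next"):
            m = getattr(self, name)
            if not m.any():
                raise ValueError(f"{name} is empty")
            if m.shape != self.ed_mask.shape:
                raise ValueError("all masks must share one grid")
        names = {o.name for o in self.orifices}
        if not {"mitral_orifice", "aortic_orifice"} <= names:
            raise ValueError(
                "geometry must label both a mitral_orifice and an aortic_orifice"
            )

    @property
    def mitral_plane(self) -> tuple:
        """(point_mm, unit_normal) of the mitral valve plane."""
        o = self.orifice("mitral_orifice")
        return (
            np.asarray(o.center_mm, dtype=float),
            np.asarray(o.normal, dtype=float),
        )

    def orifice(self, name: str) -> OrificeDisk:
        for o in self.orifices:
            if o.name == name:
                return o
        raise KeyError(name)

    def edv_ml(self) -> float:
        """End-diastolic blood-pool volume in mL (voxel count x voxel volume)."""
        return float(self.ed_mask.sum()) * self.spacing**3 / 1000.0

    def esv_ml(self) -> float:
        return float(self.es_mask_next.sum()) * self.spacing**3 / 1000.0

    def points_in_mask(self, points_mm: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Voxel-centre containment: is each point inside the mask?

        A point belongs to the voxel whose centre is nearest (rounding the
        fractional index); points off the grid are outside.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        idx = np.rint((pts - self.origin_mm) / self.spacing).astype(np.int64)
        shape = np.asarray(mask.shape)
        ok = np.all((idx >= 0) & (idx < shape), axis=1)
        out = np.zeros(len(pts), dtype=bool)
        if ok.any():
            sel = idx[ok]
            out[ok] = mask[sel[:, 0], sel[:, 1], sel[:, 2]]
        return out

    def classify_crossing(self, points_mm: np.ndarray) -> np.ndarray:
        """Label surface-crossing points as mitral/aortic orifice or wall.

        The tolerance slab around each orifice plane is one voxel, matching
        the accuracy of substep-resolution crossing detection.
        """
        pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
        labels = np.full(len(pts), "wall", dtype=object)
        slab = 1.5 * self.spacing
        # in-plane attribution tolerance: the interpolated jet edge is one
        # voxel wide, and crossing localisation is half-voxel accurate
        pad = 1.0 * self.spacing
        for o in self.orifices:
            wide = OrificeDisk(o.name, o.center_mm, o.normal, o.radius_mm + pad)
            hit = wide.contains(pts, slab_mm=slab)
            labels[hit & (labels == "wall")] = o.name
        return labels


@dataclass
class Pathline:
    """One voxel's massless-particle trajectory through the cycle.

    ``times_ms`` runs from the preceding end systole (negative times, i.e.
    the previous cycle's diastole) through end diastole (t = 0) to the
    following end systole.  ``volume_mm3`` is the blood volume the pathline
    represents (one analysis-grid voxel, attached at seeding and never
    rescaled).
    """

    positions: np.ndarray  # (K, 3) mm
    velocities: np.ndarray  # (K, 3) m/s
    times_ms: np.ndarray  # (K,)
    volume_mm3: float
    qc_status: str = QC_VALID
    component: Optional[str] = None
    inflow_phase: Optional[str] = None  # early | late | none
    seed_index: int = -1
    crossings: list = field(default_factory=list)  # (t_ms, point_mm, label)

    def __post_init__(self) -> None:
        if len(self.positions) != len(self.velocities) or len(self.positions) != len(
            self.times_ms
        ):
            raise ValueError("positions, velocities and times must have equal length")
        if not self.volume_mm3 > 0:
            raise ValueError("pathline volume must be > 0")
        if self.component is not None and self.qc_status != QC_VALID:
            raise ValueError("component may only be assigned to QC-valid pathlines")


class PathlineSet:
    """A bundle of pathlines sharing one time axis (vectorised storage).

    Stores positions and velocities as dense ``(N, K, 3)`` arrays, which the
    tracing and component code operate on directly; ``__getitem__`` exposes
    individual :class:`Pathline` views for inspection and export.
    """

    def __init__(
        self,
        positions: np.ndarray,
        velocities: np.ndarray,
        times_ms: np.ndarray,
        volumes_mm3: np.ndarray,
        qc_status: np.ndarray,
        components: Optional[np.ndarray] = None,
        inflow_phase: Optional[np.ndarray] = None,
        crossings: Optional[list] = None,
    ) -> None:
        self.positions = np.asarray(positions, dtype=np.float64)
        self.velocities = np.asarray(velocities, dtype=np.float64)
        self.times_ms = np.asarray(times_ms, dtype=np.float64)
        self.volumes_mm3 = np.asarray(volumes_mm3, dtype=np.float64)
        self.qc_status = np.asarray(qc_status, dtype=object)
        n = len(self.positions)
        self.components = (
            np.asarray(components, dtype=object)
            if components is not None
            else np.full(n, None, dtype=object)
        )
        self.inflow_phase = (
            np.asarray(inflow_phase, dtype=object)
            if inflow_phase is not None
            else np.full(n, None, dtype=object)
        )
        # per-pathline list of (t_ms, point_mm, label) surface crossings
        self.crossings = crossings if crossings is not None else [[] for _ in range(n)]
        if self.positions.shape != self.velocities.shape:
            raise ValueError("positions and velocities must have equal shape")
        if self.positions.shape[1] != len(self.times_ms):
            raise ValueError("time axis mismatch")

    def __len__(self) -> int:
        return len(self.positions)

    def __getitem__(self, i: int) -> Pathline:
        return Pathline(
            positions=self.positions[i],
            velocities=self.velocities[i],
            times_ms=self.times_ms,
            volume_mm3=float(self.volumes_mm3[i]),
            qc_status=str(self.qc_status[i]),
            component=self.components[i],
            inflow_phase=self.inflow_phase[i],
            seed_index=i,
            crossings=list(self.crossings[i]),
        )

    @property
    def valid(self) -> np.ndarray:
        return self.qc_status == QC_VALID

    def total_volume_ml(self) -> float:
        return float(self.volumes_mm3.sum()) / 1000.0

    def ed_index(self) -> int:
        """Index of the end-diastolic sample (t = 0) on the time axis."""
        i = int(np.argmin(np.abs(self.times_ms)))
        return i


@dataclass
class ComponentResult:
    """Volumes, KE time series and diastolic split of the four flow components.

    ``volumes`` maps component name to mL.  ``ke_timeseries`` maps component
    name to a (K,) array of total KE in uJ on the shared ``times_ms`` axis;
    components with zero volume carry no KE entry (absent, not zero).
    """

    volumes: dict
    ke_timeseries: dict
    ke_per_ml_at_ed: dict
    direct_flow_split: dict  # {"early": mL, "late": mL}
    edv: float
    inflow: float
    ejected: float
    times_ms: Optional[np.ndarray] = None
    mid_diastole_frame: Optional[int] = None

    def validate(self, voxel_volume_ml: float = 0.0) -> None:
        for c, v in self.volumes.items():
            if v < 0:
                raise ValueError(f"negative volume for component {c}")
        tol = max(voxel_volume_ml, 1e-9)
        if abs(sum(self.volumes.values()) - self.edv) > tol:
            raise ValueError("component volumes do not partition the EDV")
        if abs(self.volumes[DIRECT] + self.volumes[RETAINED] - self.inflow) > 1e-9:
            raise ValueError("direct + retained_inflow must equal inflow")
        if abs(self.volumes[DIRECT] + self.volumes[DELAYED] - self.ejected) > 1e-9:
            raise ValueError("direct + delayed_ejection must equal ejected")


@dataclass
class MBFResult:
    """Myocardial blood flow estimates with noise decomposition.

    All values in ml/g/min.  ``regional_mbf`` has six segments around the
    ring, ``septal_mbf`` three segments over the septal half; ``pn`` / ``tn``
    are the physiological and thermal components of the temporal noise of
    the global estimate (standard error over the control/tag pairs).
    """

    global_mbf: float
    regional_mbf: np.ndarray
    septal_mbf: np.ndarray
    per_pair_mbf: np.ndarray
    pn: Optional[float] = None
    tn: Optional[float] = None

    def __post_init__(self) -> None:
        self.regional_mbf = np.asarray(self.regional_mbf, dtype=float)
        self.septal_mbf = np.asarray(self.septal_mbf, dtype=float)
        self.per_pair_mbf = np.asarray(self.per_pair_mbf, dtype=float)
        if self.regional_mbf.shape != (6,):
            raise ValueError("regional_mbf must have six segments")
        if self.septal_mbf.shape != (3,):
            raise ValueError("septal_mbf must have three segments")
        for arr in (self.regional_mbf, self.septal_mbf, self.per_pair_mbf):
            if not np.all(np.isfinite(arr)):
                raise ValueError("MBF values must be finite")
        if self.pn is not None and self.pn < 0:
            raise ValueError("pn must be >= 0")
        if self.tn is not None and self.tn < 0:
            raise ValueError("tn must be >= 0")
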