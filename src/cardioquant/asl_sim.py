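"""Synthetic FAIR arterial-spin-labelling series.

The forward model inverts the single-TI Buxton quantification equation: a
control image carries the baseline myocardial signal, and the tagged image
is reduced by the perfusion-weighted difference

    dM = 2 * M0 * TI * exp(-TI / T1) * MBF / 60000,

with TI equal to the R-R interval and MBF the true flow in ml/g/min.

Two noise mechanisms are simulated:

* **physiological (motion) noise** -- each acquired image is rigidly
  displaced in-plane by an independent random shift whose standard
  deviation scales with the acquisition-window length (motion during a
  longer readout displaces the image more), creating control/tag
  inconsistencies that propagate into pair-to-pair MBF fluctuations;
* **thermal noise** -- additive white Gaussian noise, inflated by
  sqrt(SENSE factor) under parallel-imaging acceleration (g-factor-style
  SNR loss).

Acceleration is modelled only as fewer acquired k-space lines (a shorter
acquisition window) plus the thermal-noise inflation; aliasing and
unwrapping are not simulated.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import BloodConstants

__all__ = [
    "ASLProtocol",
    "ASLGeometry",
    "ASLTruth",
    "ASLSeries",
    "acquisition_window",
    "total_window",
    "simulate_series",
    "write_asl_series",
    "read_asl_series",
    "REFERENCE_WINDOW_MS",
    "DEFAULT_MOTION_AMPLITUDE_MM",
]

#: Acquisition window of the unaccelerated reference protocol, used to
#: normalise the motion-amplitude scaling (96 lines x 3.2 ms).
REFERENCE_WINDOW_MS = 307.0

#: In-plane displacement SD (mm) of one acquired image under the reference
#: acquisition window.  Calibrated once (see calibrate_motion_amplitude and
#: docs/methods.md) so that the reference protocol's physiological noise
#: sits at the 0.20 ml/g/min level that motivates the accelerated protocol.
DEFAULT_MOTION_AMPLITUDE_MM = 0.646


@dataclass(frozen=True)
class ASLProtocol:
    """FAIR-ASL acquisition protocol.

    Defaults describe the reference snapshot-bSSFP protocol: 96 phase-encode
    lines at TR = 3.2 ms (307 ms acquisition window), 133 ms of fat-sat and
    flip-angle-ramp overhead (440 ms total imaging window), inversion timed
    to 77% of the R-R interval, six control/tag pairs in 12 s breath-holds.
    ``sense_factor = 2`` halves the acquired lines (153 ms window, 286 ms
    total).
    """

    matrix_lines: int = 96
    tr: float = 3.2  # ms
    sense_factor: int = 1
    overhead: float = 133.0  # ms, fat-sat + ramp modules
    rr_interval: float = 1000.0  # ms
    inversion_fraction: float = 0.77
    n_pairs: int = 6
    breath_hold_s: float = 12.0

    def __post_init__(self) -> None:
        if self.matrix_lines % self.sense_factor:
            raise ValueError("matrix_lines must be divisible by sense_factor")
        if not self.tr > 0:
            raise ValueError("tr must be > 0")
        if not 0 < self.inversion_fraction < 1:
            raise ValueError("inversion_fraction must lie in (0, 1)")
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")

    @property
    def ti_ms(self) -> float:
        """Post-labelling inversion delay: one R-R interval."""
        return self.rr_interval


def acquisition_window(protocol: ASLProtocol) -> int:
    """Readout duration in integer ms: floor(lines / R * TR)."""
    return int(
        math.floor(protocol.matrix_lines / protocol.sense_factor * protocol.tr)
    )


def total_window(protocol: ASLProtocol) -> float:
    """Total per-cycle imaging window: acquisition window + overhead, ms."""
    return acquisition_window(protocol) + protocol.overhead


@dataclass(frozen=True)
class ASLGeometry:
    """Single mid-ventricular short-axis slice with an annular myocardium."""

    shape: tuple = (64, 64)
    pixel_mm: float = 2.0
    r_inner_mm: float = 18.0
    r_outer_mm: float = 26.0
    m0_myocardium: float = 1000.0
    cavity_signal: float = 1800.0
    background_signal: float = 100.0

    @property
    def center_px(self) -> tuple:
        return ((self.shape[0] - 1) / 2.0, (self.shape[1] - 1) / 2.0)

    def radius_map_mm(self) -> np.ndarray:
        iy, ix = np.indices(self.shape)
        cy, cx = self.center_px
        return np.hypot(iy - cy, ix - cx) * self.pixel_mm

    def ring_mask(self) -> np.ndarray:
        r = self.radius_map_mm()
        return (r >= self.r_inner_mm) & (r <= self.r_outer_mm)

    def base_image(self) -> np.ndarray:
        """Noise-free anatomy: bright cavity, myocardial ring, dim outside."""
        r = self.radius_map_mm()
        img = np.full(self.shape, self.background_signal, dtype=np.float64)
        img[r < self.r_inner_mm] = self.cavity_signal
        img[self.ring_mask()] = self.m0_myocardium
        return img


@dataclass(frozen=True)
class ASLTruth:
    """Hidden truth of a simulated series."""

    mbf_true: float = 1.20  # ml/g/min
    motion_amplitude: float = DEFAULT_MOTION_AMPLITUDE_MM  # mm at reference window
    thermal_sd: float = 25.0  # signal units at R = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mbf_true < 0:
            raise ValueError("mbf_true must be >= 0")
        if self.motion_amplitude < 0 or self.thermal_sd < 0:
            raise ValueError("noise amplitudes must be >= 0")


@dataclass
class ASLSeries:
    """One simulated FAIR-ASL acquisition.

    ``baseline`` is the M0 surrogate, ``noise_images`` contain thermal noise
    only (no excitation signal), ``controls``/``tags`` hold the n_pairs
    control and tagged images.
    """

    baseline: np.ndarray
    noise_images: np.ndarray  # (n_noise, H, W)
    controls: np.ndarray  # (n_pairs, H, W)
    tags: np.ndarray  # (n_pairs, H, W)
    protocol: ASLProtocol
    geometry: ASLGeometry
    truth: ASLTruth = None

    def __post_init__(self) -> None:
        shapes = {self.baseline.shape, self.controls.shape[1:], self.tags.shape[1:]}
        if self.noise_images.size:
            shapes.add(self.noise_images.shape[1:])
        if len(shapes) != 1:
            raise ValueError("all images in a series must share one shape")
        if len(self.controls) != self.protocol.n_pairs or len(self.tags) != len(
            self.controls
        ):
            raise ValueError("pair count must equal protocol.n_pairs")

    @property
    def pairs(self):
        return list(zip(self.controls, self.tags))


def perfusion_difference(
    protocol: ASLProtocol,
    mbf: float,
    m0: float,
    constants: BloodConstants = BloodConstants(),
) -> float:
    """Perfusion-weighted control-tag signal difference dM (signal units)."""
    ti = protocol.ti_ms
    return (
        2.0
        * m0
        * ti
        * math.exp(-ti / constants.t1_blood)
        * (mbf / constants.partition_coefficient)
        / 60000.0
    )


def simulate_series(
    protocol: ASLProtocol,
    truth: ASLTruth = None,
    geometry: ASLGeometry = None,
    n_noise: int = 6,
    constants: BloodConstants = BloodConstants(),
) -> ASLSeries:
    """Simulate one FAIR-ASL series under the given protocol and truth.

    The per-image displacement SD is ``motion_amplitude`` scaled by the
    ratio of the protocol's acquisition window to the 307 ms reference
    window; thermal noise has SD ``thermal_sd * sqrt(sense_factor)``.  The
    random stream consumes identical draws for any ``sense_factor``, so two
    protocols simulated from the same seed experience the same underlying
    motion and noise realisations, scaled -- a paired design.

    Deterministic: identical inputs (including seed) give bit-identical
    series.
    """
    truth = truth or ASLTruth()
    geometry = geometry or ASLGeometry()
    if not geometry.ring_mask().any():
        raise ValueError("myocardial ring mask is empty")
    rng = np.random.default_rng(truth.seed)
    base = geometry.base_image()
    m0 = geometry.m0_myocardium
    dm = perfusion_difference(protocol, truth.mbf_true, m0, constants)
    ring = geometry.ring_mask()
    tag_base = base.copy()
    tag_base[ring] -= dm

    sigma_mm = truth.motion_amplitude * acquisition_window(protocol) / REFERENCE_WINDOW_MS
    sigma_px = sigma_mm / geometry.pixel_mm
    thermal = truth.thermal_sd * math.sqrt(protocol.sense_factor)

    def acquire(img: np.ndarray) -> np.ndarray:
        shift = rng.standard_normal(2) * sigma_px
        noise = rng.standard_normal(img.shape) * thermal
        if sigma_px > 0:
            img = ndimage.shift(img, shift, order=1, mode="nearest")
        return img + noise

    baseline = base + rng.standard_normal(base.shape) * thermal
    noise_images = np.stack(
        [rng.standard_normal(base.shape) * thermal for _ in range(n_noise)]
    ) if n_noise else np.zeros((0,) + base.shape)
    controls = np.stack([acquire(base) for _ in range(protocol.n_pairs)])
    tags_list = []
    for _ in range(protocol.n_pairs):
        tags_list.append(acquire(tag_base))
    tags = np.stack(tags_list)
    return ASLSeries(
        baseline=baseline,
        noise_images=noise_images,
        controls=controls,
        tags=tags,
        protocol=protocol,
        geometry=geometry,
        truth=truth,
    )


def calibrate_motion_amplitude(
    target_pn: float = 0.20,
    protocol: ASLProtocol = None,
    n_replicates: int = 200,
    seed: int = 0,
    thermal_sd: float = 25.0,
    mbf_true: float = 1.20,
) -> float:
    """Motion amplitude (mm) whose mean estimated PN hits ``target_pn``.

    The PN response is linear in the displacement SD well above the
    thermal floor, so two proportional updates from a coarse start
    converge.  Used once to fix ``DEFAULT_MOTION_AMPLITUDE_MM``.
    """
    from .asl_quant import mbf_segments  # deferred: avoids import cycle

    protocol = protocol or ASLProtocol()

    def mean_pn(amp: float) -> float:
        pns = []
        for i in range(n_replicates):
            series = simulate_series(
                protocol,
                ASLTruth(
                    mbf_true=mbf_true,
                    motion_amplitude=amp,
                    thermal_sd=thermal_sd,
                    seed=seed + i,
                ),
            )
            pns.append(mbf_segments(series).pn)
        return float(np.mean(pns))

    amp = 0.5
    for _ in range(3):
        pn = mean_pn(amp)
        amp *= target_pn / pn
    return amp


# ---------------------------------------------------------------------------
# container I/O


def write_asl_series(series: ASLSeries, path, truth_path=None) -> Path:
    """Write a series as one .npz stack plus a JSON sidecar.

    The hidden truth goes to ``truth_path`` (default ``<path>.truth.json``)
    so a series can be handed to the quantifier blinded.
    """
    path = Path(path)
    np.savez_compressed(
        path,
        baseline=series.baseline,
        noise_images=series.noise_images,
        controls=series.controls,
        tags=series.tags,
    )
    sidecar = {
        "protocol": {
            "matrix_lines": series.protocol.matrix_lines,
            "tr": series.protocol.tr,
            "sense_factor": series.protocol.sense_factor,
            "overhead": series.protocol.overhead,
            "rr_interval": series.protocol.rr_interval,
            "inversion_fraction": series.protocol.inversion_fraction,
            "n_pairs": series.protocol.n_pairs,
            "breath_hold_s": series.protocol.breath_hold_s,
        },
        "geometry": {
            "shape": list(series.geometry.shape),
            "pixel_mm": series.geometry.pixel_mm,
            "r_inner_mm": series.geometry.r_inner_mm,
            "r_outer_mm": series.geometry.r_outer_mm,
            "m0_myocardium": series.geometry.m0_myocardium,
            "cavity_signal": series.geometry.cavity_signal,
            "background_signal": series.geometry.background_signal,
        },
    }
    side_path = path.with_suffix(path.suffix + ".json") if path.suffix != ".npz" else path.with_suffix(".json")
    side_path.write_text(json.dumps(sidecar, indent=1))
    if series.truth is not None:
        tp = Path(truth_path) if truth_path else path.with_suffix(".truth.json")
        tp.write_text(
            json.dumps(
                {
                    "mbf_true": series.truth.mbf_true,
                    "motion_amplitude": series.truth.motion_amplitude,
                    "thermal_sd": series.truth.thermal_sd,
                    "seed": series.truth.seed,
                },
                indent=1,
            )
        )
    return path


def read_asl_series(path, truth_path=None) -> ASLSeries:
    path = Path(path)
    side_path = path.with_suffix(".json")
    meta = json.loads(side_path.read_text())
    g = meta["geometry"]
    geometry = ASLGeometry(
        shape=tuple(g["shape"]),
        pixel_mm=g["pixel_mm"],
        r_inner_mm=g["r_inner_mm"],
        r_outer_mm=g["r_outer_mm"],
        m0_myocardium=g["m0_myocardium"],
        cavity_signal=g["cavity_signal"],
        background_signal=g["background_signal"],
    )
    protocol = ASLProtocol(**meta["protocol"])
    truth = None
    tp = Path(truth_path) if truth_path else path.with_suffix(".truth.json")
    if tp.exists():
        truth = ASLTruth(**json.loads(tp.read_text()))
    with np.load(path) as z:
        return ASLSeries(
            baseline=z["baseline"],
            noise_images=z["noise_images"],
            controls=z["controls"],
            tags=z["tags"],
            protocol=protocol,
            geometry=geometry,
            truth=truth,
        )
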