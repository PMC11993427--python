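"""Closed-form acquisition-timing calculators for the imaging protocols.

These reproduce the arithmetic that links printed sequence parameters to
the derived timings: the temporal resolution of a k-space-segmented,
three-directionally velocity-encoded cine phase-contrast sequence, and the
k-space coverage bookkeeping used for scan-duration sanity reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["FlowSequenceParams", "temporal_resolution", "kspace_acq_time"]


@dataclass(frozen=True)
class FlowSequenceParams:
    """Cine phase-contrast sequence parameters.

    Attributes
    ----------
    tr : float
        Repetition time in ms.
    k_seg : int
        k-space segmentation factor (lines per cardiac phase per cycle).
    n_encodes : int
        Velocity-encoding points per k-space line.  Three-directional
        encoding needs four acquisitions (one reference + three encoded),
        hence the default of 4.
    """

    tr: float
    k_seg: int
    n_encodes: int = 4

    def __post_init__(self) -> None:
        if not self.tr > 0:
            raise ValueError("tr must be > 0")
        if self.k_seg < 1 or self.n_encodes < 1:
            raise ValueError("k_seg and n_encodes must be positive integers")


def temporal_resolution(params: FlowSequenceParams) -> float:
    """Temporal resolution of the cine phase-contrast sequence, in ms.

    One cardiac phase takes ``n_encodes x k_seg x tr``: every k-space line
    is acquired once per velocity encode, and ``k_seg`` lines are collected
    per phase per heartbeat.
    """
    return params.n_encodes * params.k_seg * params.tr


def kspace_acq_time(n_lines: int, lines_per_cycle: int) -> dict:
    """Heartbeats needed for full k-space coverage (navigator-free floor).

    Returns a summary dict with the cycles needed (ceiling division) and
    the lines collected per cycle.  Navigator efficiency and arrhythmia
    rejection are patient-dependent and deliberately not modelled.
    """
    if n_lines <= 0:
        raise ValueError("n_lines must be > 0")
    if lines_per_cycle <= 0:
        raise ValueError("lines_per_cycle must be > 0")
    cycles = math.ceil(n_lines / lines_per_cycle)
    return {
        "n_lines": n_lines,
        "lines_per_cycle": lines_per_cycle,
        "cycles_needed": cycles,
    }
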