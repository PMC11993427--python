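"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

import pytest

from cardioquant.phantoms import PhantomParams, make_duct_phantom, make_lv_phantom
from cardioquant.tracing import TraceConfig, qc_pathlines, trace_cycle


@pytest.fixture(scope="session")
def lv():
    """Full-size LV phantom at cohort defaults (EDV 179 mL, EF 0.42)."""
    return make_lv_phantom()


@pytest.fixture(scope="session")
def lv_traced(lv):
    """Production-settings pathlines of the full LV phantom, QC'ed."""
    field, geom, _truth = lv
    pathlines = trace_cycle(field, geom, TraceConfig())
    pathlines, report = qc_pathlines(pathlines, geom)
    return pathlines, report


@pytest.fixture(scope="session")
def small_params():
    """A reduced chamber (EDV 60 mL) for the heavier parametric checks."""
    return PhantomParams(
        edv=60.0, chamber_radius_mm=24.0, orifice_radius_mm=10.0, orifice_offset_mm=11.0
    )


@pytest.fixture(scope="session")
def small_lv(small_params):
    return make_lv_phantom(small_params)


@pytest.fixture(scope="session")
def duct_slow():
    """Duct phantom in which half the box length is traversed per half cycle."""
    field, geom = make_duct_phantom(v=15.0 / 491.80327868852459, extent_mm=30.0)
    return field, geom
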