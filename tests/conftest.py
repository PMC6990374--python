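"""Shared fixtures.  The expensive tissue simulations are session-scoped and
reused by the unit, property and acceptance tests.

Simulation sizes: unit/property checks run on strips and, where a full
infarct sheet is required, on a 400 um version of the 4 x 4 cm geometry
(the mechanism being probed is resolution-robust; the calibration targets
themselves always use the reference 200 um spacing).
"""

from __future__ import annotations

import numpy as np
import pytest

from infarctsim import geometry as geo
from infarctsim import metrics as met
from infarctsim import monodomain as md
from infarctsim import protocols as pro
from infarctsim import vulnerability as vul
from infarctsim.cellmodel import RemodelingSpec

#: Root seed of the test suite's stochastic fixtures (fibrosis topologies).
TEST_ROOT_SEED = 1234


def measure_strip_cv(sigma: float, h_um: float = 200.0, dt: float = 0.02,
                     width_mm: float = 2.0, t_end: float = 150.0,
                     gna_scale: float = 1.0,
                     probes_mm: tuple[float, float] = (10.0, 30.0)) -> float:
    """Planar-wave CV (m/s) on a 4 cm homogeneous strip via the
    activation-time difference between two mid-line probes."""
    from infarctsim.cellmodel import CellParams

    g = geo.build_strip(40.0, width_mm, h_um)
    cond = md.ConductivityField.from_grid(g, sigma_healthy=sigma)
    stim = md.StimulusSpec.left_edge(g, onsets=(0.0,))
    cfg = md.SimulationConfig(t_end=t_end, sample_interval=0.5, dt=dt)
    rec = md.run(g, cond, params=CellParams(gna_scale=gna_scale),
                 stimuli=[stim], config=cfg)
    maps = met.activation_repolarization_maps(rec, (0.0, t_end))
    row = g.ny // 2
    p1 = (row, int(round(probes_mm[0] / g.h_mm)))
    p2 = (row, int(round(probes_mm[1] / g.h_mm)))
    return met.conduction_velocity(maps, p1, p2)


_CV_CACHE: dict[tuple, float] = {}


def strip_cv(sigma: float, **kw) -> float:
    key = (sigma, tuple(sorted(kw.items())))
    if key not in _CV_CACHE:
        _CV_CACHE[key] = measure_strip_cv(sigma, **kw)
    return _CV_CACHE[key]


@pytest.fixture(scope="session")
def capture_boundary():
    """(min capturing CI, {ci: captured}) on the healthy reference strip."""
    g = geo.build_strip(40.0, 6.0, 200.0)
    cond = md.ConductivityField.from_grid(g)
    outcomes: dict[float, bool] = {}
    ci = pro.find_min_capture_ci(g, cond, spec=pro.S1S2Spec(electrode="left"),
                                 outcomes=outcomes)
    return ci, outcomes


@pytest.fixture(scope="session")
def mechanism_runs():
    """Fig-3-style S1-S2 runs on the 400 um infarct sheet.

    Returns {arm: (recording, outcome)} for the prolonged-APD arm ("3A") and
    the reduced-INa arm ("3B", sodium conductance at 30%).
    """
    out = {}
    for arm, rem in (("3A", RemodelingSpec(mode="prolonged_apd")),
                     ("3B", RemodelingSpec(mode="reduced_ina",
                                           ina_scale=0.3))):
        g = geo.add_idealized_scar(geo.build_sheet(40.0, 400.0))
        cond = md.ConductivityField.from_grid(g)
        rec = pro.run_s1s2(g, cond, ci=320.0, remodeling=rem,
                           post_s2_ms=1500.0)
        outc = met.classify_outcome(rec, rec.meta["s1_times"],
                                    rec.meta["s2_time"])
        out[arm] = (rec, outc)
    return out


@pytest.fixture(scope="session")
def sigma_sweep():
    """Conductivity-only sweep (ina = 1.0, FIB = 0) on the 400 um sheet."""
    spec = vul.SweepSpec(ina_scales=(1.0,),
                         sigma_scales=(1.0, 0.5, 0.25, 0.1),
                         fib_densities=(0.0,), h_um=400.0, post_s2_ms=800.0,
                         root_seed=TEST_ROOT_SEED)
    return vul.run_sweep(spec)


@pytest.fixture(scope="session")
def traversal_scan():
    """S1 isthmus-traversal outcomes at 50% and 55% fibrosis, 10 seeds each,
    on the reference 200 um sheet."""
    return vul.isthmus_traversal_scan([0.50, 0.55], n_seeds=10,
                                      root_seed=TEST_ROOT_SEED)


@pytest.fixture(scope="session")
def homogeneous_sheet_maps():
    """Field maps plus RVI for a planar wave on a homogeneous 2 x 1 cm
    sheet (200 um)."""
    g = geo.build_strip(20.0, 10.0, 200.0)
    cond = md.ConductivityField.from_grid(g)
    stim = md.StimulusSpec.left_edge(g, onsets=(0.0,))
    cfg = md.SimulationConfig(t_end=420.0, sample_interval=1.0)
    rec = md.run(g, cond, stimuli=[stim], config=cfg)
    maps = met.activation_repolarization_maps(rec, (0.0, 420.0))
    met.rvi_map(maps)
    return rec, maps


def assert_gates_valid(state) -> None:
    state.validate()  # raises on any gate/concentration violation
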