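"""Monodomain solver: operator structure, conservation, stability guard and
planar-wave behaviour."""

import numpy as np
import pytest
import scipy.sparse as sp

from conftest import strip_cv
from infarctsim import geometry as geo
from infarctsim import monodomain as md
from infarctsim.exceptions import ConfigurationError


@pytest.fixture(scope="module")
def small_grid():
    return geo.build_strip(4.0, 2.0, 200.0)


def test_operator_rows_sum_to_zero(small_grid):
    cond = md.ConductivityField.from_grid(small_grid)
    L = md.assemble_diffusion(small_grid, cond)
    assert np.abs(np.asarray(L.sum(axis=1))).max() < 1e-12


def test_flux_matrix_symmetric(small_grid):
    cond = md.ConductivityField.from_grid(small_grid)
    K = md.assemble_diffusion(small_grid, cond, lumped=False)
    assert sp.issparse(K)
    assert abs(K - K.T).max() == 0.0


def test_uniform_voltage_is_annihilated(small_grid):
    cond = md.ConductivityField.from_grid(small_grid)
    L = md.assemble_diffusion(small_grid, cond)
    v = np.full(L.shape[0], -83.4)
    assert np.abs(L @ v).max() < 1e-10


def test_1d_strip_matches_second_difference_stencil():
    """Interior rows of a homogeneous strip equal the classical
    D/h^2 * (1, -2, 1) stencil with D = sigma/(beta Cm) (calibration off)."""
    g = geo.build_strip(4.0, 2.0, 200.0)
    cond = md.ConductivityField.from_grid(g, sigma_healthy=0.143)
    L = md.assemble_diffusion(g, cond, calibration=1.0)
    d_over_h2 = 0.143 / (0.14 * 1.0 * 10.0) / (0.2 ** 2)
    nxn = g.nx + 1
    mid = (g.ny // 2) * nxn + g.nx // 2
    row = L.getrow(mid).toarray().ravel()
    assert row[mid] == pytest.approx(-4 * d_over_h2, rel=1e-12)
    assert row[mid - 1] == pytest.approx(d_over_h2, rel=1e-12)
    assert row[mid + 1] == pytest.approx(d_over_h2, rel=1e-12)


def test_nonconducting_element_blocks_flux_locally():
    """An inert element removes its conductivity from the surrounding faces
    only; the flux matrix stays symmetric with zero row sums."""
    g = geo.build_strip(4.0, 4.0, 200.0)
    cond = md.ConductivityField.from_grid(g)
    K0 = md.assemble_diffusion(g, cond, lumped=False)
    g2 = g.copy()
    g2.labels[10, 10] = geo.Label.SCAR
    cond2 = md.ConductivityField.from_grid(g2)
    K1 = md.assemble_diffusion(g2, cond2, lumped=False)
    diff = (K0 - K1).tocoo()
    assert abs(K1 - K1.T).max() == 0.0
    assert np.abs(np.asarray(K1.sum(axis=1))).max() < 1e-12
    # change confined to the 12 edges bordering the element (24 off-diagonal
    # entries) plus their diagonals
    touched_nodes = {r * (g.nx + 1) + c
                     for r in (10, 11) for c in (10, 11)}
    for r, c in zip(diff.row, diff.col):
        assert r in touched_nodes or c in touched_nodes


def test_isolated_node_evolves_by_reaction_only():
    """A node whose four faces are all blocked keeps zero edge weights."""
    g = geo.build_strip(2.0, 2.0, 200.0)
    # isolate the node at (5, 5) by making its four incident elements inert
    for r in (4, 5):
        for c in (4, 5):
            g.labels[r, c] = geo.Label.FIBROTIC
    cond = md.ConductivityField.from_grid(g)
    L = md.assemble_diffusion(g, cond)
    nid = 5 * (g.nx + 1) + 5
    assert L.getrow(nid).nnz == 0


def test_weighted_mean_conserved_by_pure_diffusion(small_grid):
    """Without reaction or stimulus, the volume-weighted spatial mean of Vm
    is invariant under the diffusion operator."""
    cond = md.ConductivityField.from_grid(small_grid)
    L = md.assemble_diffusion(small_grid, cond)
    vol = md.node_volume_fractions(small_grid).ravel()
    rng = np.random.default_rng(0)
    v = rng.normal(-80.0, 10.0, L.shape[0])
    m0 = float(vol @ v)
    dt = 0.01
    for _ in range(200):
        v = v + dt * (L @ v)
    assert float(vol @ v) == pytest.approx(m0, abs=1e-9 * abs(m0))


def test_stability_bound_enforced():
    g = geo.build_strip(4.0, 2.0, 100.0)
    cond = md.ConductivityField.from_grid(g)
    stim = md.StimulusSpec.left_edge(g, onsets=(0.0,))
    cfg = md.SimulationConfig(t_end=5.0, dt=0.05)  # bound ~0.02 ms at 100 um
    with pytest.raises(ConfigurationError, match="stability"):
        md.run(g, cond, stimuli=[stim], config=cfg)


def test_empty_stimulus_region_rejected(small_grid):
    cond = md.ConductivityField.from_grid(small_grid)
    stim = md.StimulusSpec(region=np.zeros(small_grid.shape_nodes, bool),
                           onsets=(0.0,))
    with pytest.raises(ConfigurationError):
        md.run(small_grid, cond, stimuli=[stim],
               config=md.SimulationConfig(t_end=5.0))


def test_rest_is_quiescent():
    """From the relaxed resting state with no stimulus, Vm drifts < 0.1 mV
    everywhere over 100 ms (rest is a fixed point up to drift)."""
    from infarctsim.cellmodel import CellParams, CellState, run_cell

    g = geo.build_strip(10.0, 2.0, 200.0)
    cond = md.ConductivityField.from_grid(g)
    _, _, rest = run_cell(CellState.resting(), CellParams(), 2000.0)
    n_active = int(g.active_nodes().sum())
    init = np.tile(rest.to_array(), (n_active, 1))
    cfg = md.SimulationConfig(t_end=100.0, sample_interval=10.0)
    rec = md.run(g, cond, stimuli=[], config=cfg, init=init)
    v = rec.vm[:, rec.active]
    assert np.nanmax(np.abs(v - v[0])) < 0.1


def test_mesh_refinement_sanity():
    """Halving the spacing changes planar CV by < 3% (asymptotic check at
    100 um -> 50 um; the reference 200 um grid carries the calibrated
    wavefront correction instead)."""
    kw = dict(width_mm=0.6, t_end=90.0, probes_mm=(5.0, 15.0))
    cv100 = strip_cv(0.143, h_um=100.0, dt=0.01, **kw)
    cv50 = strip_cv(0.143, h_um=50.0, dt=0.005, **kw)
    assert abs(cv50 - cv100) / cv100 < 0.03


def test_cv_decreases_with_ina():
    cvs = [strip_cv(0.143, gna_scale=s) for s in (1.0, 0.5, 0.3)]
    assert cvs[0] > cvs[1] > cvs[2]


def test_recording_subsample():
    g = geo.build_strip(4.0, 2.0, 200.0)
    cond = md.ConductivityField.from_grid(g)
    stim = md.StimulusSpec.left_edge(g, onsets=(0.0,))
    rec = md.run(g, cond, stimuli=[stim],
                 config=md.SimulationConfig(t_end=20.0))
    sub = rec.subsample(2)
    assert sub.times.size == (rec.times.size + 1) // 2
    np.testing.assert_array_equal(sub.vm[1], rec.vm[2])
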