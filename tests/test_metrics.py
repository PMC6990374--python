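"""Field maps, RVI arithmetic and outcome classification."""

import numpy as np
import pytest

from infarctsim import geometry as geo
from infarctsim import metrics as met
from infarctsim import monodomain as md
from infarctsim.exceptions import ConfigurationError


def _step_wave_recording(grid, cv_mm_ms=0.5, apd=300.0, t_end=500.0,
                         dt=2.0):
    """Synthetic rightward plane wave: node at x activates at x/cv and stays
    depolarized for ``apd`` ms."""
    times = np.arange(0.0, t_end, dt)
    x = grid.node_x_mm()[None, None, :]
    t = times[:, None, None]
    at = x / cv_mm_ms
    vm = np.where((t >= at) & (t < at + apd), 20.0, -86.0)
    vm = np.broadcast_to(vm, (times.size,) + grid.shape_nodes).astype(
        np.float32)
    return md.VmRecording(times=times, vm=vm.copy(), grid=grid,
                          active=grid.active_nodes())


@pytest.fixture(scope="module")
def step_maps():
    g = geo.build_strip(20.0, 2.0, 200.0)
    rec = _step_wave_recording(g)
    return met.activation_repolarization_maps(rec, (0.0, 500.0))


def test_step_wave_activation_linear_in_x(step_maps):
    """A 0.5 mm/ms rightward wave produces AT with slope 2 ms/mm."""
    at = step_maps.at[step_maps.grid.ny // 2]
    x = step_maps.grid.node_x_mm()
    sel = ~np.isnan(at)
    slope = np.polyfit(x[sel][5:-5], at[sel][5:-5], 1)[0]
    assert slope == pytest.approx(2.0, rel=0.02)


def test_step_wave_cv_readback(step_maps):
    row = step_maps.grid.ny // 2
    cv = met.conduction_velocity(step_maps, (row, 10), (row, 60))
    assert cv == pytest.approx(0.5, rel=0.02)


def test_conduction_velocity_noncausal_pair(step_maps):
    row = step_maps.grid.ny // 2
    with pytest.raises(ConfigurationError, match="non-causal"):
        met.conduction_velocity(step_maps, (row, 60), (row, 10))


def test_never_activated_nodes_masked():
    g = geo.build_strip(20.0, 2.0, 200.0)
    rec = _step_wave_recording(g, t_end=500.0)
    rec.vm[:, :, 60:] = -86.0  # wave never reaches x > 12 mm
    maps = met.activation_repolarization_maps(rec, (0.0, 500.0))
    assert np.all(np.isnan(maps.at[:, 61:]))
    assert np.all(np.isnan(maps.rt[:, 61:]))
    # column 0 is depolarized from the first sample (no crossing -> masked)
    assert not np.any(np.isnan(maps.at[:, 1:50]))


def _maps_from_fields(grid, at, rt):
    return met.FieldMaps(at=at, rt=rt, grid=grid, window=(0.0, 1.0))


def test_rvi_uniform_wave_resembles_apd():
    """For a plane wave with constant APD, RVI ~ APD minus the small
    proximal-to-distal activation delay."""
    g = geo.build_strip(20.0, 2.0, 200.0)
    x = g.node_x_mm()
    at = np.tile(2.0 * x, (g.ny + 1, 1))          # 0.5 mm/ms rightward
    rt = at + 300.0
    rvi = met.rvi_map(_maps_from_fields(g, at, rt), pairing_radius_mm=2.0)
    inner = rvi[:, 15:-15]
    assert np.nanmin(inner) >= 300.0 - 2.0 * 2.0 - 1e-9
    assert np.nanmax(inner) <= 300.0
    apd = (rt - at)[:, 15:-15]
    # the map tracks the APD distribution
    assert abs(np.nanmean(inner) - np.nanmean(apd)) < 5.0


@pytest.mark.parametrize("rt_p,at_d,expected", [
    (420.0, 400.0, 20.0),     # late proximal repolarization, small margin
    (420.0, 430.0, -10.0),    # distal excited before proximal recovered
])
def test_rvi_two_point_arithmetic(rt_p, at_d, expected):
    g = geo.build_strip(2.0, 0.4, 200.0)
    nyn, nxn = g.shape_nodes
    at = np.full((nyn, nxn), np.nan)
    rt = np.full((nyn, nxn), np.nan)
    at[1, 4], rt[1, 4] = 100.0, rt_p          # proximal node
    at[1, 5] = at_d                            # distal neighbor
    rvi = met.rvi_map(_maps_from_fields(g, at, rt), pairing_radius_mm=0.4)
    assert rvi[1, 5] == pytest.approx(expected)
    assert np.isnan(rvi[1, 4])  # no earlier-activated neighbor


def test_rvi_rejects_tiny_radius():
    g = geo.build_strip(2.0, 0.4, 200.0)
    maps = _maps_from_fields(g, np.zeros(g.shape_nodes),
                             np.zeros(g.shape_nodes))
    with pytest.raises(ConfigurationError):
        met.rvi_map(maps, pairing_radius_mm=0.1)


def test_upward_crossings_hysteresis():
    """Sub-threshold wiggle across the -20 mV line is one activation, not
    two; a full repolarization re-arms the detector."""
    g = geo.build_strip(1.0, 0.4, 200.0)
    seq = [-86, -30, -15, -25, -10, 10, -30, -15, -70, -86, 15, -86]
    times = np.arange(len(seq), dtype=float)
    vm = np.tile(np.array(seq, np.float32)[:, None, None],
                 (1,) + g.shape_nodes)
    rec = md.VmRecording(times=times, vm=vm, grid=g,
                         active=g.active_nodes())
    t = met.upward_crossing_times(rec, (1, 1))
    assert t.size == 2


def test_outcome_invariant_sustained_iff_multiple_cycles():
    with pytest.raises(ValueError):
        met.Outcome(category=met.OutcomeClass.REENTRY_SUSTAINED, n_cycles=1)
    with pytest.raises(ValueError):
        met.Outcome(category=met.OutcomeClass.REENTRY_NONSUSTAINED,
                    n_cycles=2)
    met.Outcome(category=met.OutcomeClass.REENTRY_SUSTAINED, n_cycles=3)


# ---------------------------------------------------------------------------
# simulated planar wave on tissue (electrotonic uniformity, RVI ~ APD)
# ---------------------------------------------------------------------------

def test_planar_wave_apd_spatially_uniform(homogeneous_sheet_maps):
    """Electrotonic coupling keeps the APD spread below 5 ms in homogeneous
    tissue."""
    _, maps = homogeneous_sheet_maps
    interior = maps.apd[5:-5, 10:-10]
    assert np.nanstd(interior) < 5.0


def test_planar_wave_rvi_resembles_apd(homogeneous_sheet_maps):
    """During uncomplicated propagation min RVI >= 0 and the RVI sits just
    below the APD (by at most the pairing-delay, ~2 mm / CV)."""
    _, maps = homogeneous_sheet_maps
    rvi = maps.rvi[5:-5, 10:-10]
    apd = maps.apd[5:-5, 10:-10]
    assert np.nanmin(rvi) >= 0.0
    diff = apd - rvi
    assert 0.0 <= np.nanmean(diff) < 6.0   # 2 mm / 0.6 mm/ms ~ 3.3 ms
    assert np.nanmax(np.abs(diff)) < 12.0


@pytest.fixture(scope="module")
def heterogeneous_apd_maps():
    """Planar wave across a strip with a 10 mm prolonged-APD band: the APD
    distribution has genuine spatial structure."""
    from infarctsim.cellmodel import RemodelingSpec

    g = geo.build_strip(30.0, 6.0, 200.0)
    xc = (np.arange(g.nx) + 0.5) * g.h_mm
    g.labels[:, (xc >= 10.0) & (xc < 20.0)] = geo.Label.BZ
    cond = md.ConductivityField.from_grid(g)
    stim = md.StimulusSpec.left_edge(g, onsets=(0.0,))
    rec = md.run(g, cond, remodeling=RemodelingSpec(mode="prolonged_apd"),
                 stimuli=[stim], config=md.SimulationConfig(t_end=560.0))
    maps = met.activation_repolarization_maps(rec, (0.0, 560.0))
    met.rvi_map(maps)
    return maps


def test_rvi_map_correlates_with_apd_distribution(heterogeneous_apd_maps):
    """Where the APD distribution varies (remodeled band), the RVI map
    mirrors it: Pearson r > 0.9 during normal propagation."""
    maps = heterogeneous_apd_maps
    rvi = maps.rvi[3:-3, 12:-12]
    apd = maps.apd[3:-3, 12:-12]
    sel = ~(np.isnan(rvi) | np.isnan(apd))
    assert np.nanmax(apd) - np.nanmin(apd) > 30.0  # real structure
    r = np.corrcoef(rvi[sel], apd[sel])[0, 1]
    assert r > 0.9


def test_rvi_pairing_radius_insensitivity(heterogeneous_apd_maps,
                                          mechanism_runs):
    """RVI stays positive under normal propagation for pairing radii 1-4 mm,
    and the block/re-entry classification of the mechanism runs does not
    depend on the radius."""
    maps = heterogeneous_apd_maps
    for radius in (1.0, 2.0, 4.0):
        rvi = met.rvi_map(met.FieldMaps(at=maps.at, rt=maps.rt,
                                        grid=maps.grid, window=maps.window),
                          pairing_radius_mm=radius)
        assert np.nanmin(rvi) >= 0.0
    for _arm, (rec, ref) in mechanism_runs.items():
        for radius in (1.0, 4.0):
            out = met.classify_outcome(rec, rec.meta["s1_times"],
                                       rec.meta["s2_time"],
                                       pairing_radius_mm=radius)
            assert out.category == ref.category


def test_negative_rvi_iff_reentry(mechanism_runs, sigma_sweep):
    """Cross-validation of the two detectors: re-entrant runs have negative
    minimum RVI; uncomplicated conduction keeps it positive."""
    for _arm, (_rec, out) in mechanism_runs.items():
        assert out.n_cycles >= 1
        assert out.min_rvi < 0.0
    no_block = sigma_sweep[sigma_sweep.outcome == "NO_BLOCK"]
    assert (no_block.min_rvi > 0.0).all()
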