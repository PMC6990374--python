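"""Single-cell ionic model: resting stability, AP morphology, pacing,
APD measurement and remodeling effects."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from infarctsim import cellmodel as cm
from infarctsim.exceptions import IntegrationError, NoCaptureError


@pytest.fixture(scope="module")
def settled_rest():
    """Quiescent state after 2 s without stimulation (true resting point)."""
    _, _, state = cm.run_cell(cm.CellState.resting(), cm.CellParams(), 2000.0)
    return state


def test_resting_state_stable(settled_rest):
    """1000 unstimulated steps drift the membrane by < 0.01 mV."""
    s = settled_rest
    v0 = s.vm
    p = cm.CellParams()
    for _ in range(1000):
        s = cm.step_cell(s, p, istim=0.0, dt=0.02)
    assert abs(s.vm - v0) < 0.01


def test_identity_scaling(settled_rest):
    """Multipliers of 1.0 reproduce the unscaled model exactly."""
    p_default = cm.CellParams()
    p_explicit = cm.CellParams(gna_scale=1.0, gkr_scale=1.0, gks_scale=1.0)
    a = cm.step_cell(settled_rest, p_default, istim=30.0, dt=0.02)
    b = cm.step_cell(settled_rest, p_explicit, istim=30.0, dt=0.02)
    np.testing.assert_array_equal(a.to_array(), b.to_array())


def test_action_potential_fires(settled_rest):
    """A 100 uA/cm^2 x 1 ms pulse drives Vm above 0 mV within 5 ms."""
    t, vm, _ = cm.run_cell(settled_rest, cm.CellParams(), 6.0,
                           stim_start=0.0, stim_dur=1.0, stim_amp=100.0,
                           sample_interval=0.1)
    assert vm.max() > 0.0
    assert t[np.argmax(vm > 0.0)] < 5.0


def test_gates_bounded_under_random_stimulation(settled_rest):
    """Gating variables stay in [0, 1] under an arbitrary stimulus train."""
    rng = np.random.default_rng(7)
    s = settled_rest
    p = cm.CellParams()
    for _ in range(40):
        amp = float(rng.uniform(-30.0, 120.0))
        dur = float(rng.uniform(0.5, 4.0))
        for _ in range(int(dur / 0.02)):
            s = cm.step_cell(s, p, istim=amp, dt=0.02)  # validates each step
    s.validate()


def test_step_cell_rejects_nonfinite_state(settled_rest):
    bad = cm.CellState(vm=np.nan, eta=settled_rest.eta.copy())
    with pytest.raises(IntegrationError, match="vm"):
        cm.step_cell(bad, cm.CellParams(), 0.0, 0.02)


def test_step_cell_rejects_bad_dt(settled_rest):
    with pytest.raises(ValueError):
        cm.step_cell(settled_rest, cm.CellParams(), 0.0, 0.5)


# ---------------------------------------------------------------------------
# measure_apd
# ---------------------------------------------------------------------------

def _square_pulse(t_on=10.0, t_off=310.0, t_end=400.0, dt=1.0,
                  lo=-86.0, hi=40.0):
    t = np.arange(0.0, t_end, dt)
    vm = np.where((t >= t_on) & (t < t_off), hi, lo)
    return t, vm


def test_measure_apd_square_pulse():
    t, vm = _square_pulse()
    apd = cm.measure_apd(t, vm, 0.9)
    assert apd.size == 1
    assert apd[0] == pytest.approx(300.0, abs=2.0)


def test_measure_apd_two_identical_pulses():
    t1, v1 = _square_pulse()
    t2, v2 = _square_pulse()
    t = np.concatenate([t1, t2 + 400.0])
    vm = np.concatenate([v1, v2])
    apd = cm.measure_apd(t, vm)
    assert apd.size == 2
    assert apd[0] == pytest.approx(apd[1], abs=1e-9)


def test_measure_apd_no_upstroke_returns_empty():
    t = np.arange(0.0, 100.0)
    assert cm.measure_apd(t, np.full_like(t, -86.0)).size == 0


def test_measure_apd_rejects_bad_fraction():
    t, vm = _square_pulse()
    with pytest.raises(ValueError):
        cm.measure_apd(t, vm, repolarization_fraction=1.5)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(width=st.floats(20.0, 350.0), start=st.floats(5.0, 40.0),
       hi=st.floats(0.0, 45.0), frac=st.floats(0.5, 0.95))
def test_measure_apd_recovers_pulse_width(width, start, hi, frac):
    """For any square pulse the measured duration equals the pulse width to
    within one sample, at every repolarization fraction."""
    t, vm = _square_pulse(t_on=start, t_off=start + width,
                          t_end=start + width + 50.0, lo=-86.0, hi=hi)
    apd = cm.measure_apd(t, vm, repolarization_fraction=frac)
    assert apd.size == 1
    assert apd[0] == pytest.approx(width, abs=2.0)


# ---------------------------------------------------------------------------
# pacing
# ---------------------------------------------------------------------------

def test_pace_to_steady_converges():
    """At 2 Hz the APD of beats 99 and 100 agree to < 1 ms."""
    res = cm.pace_to_steady(cm.CellParams(), frequency=2.0, n_beats=100)
    assert abs(res.apd_per_beat[-1] - res.apd_per_beat[-2]) < 1.0
    # endocardial APD90 at 2 Hz lies in the published ballpark
    assert 240.0 < res.apd_per_beat[-1] < 320.0
    res.state.validate()


def test_pace_single_beat():
    res = cm.pace_to_steady(cm.CellParams(), n_beats=1)
    assert res.apd_per_beat.size == 1
    assert np.isfinite(res.apd_per_beat[0])


def test_no_capture_error_reports_beat():
    with pytest.raises(NoCaptureError) as err:
        cm.pace_to_steady(cm.CellParams(), n_beats=2, stim_amp=1.0)
    assert err.value.beat == 1


def test_prolonged_apd_remodeling_lengthens_apd():
    control = cm.pace_to_steady(cm.CellParams(), n_beats=60)
    rem = cm.RemodelingSpec(mode="prolonged_apd")
    assert rem.gkr_scale == 0.20 and rem.gks_scale == 0.30
    prolonged = cm.pace_to_steady(rem.cell_params(), n_beats=60)
    assert prolonged.apd_per_beat[-1] > control.apd_per_beat[-1] + 30.0


def test_apd_monotone_in_repolarizing_conductances():
    """Steady APD grows as the IKr/IKs conductances shrink (3 levels)."""
    apds = []
    for gkr, gks in [(1.0, 1.0), (0.6, 0.65), (0.2, 0.3)]:
        res = cm.pace_to_steady(
            cm.CellParams(gkr_scale=gkr, gks_scale=gks), n_beats=60)
        apds.append(float(res.apd_per_beat[-1]))
    assert apds[0] < apds[1] < apds[2]


def test_upstroke_velocity_monotone_in_ina():
    """Max dVm/dt during the upstroke falls as the INa scale falls."""
    vmax = []
    for ina in (1.0, 0.5, 0.25):
        params = cm.CellParams(gna_scale=ina)
        start = cm.pace_to_steady(params, n_beats=30).state
        t, vm, _ = cm.run_cell(start, params, 20.0, stim_start=2.0,
                               stim_dur=1.0, stim_amp=100.0,
                               sample_interval=0.05, dt=0.02)
        vmax.append(cm.max_upstroke_velocity(t, vm))
    assert vmax[0] > vmax[1] > vmax[2]


def test_remodeling_spec_validation():
    with pytest.raises(ValueError):
        cm.RemodelingSpec(mode="nonsense")
    with pytest.raises(ValueError):
        cm.RemodelingSpec(mode="reduced_ina", ina_scale=0.0)
    spec = cm.RemodelingSpec(mode="prolonged_apd", gkr_scale=0.9)
    assert spec.gkr_scale == 0.20  # mode forces the published fractions
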