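"""Single-cell ventricular myocyte model (ten Tusscher-Panfilov 2006,
endocardial variant) with border-zone remodeling.

Two remodeling phenotypes of the infarct border zone are supported:

* ``prolonged_apd`` -- the rapid and slow delayed-rectifier potassium
  conductances (IKr, IKs) are reduced to 20% and 30% of control, prolonging
  the action potential.
* ``reduced_ina``   -- the fast sodium conductance is scaled by a factor in
  (0, 1], reducing excitability and upstroke velocity (and, in tissue,
  conduction velocity) without prolonging the action potential.

Voltage is integrated by forward Euler, Hodgkin-Huxley gates by the
Rush-Larsen exponential update, and concentrations by forward Euler, all at a
shared time step (0.02 ms default).  Voltage-dependent rates are tabulated
(0.05 mV resolution) with linear interpolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels as K
from .exceptions import IntegrationError, NoCaptureError

__all__ = [
    "CellState", "CellParams", "RemodelingSpec", "PacingResult",
    "step_cell", "run_cell", "pace_to_steady", "measure_apd",
    "STATE_NAMES", "MODEL_VARIANT",
]

STATE_NAMES = K.STATE_NAMES
#: Ionic model variant recorded in configs and output metadata.
MODEL_VARIANT = "tentusscher_panfilov_2006_endo"

#: Indices of gating variables (bounded in [0, 1]) within the state vector.
GATE_INDICES = tuple(range(1, 13)) + (18,)
#: Indices of ionic concentrations (strictly positive, mM).
CONCENTRATION_INDICES = (13, 14, 15, 16, 17)


@dataclass
class CellState:
    """Membrane voltage plus the gating/concentration vector of the TT model.

    ``eta`` holds the 18 non-voltage state variables in the order of
    ``STATE_NAMES[1:]``.
    """

    vm: float
    eta: np.ndarray

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "CellState":
        arr = np.asarray(arr, dtype=np.float64)
        if arr.shape != (K.N_STATE,):
            raise ValueError(f"state vector must have {K.N_STATE} entries")
        return cls(vm=float(arr[0]), eta=arr[1:].copy())

    def to_array(self) -> np.ndarray:
        out = np.empty(K.N_STATE, dtype=np.float64)
        out[0] = self.vm
        out[1:] = self.eta
        return out

    def validate(self) -> None:
        arr = self.to_array()
        if not np.all(np.isfinite(arr)):
            bad = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise IntegrationError(
                f"non-finite state variable '{STATE_NAMES[bad]}'")
        for g in GATE_INDICES:
            if not (-1e-9 <= arr[g] <= 1.0 + 1e-9):
                raise IntegrationError(
                    f"gating variable '{STATE_NAMES[g]}' out of [0, 1]: {arr[g]}")
        for c in CONCENTRATION_INDICES:
            if arr[c] <= 0:
                raise IntegrationError(
                    f"concentration '{STATE_NAMES[c]}' not positive: {arr[c]}")

    @classmethod
    def resting(cls) -> "CellState":
        """Published resting initial conditions (not the paced steady state)."""
        return cls.from_array(K.INITIAL_STATE)


@dataclass(frozen=True)
class CellParams:
    """Per-current conductance multipliers and membrane capacitance.

    ``cm`` is the tissue membrane capacitance per unit area (uF/cm^2); it
    converts the stimulus current density (uA/cm^2) to the per-capacitance
    units (pA/pF) of the ionic model and enters the conductivity-to-
    diffusivity conversion of the tissue solver.
    """

    gna_scale: float = 1.0
    gkr_scale: float = 1.0
    gks_scale: float = 1.0
    cm: float = 1.0
    subtype: str = "endocardial"

    def __post_init__(self):
        for name in ("gna_scale", "gkr_scale", "gks_scale"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.cm <= 0:
            raise ValueError("cm must be > 0")
        if self.subtype != "endocardial":
            raise ValueError("only the endocardial parameter set is implemented")


REMODELING_MODES = ("none", "prolonged_apd", "reduced_ina", "combined")

#: IKr / IKs conductance fractions of the prolonged-APD border-zone phenotype.
PROLONGED_APD_GKR = 0.20
PROLONGED_APD_GKS = 0.30


@dataclass(frozen=True)
class RemodelingSpec:
    """Which border-zone electrophysiological phenotype to apply."""

    mode: str = "none"
    ina_scale: float = 1.0
    gkr_scale: float = 1.0
    gks_scale: float = 1.0

    def __post_init__(self):
        if self.mode not in REMODELING_MODES:
            raise ValueError(f"mode must be one of {REMODELING_MODES}")
        if not (0.0 < self.ina_scale <= 1.0):
            raise ValueError("ina_scale must lie in (0, 1]")
        if self.mode in ("prolonged_apd", "combined"):
            object.__setattr__(self, "gkr_scale", PROLONGED_APD_GKR)
            object.__setattr__(self, "gks_scale", PROLONGED_APD_GKS)
        if self.mode in ("none", "prolonged_apd"):
            object.__setattr__(self, "ina_scale", 1.0)

    def cell_params(self, base: CellParams | None = None) -> CellParams:
        base = base or CellParams()
        if self.mode == "none":
            return base
        return replace(
            base,
            gna_scale=base.gna_scale * self.ina_scale,
            gkr_scale=base.gkr_scale * self.gkr_scale,
            gks_scale=base.gks_scale * self.gks_scale,
        )


def _check_dt(dt: float) -> None:
    if not (0.0 < dt <= 0.1):
        raise ValueError("dt must lie in (0, 0.1] ms")


def step_cell(state: CellState, params: CellParams, istim: float,
              dt: float) -> CellState:
    """Advance one cell by ``dt`` ms under stimulus ``istim`` (uA/cm^2)."""
    _check_dt(dt)
    state.validate()
    tab, xk1 = K.get_rate_tables(dt)
    S = state.to_array().reshape(1, -1)
    K._cell_update(S, 0, params.gna_scale, params.gkr_scale, params.gks_scale,
                   istim / params.cm, 0.0, dt, tab, xk1)
    out = CellState.from_array(S[0])
    out.validate()
    return out


def run_cell(state: CellState, params: CellParams, duration: float,
             stim_start: float = 0.0, stim_dur: float = 0.0,
             stim_amp: float = 0.0, dt: float = 0.02,
             sample_interval: float = 1.0) -> tuple[np.ndarray, np.ndarray, CellState]:
    """Free-run a cell with one optional stimulus pulse.

    Returns ``(times_ms, vm_mV, final_state)`` with Vm sampled every
    ``sample_interval`` ms (starting at t = 0).
    """
    _check_dt(dt)
    tab, xk1 = K.get_rate_tables(dt)
    n_steps = int(round(duration / dt))
    stride = max(1, int(round(sample_interval / dt)))
    nrec = (n_steps + stride - 1) // stride
    vm_out = np.empty(nrec, dtype=np.float64)
    S = state.to_array().reshape(1, -1)
    K.run_single(S, params.gna_scale, params.gkr_scale, params.gks_scale, dt,
                 n_steps, stim_start, stim_dur, stim_amp / params.cm,
                 vm_out, stride, tab, xk1)
    times = np.arange(nrec) * stride * dt
    final = CellState.from_array(S[0])
    final.validate()
    return times, vm_out, final


@dataclass
class PacingResult:
    """Steady-pacing outcome: final state plus the per-beat APD trace."""

    state: CellState
    apd_per_beat: np.ndarray = field(default_factory=lambda: np.empty(0))
    times: np.ndarray | None = None
    vm: np.ndarray | None = None


_STEADY_CACHE: dict[tuple, PacingResult] = {}


def pace_to_steady(params: CellParams | None = None, frequency: float = 2.0,
                   n_beats: int = 100, stim_amp: float = 100.0,
                   stim_dur: float = 1.0, dt: float = 0.02,
                   record_last: int = 2) -> PacingResult:
    """Pace a single cell to its periodic steady state.

    Defaults follow the tissue-initialization protocol: 2.0 Hz for 100 cycles
    with a 100 uA/cm^2, 1 ms stimulus.  The Vm trace of the last
    ``record_last`` beats is kept (0.1 ms sampling) and the APD90 of every
    beat is returned for diagnostics.  Results are cached per parameter set.

    Raises :class:`NoCaptureError` (with the beat index) if a beat fails to
    reach 0 mV.
    """
    params = params or CellParams()
    if frequency <= 0:
        raise ValueError("frequency must be > 0")
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    _check_dt(dt)
    key = (params.gna_scale, params.gkr_scale, params.gks_scale, params.cm,
           frequency, n_beats, stim_amp, stim_dur, dt, record_last)
    if key in _STEADY_CACHE:
        return _STEADY_CACHE[key]

    tab, xk1 = K.get_rate_tables(dt)
    bcl = 1000.0 / frequency
    stride = max(1, int(round(0.1 / dt)))
    steps_per_beat = int(round(bcl / dt))
    samples_per_beat = (steps_per_beat + stride - 1) // stride
    vm_all = np.empty(samples_per_beat * n_beats, dtype=np.float64)

    S = K.INITIAL_STATE.copy().reshape(1, -1)
    K.pace_single(S, params.gna_scale, params.gkr_scale, params.gks_scale, dt,
                  bcl, n_beats, stim_amp / params.cm, stim_dur, vm_all, stride,
                  tab, xk1)

    sample_dt = stride * dt
    apds = np.full(n_beats, np.nan)
    for b in range(n_beats):
        seg = vm_all[b * samples_per_beat:(b + 1) * samples_per_beat]
        if seg.max() < 0.0:
            raise NoCaptureError(f"beat {b + 1} failed to capture", beat=b + 1)
        t = np.arange(seg.size) * sample_dt
        vals = measure_apd(t, seg)
        if vals.size:
            apds[b] = vals[0]

    keep = min(record_last, n_beats)
    tail = vm_all[(n_beats - keep) * samples_per_beat:]
    times = np.arange(tail.size) * sample_dt
    final = CellState.from_array(S[0])
    final.validate()
    result = PacingResult(state=final, apd_per_beat=apds, times=times, vm=tail)
    _STEADY_CACHE[key] = result
    return result


def measure_apd(times: np.ndarray, vm: np.ndarray,
                repolarization_fraction: float = 0.9) -> np.ndarray:
    """Action potential duration(s) of a Vm trace.

    APD is measured at the level ``Vrest + (1 - fraction) * (Vpeak - Vrest)``
    (APD90 for the default fraction 0.9), from the upward to the next
    downward crossing, with linear interpolation between samples.  Returns one
    duration per complete beat; an empty array if no upstroke is present.
    """
    if not (0.0 < repolarization_fraction < 1.0):
        raise ValueError("repolarization_fraction must lie in (0, 1)")
    times = np.asarray(times, dtype=np.float64)
    vm = np.asarray(vm, dtype=np.float64)
    if times.shape != vm.shape or vm.ndim != 1:
        raise ValueError("times and vm must be equal-length 1-D arrays")
    vrest = float(vm.min())
    vpeak = float(vm.max())
    if vpeak - vrest < 10.0:  # no depolarization worth calling a beat
        return np.empty(0)
    level = vrest + (1.0 - repolarization_fraction) * (vpeak - vrest)

    above = vm > level
    flips = np.flatnonzero(above[1:] != above[:-1])
    apds = []
    t_up = None
    for idx in flips:
        # crossing between samples idx and idx+1, linear interpolation
        v0, v1 = vm[idx], vm[idx + 1]
        frac = (level - v0) / (v1 - v0)
        t_cross = times[idx] + frac * (times[idx + 1] - times[idx])
        if not above[idx]:  # upward crossing
            t_up = t_cross
        elif t_up is not None:  # downward crossing closing a beat
            apds.append(t_cross - t_up)
            t_up = None
    return np.asarray(apds)


def max_upstroke_velocity(times: np.ndarray, vm: np.ndarray) -> float:
    """Maximal dVm/dt (mV/ms) over a trace; requires uniform sampling."""
    dt = float(times[1] - times[0])
    return float(np.max(np.diff(vm)) / dt)
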