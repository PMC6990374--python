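"""S1-S2 pacing orchestration, capture detection and coupling-interval
search.

The vulnerability protocol paces the tissue with three S1 beats at a basic
cycle length of 500 ms followed by one premature S2 delivered at the same
electrode; the S2 coupling interval is shortened from 500 ms in 10 ms steps
until propagation failure.  Tissue is initialized from the 2 Hz / 100-beat
single-cell steady state of each region's cell variant (control for healthy
tissue, remodeled for the border zone), after which the S1 train equilibrates
tissue-level coupling.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .cellmodel import CellParams, RemodelingSpec
from .exceptions import ConfigurationError, ProtocolError
from .geometry import TissueGrid
from .metrics import ACTIVATION_THRESHOLD
from .monodomain import (ConductivityField, SimulationConfig, StimulusSpec,
                         VmRecording, initial_states, run)

__all__ = ["S1S2Spec", "run_s1s2", "detect_capture", "find_min_capture_ci",
           "distal_probe"]

#: Default S2 coupling interval (ms) for the vulnerability experiments: the
#: shortest interval that still captures healthy myocardium.
DEFAULT_CI = 320.0


@dataclass(frozen=True)
class S1S2Spec:
    """S1-S2 protocol parameters."""

    n_s1: int = 3
    bcl: float = 500.0          #: basic cycle length, ms
    ci_start: float = 500.0     #: first tested coupling interval, ms
    ci_step: float = 10.0       #: decrement, ms
    ci_floor: float = 150.0     #: search cutoff, ms
    amplitude: float = 100.0    #: uA/cm^2
    duration: float = 1.0       #: ms
    electrode: str = "bottom"   #: "bottom" (sheets) or "left" (strips)
    electrode_depth_mm: float = 0.4

    def __post_init__(self):
        if self.ci_step <= 0:
            raise ConfigurationError("ci_step must be > 0")
        if self.ci_start > self.bcl:
            raise ConfigurationError("ci_start must not exceed bcl")
        if self.n_s1 < 1:
            raise ConfigurationError("n_s1 must be >= 1")
        if self.electrode not in ("bottom", "left"):
            raise ConfigurationError("electrode must be 'bottom' or 'left'")

    def electrode_spec(self, grid: TissueGrid,
                       onsets: tuple[float, ...]) -> StimulusSpec:
        factory = (StimulusSpec.bottom_edge if self.electrode == "bottom"
                   else StimulusSpec.left_edge)
        return factory(grid, depth_mm=self.electrode_depth_mm,
                       amplitude=self.amplitude, duration=self.duration,
                       onsets=onsets)

    @property
    def s1_onsets(self) -> tuple[float, ...]:
        return tuple(i * self.bcl for i in range(self.n_s1))

    def s2_time(self, ci: float) -> float:
        return (self.n_s1 - 1) * self.bcl + ci


def distal_probe(grid: TissueGrid, electrode: str = "bottom",
                 band_mm: float = 1.0) -> np.ndarray:
    """Active nodes within ``band_mm`` of the sheet edge opposite the
    electrode (capture is scored here)."""
    nyn, nxn = grid.shape_nodes
    band = max(1, int(round(band_mm / grid.h_mm)))
    probe = np.zeros((nyn, nxn), dtype=bool)
    if electrode == "bottom":
        probe[-band:, :] = True
    else:
        probe[:, -band:] = True
    return probe & grid.active_nodes()


def detect_capture(rec: VmRecording, stim_time: float,
                   probe: np.ndarray, window_ms: float = 150.0,
                   threshold: float = ACTIVATION_THRESHOLD) -> bool:
    """True iff every probe node crosses ``threshold`` upward within
    ``window_ms`` after ``stim_time``."""
    if not probe.any():
        raise ConfigurationError("empty capture probe")
    sl = (rec.times >= stim_time) & (rec.times <= stim_time + window_ms)
    v = rec.vm[sl][:, probe].astype(np.float64)
    if v.shape[0] < 2:
        return False
    above = v > threshold
    up = (above[1:] & ~above[:-1]).any(axis=0)
    return bool(up.all())


def run_s1s2(grid: TissueGrid, cond: ConductivityField, ci: float = DEFAULT_CI,
             spec: S1S2Spec | None = None,
             remodeling: RemodelingSpec | None = None,
             params: CellParams | None = None,
             config: SimulationConfig | None = None,
             post_s2_ms: float = 1500.0,
             check_s1_capture: bool = True,
             init: np.ndarray | str = "steady",
             stop_when=None) -> VmRecording:
    """Run the full S1-S2 protocol and record through ``post_s2_ms`` beyond
    the S2 beat (long enough to observe re-entrant cycles).

    Raises :class:`ProtocolError` if the first S1 fails to capture the
    healthy myocardium (checked at the distal probe).
    """
    spec = spec or S1S2Spec()
    remodeling = remodeling or RemodelingSpec()
    params = params or CellParams()
    config = config or SimulationConfig()
    s2 = spec.s2_time(ci)
    config = replace(config, t_end=s2 + post_s2_ms)

    stim = spec.electrode_spec(grid, spec.s1_onsets + (s2,))
    rec = run(grid, cond, params=params, remodeling=remodeling,
              stimuli=[stim], config=config, init=init, stop_when=stop_when)
    rec.meta["s1_times"] = spec.s1_onsets
    rec.meta["s2_time"] = s2
    rec.meta["ci"] = ci

    if check_s1_capture:
        probe = distal_probe(grid, spec.electrode)
        if not detect_capture(rec, spec.s1_onsets[0], probe,
                              window_ms=min(150.0, spec.bcl)):
            raise ProtocolError("S1 no-capture: first S1 did not reach the "
                                "distal probe")
    return rec


def find_min_capture_ci(grid: TissueGrid, cond: ConductivityField,
                        spec: S1S2Spec | None = None,
                        remodeling: RemodelingSpec | None = None,
                        params: CellParams | None = None,
                        config: SimulationConfig | None = None,
                        capture_window_ms: float = 150.0,
                        outcomes: dict[float, bool] | None = None
                        ) -> float | None:
    """Smallest tested S2 coupling interval that still captures.

    The S1 train is simulated once; the post-train evolution is then
    check-pointed at every candidate S2 time, and each candidate interval is
    tested by restarting from its checkpoint with the S2 stimulus.  The
    search decrements from ``ci_start`` and stops at the first failure
    (capture is monotone in the interval; this is asserted as the search
    proceeds).  Returns None if even ``ci_start`` fails.
    """
    spec = spec or S1S2Spec()
    remodeling = remodeling or RemodelingSpec()
    params = params or CellParams()
    config = config or SimulationConfig()
    probe = distal_probe(grid, spec.electrode)

    candidates = np.arange(spec.ci_start, spec.ci_floor - 1e-9, -spec.ci_step)
    t_base = (spec.n_s1 - 1) * spec.bcl

    # phase 1: S1 train up to the last S1 beat
    s1 = spec.electrode_spec(grid, spec.s1_onsets)
    cfg1 = replace(config, t_end=t_base, sample_interval=spec.bcl / 2)
    rec = run(grid, cond, params=params, remodeling=remodeling, stimuli=[s1],
              config=cfg1, init="steady")
    states = rec.meta["final_states"]

    # phase 2: checkpoint the unstimulated evolution at each candidate S2 time
    snaps: dict[float, np.ndarray] = {}
    t_cursor = 0.0  # relative to t_base; the last S1 fires at offset 0
    last_s1 = spec.electrode_spec(grid, (0.0,))
    for ci in sorted(candidates):
        dt_seg = ci - t_cursor
        stimuli = [last_s1] if t_cursor == 0.0 else []
        cfg2 = replace(config, t_end=dt_seg, sample_interval=dt_seg)
        seg = run(grid, cond, params=params, remodeling=remodeling,
                  stimuli=stimuli, config=cfg2, init=states)
        states = seg.meta["final_states"]
        snaps[float(ci)] = states.copy()
        t_cursor = ci

    # phase 3: decrement the coupling interval until propagation failure
    s2 = spec.electrode_spec(grid, (0.0,))
    cfg3 = replace(config, t_end=capture_window_ms + 10.0,
                   sample_interval=min(config.sample_interval, 1.0))
    last_captured: float | None = None
    for ci in candidates:
        trial = run(grid, cond, params=params, remodeling=remodeling,
                    stimuli=[s2], config=cfg3, init=snaps[float(ci)])
        captured = detect_capture(trial, 0.0, probe,
                                  window_ms=capture_window_ms)
        if outcomes is not None:
            outcomes[float(ci)] = captured
        if captured:
            last_captured = float(ci)
        else:
            if last_captured is None and ci == spec.ci_start:
                return None
            break
    return last_captured
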