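"""Explicit finite-difference monodomain solver on the regular element grid.

The transmembrane voltage obeys the monodomain reaction-diffusion equation

    beta Cm dVm/dt = div(sigma grad Vm) - beta (Iion - Istim)

discretized node-based with a flux-conservative 5-point stencil.  Each edge
between adjacent nodes carries the mean conductivity of its two flanking
elements, with non-conducting (scar/fibrotic) elements and the sheet exterior
contributing zero -- homogeneous Neumann (no-flux) conditions at the sheet
boundary and at every internal scar/fibrosis interface.  Each node's rate of
change is the net face flux divided by its conducting control-volume fraction
(the finite-volume analogue of a lumped finite-element mass matrix), so a
plane wave travels at the same speed along a no-flux boundary as in the bulk.
Diffusion is advanced by forward Euler at the same time step as the reaction
(Rush-Larsen membrane update), avoiding splitting-order artifacts.

The conductivity-to-diffusivity conversion is D = sigma / (beta * Cm), scaled
by a single dimensionless calibration factor chosen so that a plane wave in
healthy tissue at sigma = 0.143 S/m travels at 0.6 m/s on the default
200 um / 0.02 ms discretization (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.sparse as sp

from . import _kernels as K
from .cellmodel import CellParams, RemodelingSpec, pace_to_steady
from .exceptions import ConfigurationError, IntegrationError, NoCaptureError
from .geometry import Label, TissueGrid

__all__ = [
    "ConductivityField", "StimulusSpec", "SimulationConfig", "VmRecording",
    "assemble_diffusion", "run", "SIGMA_HEALTHY", "SIGMA_REDUCED",
    "CV_CALIBRATION",
]

#: Isotropic tissue conductivity of healthy 2-D myocardium (S/m), calibrated
#: in the source experiments to a 0.6 m/s planar conduction velocity.
SIGMA_HEALTHY = 0.143
#: Reduced conductivity producing 0.4 m/s (transverse-equivalent).
SIGMA_REDUCED = 0.064

#: Dimensionless adjustment of the sigma -> diffusivity conversion such that
#: the default 200 um / 0.02 ms discretization reproduces the stated planar
#: conduction velocities (0.6 m/s at 0.143 S/m, 0.4 m/s at 0.064 S/m) as
#: closely as a single factor allows; it absorbs the unstated membrane
#: capacitance and the finite-h wavefront error of the 5-point stencil.
#: See docs/methods.md for the calibration procedure.
CV_CALIBRATION = 1.193


@dataclass
class ConductivityField:
    """Per-element isotropic conductivity (S/m); zero on scar/fibrosis."""

    sigma: np.ndarray  # (ny, nx), S/m

    @classmethod
    def from_grid(cls, grid: TissueGrid, sigma_healthy: float = SIGMA_HEALTHY,
                  sigma_scale_bz: float = 1.0) -> "ConductivityField":
        """Healthy elements carry ``sigma_healthy``; BZ elements the same base
        value scaled by ``sigma_scale_bz``; scar and fibrotic elements zero."""
        if sigma_healthy < 0 or sigma_scale_bz < 0:
            raise ConfigurationError("conductivities must be >= 0")
        sig = np.zeros_like(grid.labels, dtype=np.float64)
        sig[grid.labels == Label.HEALTHY] = sigma_healthy
        sig[grid.labels == Label.BZ] = sigma_healthy * sigma_scale_bz
        return cls(sigma=sig)


@dataclass(frozen=True)
class StimulusSpec:
    """A transmembrane stimulus applied to a set of nodes.

    ``region`` is a boolean node mask of shape (ny+1, nx+1); ``onsets`` lists
    the stimulus onset times in ms.
    """

    region: np.ndarray
    amplitude: float = 100.0   # uA/cm^2
    duration: float = 1.0      # ms
    onsets: tuple[float, ...] = (0.0,)

    def __post_init__(self):
        if self.amplitude <= 0:
            raise ConfigurationError("stimulus amplitude must be > 0")
        if self.duration <= 0:
            raise ConfigurationError("stimulus duration must be > 0")

    @classmethod
    def bottom_edge(cls, grid: TissueGrid, depth_mm: float = 0.4,
                    **kw) -> "StimulusSpec":
        """Electrode covering the lowermost ``depth_mm`` of the sheet
        (at least two node rows regardless of spacing)."""
        rows = max(2, int(round(depth_mm / grid.h_mm)) + 1)
        region = np.zeros(grid.shape_nodes, dtype=bool)
        region[:rows, :] = True
        region &= grid.active_nodes()
        return cls(region=region, **kw)

    @classmethod
    def left_edge(cls, grid: TissueGrid, depth_mm: float = 0.4,
                  **kw) -> "StimulusSpec":
        """Electrode covering the leftmost ``depth_mm`` (strip geometries)."""
        cols = max(2, int(round(depth_mm / grid.h_mm)) + 1)
        region = np.zeros(grid.shape_nodes, dtype=bool)
        region[:, :cols] = True
        region &= grid.active_nodes()
        return cls(region=region, **kw)


@dataclass
class SimulationConfig:
    """Solver configuration (every field has a physical default)."""

    dt: float = 0.02                #: time step, ms
    t_end: float = 500.0            #: simulated duration, ms
    sample_interval: float = 1.0    #: Vm output sampling, ms
    beta_per_um: float = 0.14       #: surface-to-volume ratio, 1/um
    cm: float = 1.0                 #: membrane capacitance, uF/cm^2
    diffusion_calibration: float | None = None  #: None -> CV_CALIBRATION
    vm_abort: float = 200.0         #: |Vm| instability abort threshold, mV
    record_dtype: str = "float32"

    def __post_init__(self):
        if self.dt <= 0 or self.dt > 0.1:
            raise ConfigurationError("dt must lie in (0, 0.1] ms")
        if self.beta_per_um <= 0 or self.cm <= 0:
            raise ConfigurationError("beta and cm must be > 0")

    @property
    def calibration(self) -> float:
        return (CV_CALIBRATION if self.diffusion_calibration is None
                else self.diffusion_calibration)

    def diffusivity(self, sigma: np.ndarray | float) -> np.ndarray | float:
        """Convert conductivity (S/m) to diffusivity (mm^2/ms)."""
        return np.asarray(sigma) / (self.beta_per_um * self.cm * 10.0) \
            * self.calibration

    def stability_dt_bound(self, sigma_max: float, h_mm: float) -> float:
        """Explicit-diffusion stability bound dt < h^2 / (4 D_max)."""
        d = float(self.diffusivity(sigma_max))
        return np.inf if d == 0 else h_mm * h_mm / (4.0 * d)


@dataclass
class VmRecording:
    """Vm sampled over (time x node grid) plus the stimulus event log."""

    times: np.ndarray               # (T,), ms
    vm: np.ndarray                  # (T, ny+1, nx+1), mV; NaN at inert nodes
    grid: TissueGrid
    active: np.ndarray              # (ny+1, nx+1) bool
    stim_events: list[tuple[float, str]] = field(default_factory=list)
    config: SimulationConfig | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_samples(self) -> int:
        return int(self.times.size)

    def frame(self, t: float) -> np.ndarray:
        """Vm field at the sample closest to time ``t`` (ms)."""
        k = int(np.argmin(np.abs(self.times - t)))
        return self.vm[k]

    def subsample(self, stride: int) -> "VmRecording":
        """Recording with every ``stride``-th sample (classification
        robustness checks)."""
        return VmRecording(self.times[::stride].copy(), self.vm[::stride],
                           self.grid, self.active, list(self.stim_events),
                           self.config, dict(self.meta))


# ---------------------------------------------------------------------------
# Operator assembly
# ---------------------------------------------------------------------------

def _edge_sigma(sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Mean flanking-element conductivity for horizontal and vertical node
    edges.

    Returns ``(sx, sy)``: ``sx[r, c]`` is the conductivity of the edge between
    nodes (r, c) and (r, c+1); ``sy[r, c]`` between (r, c) and (r+1, c).
    Missing (exterior) and zero-sigma elements contribute zero, which realizes
    the no-flux conditions.
    """
    ny, nx = sigma.shape
    padded = np.zeros((ny + 2, nx + 2))
    padded[1:-1, 1:-1] = sigma
    # horizontal edge at node row r spans element rows r-1 (below), r (above)
    sx = 0.5 * (padded[0:ny + 1, 1:-1] + padded[1:ny + 2, 1:-1])  # (ny+1, nx)
    # vertical edge at node col c flanked by element cols c-1 (left), c (right)
    sy = 0.5 * (padded[1:-1, 0:nx + 1] + padded[1:-1, 1:nx + 2])  # (ny, nx+1)
    return sx, sy


def node_volume_fractions(grid: TissueGrid) -> np.ndarray:
    """Conducting control-volume fraction of each node (0, 1/4 ... 1).

    A node's control volume is the quarter of each of its (up to four)
    incident elements; only conducting elements contribute.
    """
    return grid.node_touch_counts(grid.conducting).astype(np.float64) / 4.0


def assemble_diffusion(grid: TissueGrid, cond: ConductivityField,
                       beta_per_um: float = 0.14, cm: float = 1.0,
                       calibration: float | None = None,
                       lumped: bool = True) -> sp.csr_matrix:
    """Sparse diffusion operator L (1/ms) over the flattened node grid.

    ``(L @ vm)`` is the diffusive dVm/dt.  Rows sum to zero and rows of inert
    nodes are empty.  With ``lumped=True`` (the solver's operator) each row is
    divided by the node's conducting control-volume fraction, i.e.
    ``L = M^-1 K`` with the symmetric flux matrix K and the lumped volume
    matrix M; pass ``lumped=False`` to obtain the symmetric K/h^2 itself.
    """
    cfg = SimulationConfig(beta_per_um=beta_per_um, cm=cm,
                           diffusion_calibration=calibration)
    if cond.sigma.shape != grid.labels.shape:
        raise ConfigurationError("conductivity field does not match grid")
    h = grid.h_mm
    sx, sy = _edge_sigma(cond.sigma)
    wx = np.asarray(cfg.diffusivity(sx)) / (h * h)   # (ny+1, nx)
    wy = np.asarray(cfg.diffusivity(sy)) / (h * h)   # (ny, nx+1)

    nyn, nxn = grid.shape_nodes
    n = nyn * nxn

    def nid(r, c):
        return r * nxn + c

    rows, cols, vals = [], [], []
    # horizontal edges
    rr, cc = np.nonzero(wx > 0)
    a = nid(rr, cc)
    b = nid(rr, cc + 1)
    w = wx[rr, cc]
    rows += [a, b, a, b]
    cols += [b, a, a, b]
    vals += [w, w, -w, -w]
    # vertical edges
    rr, cc = np.nonzero(wy > 0)
    a = nid(rr, cc)
    b = nid(rr + 1, cc)
    w = wy[rr, cc]
    rows += [a, b, a, b]
    cols += [b, a, a, b]
    vals += [w, w, -w, -w]

    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    K = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsr()
    if not lumped:
        return K
    vol = node_volume_fractions(grid).ravel()
    inv_vol = np.zeros(n)
    nz = vol > 0
    inv_vol[nz] = 1.0 / vol[nz]
    return sp.diags(inv_vol) @ K


def _neighbor_arrays(grid: TissueGrid, cond: ConductivityField,
                     cfg: SimulationConfig,
                     active_flat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(n_active, 4) neighbor-index and edge-weight arrays for the kernel."""
    h = grid.h_mm
    sx, sy = _edge_sigma(cond.sigma)
    wx = np.asarray(cfg.diffusivity(sx)) / (h * h)
    wy = np.asarray(cfg.diffusivity(sy)) / (h * h)

    nyn, nxn = grid.shape_nodes
    full_to_active = np.full(nyn * nxn, -1, dtype=np.int64)
    full_to_active[active_flat] = np.arange(active_flat.size)

    rr = active_flat // nxn
    cc = active_flat % nxn
    n = active_flat.size
    nbr = np.full((n, 4), -1, dtype=np.int32)
    wgt = np.zeros((n, 4), dtype=np.float64)
    vol = node_volume_fractions(grid).ravel()[active_flat]  # > 0 on active

    # +x neighbor
    ok = cc + 1 <= nxn - 1
    w = np.where(ok, wx[rr, np.minimum(cc, nxn - 2)], 0.0)
    w[~ok] = 0.0
    tgt = np.where(ok, rr * nxn + cc + 1, 0)
    _fill(nbr, wgt, 0, w, tgt, full_to_active)
    # -x neighbor
    ok = cc - 1 >= 0
    w = np.where(ok, wx[rr, np.maximum(cc - 1, 0)], 0.0)
    w[~ok] = 0.0
    tgt = np.where(ok, rr * nxn + cc - 1, 0)
    _fill(nbr, wgt, 1, w, tgt, full_to_active)
    # +y neighbor
    ok = rr + 1 <= nyn - 1
    w = np.where(ok, wy[np.minimum(rr, nyn - 2), cc], 0.0)
    w[~ok] = 0.0
    tgt = np.where(ok, (rr + 1) * nxn + cc, 0)
    _fill(nbr, wgt, 2, w, tgt, full_to_active)
    # -y neighbor
    ok = rr - 1 >= 0
    w = np.where(ok, wy[np.maximum(rr - 1, 0), cc], 0.0)
    w[~ok] = 0.0
    tgt = np.where(ok, (rr - 1) * nxn + cc, 0)
    _fill(nbr, wgt, 3, w, tgt, full_to_active)
    wgt /= vol[:, None]
    return nbr, wgt


def _fill(nbr, wgt, k, w, tgt_full, full_to_active):
    use = w > 0
    tgt_act = full_to_active[tgt_full]
    use &= tgt_act >= 0
    nbr[use, k] = tgt_act[use]
    wgt[use, k] = w[use]


# ---------------------------------------------------------------------------
# Time integration
# ---------------------------------------------------------------------------

def initial_states(grid: TissueGrid, remodeling: RemodelingSpec,
                   params: CellParams, active_flat: np.ndarray,
                   prepace_beats: int = 100,
                   prepace_hz: float = 2.0) -> np.ndarray:
    """Per-node initial state matrix from region-wise paced steady states.

    Healthy nodes receive the control steady state; BZ nodes (touching >= 1
    BZ element) the steady state of the remodeled cell variant.
    """
    control = pace_to_steady(params, frequency=prepace_hz,
                             n_beats=prepace_beats).state.to_array()
    S = np.tile(control, (active_flat.size, 1))
    if remodeling.mode != "none":
        bz = grid.bz_nodes().ravel()[active_flat]
        if bz.any():
            try:
                rem = pace_to_steady(remodeling.cell_params(params),
                                     frequency=prepace_hz,
                                     n_beats=prepace_beats).state.to_array()
            except NoCaptureError:
                # a variant too depressed to pace starts from quiescent rest
                rem = K.INITIAL_STATE
            S[bz] = rem
    return S


def run(grid: TissueGrid, cond: ConductivityField,
        params: CellParams | None = None,
        remodeling: RemodelingSpec | None = None,
        stimuli: Sequence[StimulusSpec] = (),
        config: SimulationConfig | None = None,
        init: np.ndarray | str = "steady",
        stop_when: Callable[[float, np.ndarray], bool] | None = None,
        check_interval: float = 1.0) -> VmRecording:
    """Advance the monodomain model to ``config.t_end`` and record Vm.

    ``init`` is either a pre-built (n_active, 19) state matrix, ``"steady"``
    (region-wise 2 Hz / 100-beat steady states) or ``"resting"`` (published
    resting state everywhere).  ``stop_when(t, vm_active)`` is polled every
    ``check_interval`` ms and ends the run early when it returns True.

    Raises :class:`IntegrationError` (with time and node index) if |Vm|
    exceeds the abort threshold.
    """
    params = params or CellParams()
    remodeling = remodeling or RemodelingSpec()
    config = config or SimulationConfig()

    h = grid.h_mm
    sigma_max = float(cond.sigma.max())
    bound = config.stability_dt_bound(sigma_max, h)
    if config.dt >= bound:
        raise ConfigurationError(
            f"dt = {config.dt} ms violates the explicit stability bound "
            f"{bound:.4f} ms at h = {grid.h_um} um")

    active = grid.active_nodes()
    active_flat = np.flatnonzero(active.ravel())
    n_act = active_flat.size
    nbr, wgt = _neighbor_arrays(grid, cond, config, active_flat)

    if isinstance(init, str):
        if init == "steady":
            S = initial_states(grid, remodeling, params, active_flat)
        elif init == "resting":
            S = np.tile(K.INITIAL_STATE, (n_act, 1))
        else:
            raise ConfigurationError(f"unknown init mode '{init}'")
    else:
        S = np.array(init, dtype=np.float64)
        if S.shape != (n_act, K.N_STATE):
            raise ConfigurationError(
                f"init state matrix must have shape {(n_act, K.N_STATE)}")

    gna = np.ones(n_act)
    gkr = np.ones(n_act)
    gks = np.ones(n_act)
    if remodeling.mode != "none":
        bz = grid.bz_nodes().ravel()[active_flat]
        rem = remodeling.cell_params(CellParams())
        gna[bz] = rem.gna_scale
        gkr[bz] = rem.gkr_scale
        gks[bz] = rem.gks_scale
    # global multipliers (if any) on top
    gna *= params.gna_scale
    gkr *= params.gkr_scale
    gks *= params.gks_scale

    tab, xk1 = K.get_rate_tables(config.dt)
    dt = config.dt
    n_steps = int(round(config.t_end / dt))
    rec_stride = max(1, int(round(config.sample_interval / dt)))
    n_rec = n_steps // rec_stride + 1
    nyn, nxn = grid.shape_nodes
    vm_rec = np.full((n_rec, nyn * nxn), np.nan, dtype=config.record_dtype)
    times = np.empty(n_rec)

    # stimulus schedule: list of (step_on, step_off, amp_per_cm, idx)
    schedule = []
    events = []
    for stim in stimuli:
        region_flat = np.flatnonzero((stim.region & active).ravel())
        idx = np.searchsorted(active_flat, region_flat)
        if idx.size == 0:
            raise ConfigurationError("stimulus region contains no active nodes")
        for onset in stim.onsets:
            schedule.append((int(round(onset / dt)),
                             int(round((onset + stim.duration) / dt)),
                             stim.amplitude / params.cm, idx))
            events.append((float(onset), f"stimulus {stim.amplitude} uA/cm^2 "
                           f"x {stim.duration} ms, {idx.size} nodes"))
    schedule.sort(key=lambda s: s[0])

    istim = np.zeros(n_act)
    check_stride = max(1, int(round(check_interval / dt)))

    w = 0
    vm_rec[w, active_flat] = S[:, 0]
    times[w] = 0.0
    w += 1
    stopped_at = None
    for k in range(n_steps):
        need_clear = False
        for (on, off, amp, idx) in schedule:
            if on <= k < off:
                istim[idx] = amp
                need_clear = True
        vmax = K.step_tissue(S, nbr, wgt, gna, gkr, gks, istim, dt, tab, xk1)
        if need_clear:
            istim[:] = 0.0
        t = (k + 1) * dt
        if (k + 1) % rec_stride == 0 and w < n_rec:
            vm_rec[w, active_flat] = S[:, 0]
            times[w] = t
            w += 1
        if (k + 1) % check_stride == 0:
            if not np.isfinite(vmax) or abs(vmax) > config.vm_abort:
                v = S[:, 0]
                bad = int(np.argmax(np.abs(v)))
                raise IntegrationError(
                    f"instability at t = {t:.2f} ms, node "
                    f"{int(active_flat[bad])} (Vm = {v[bad]:.1f} mV)")
            if stop_when is not None and stop_when(t, S[:, 0]):
                stopped_at = t
                break

    vm_rec = vm_rec[:w].reshape(w, nyn, nxn)
    rec = VmRecording(times=times[:w].copy(), vm=vm_rec, grid=grid,
                      active=active, stim_events=events, config=config,
                      meta={"model_variant": "tentusscher_panfilov_2006_endo",
                            "remodeling_mode": remodeling.mode,
                            "stopped_early_at_ms": stopped_at,
                            "n_active_nodes": int(n_act)})
    rec.meta["final_states"] = S
    rec.meta["active_flat"] = active_flat
    return rec
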