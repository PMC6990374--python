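"""Field maps, the re-entry vulnerability index (RVI), and outcome
classification.

Activation time (AT) is the first upward crossing of a threshold (-20 mV by
default) inside a beat window; repolarization time (RT) the subsequent
downward crossing of the 90%-repolarization level; APD = RT - AT.

The RVI quantifies wavefront-waveback interaction around a potential
re-entrant circuit: for a distal node d and a proximal neighbor p (activated
earlier, within a pairing radius), RVI(d) = min_p RT(p) - AT(d).  During
plain propagation the RVI map resembles the APD map; at a line of block the
RVI drops well below the APD, and it turns negative when the circuit
re-excites tissue (re-entry).  Regions with RVI below 30% of the mean tissue
APD are scored as conduction block.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
import warnings

import numpy as np

from .exceptions import ConfigurationError
from .geometry import TissueGrid
from .monodomain import VmRecording

__all__ = [
    "FieldMaps", "OutcomeClass", "Outcome",
    "activation_repolarization_maps", "conduction_velocity", "rvi_map",
    "classify_outcome", "count_sentinel_activations", "mean_tissue_apd",
    "upward_crossing_times",
]

#: Default activation-detection threshold (mV).
ACTIVATION_THRESHOLD = -20.0
#: Fraction of the per-node AP amplitude that must be repolarized at RT.
REPOL_FRACTION = 0.9
#: RVI-to-mean-APD ratio below which a region counts as conduction block.
RVI_BLOCK_FRACTION = 0.30


@dataclass
class FieldMaps:
    """Per-node activation/repolarization/APD (and optional RVI) maps, ms.

    Arrays are (ny+1, nx+1) with NaN at nodes that never activated in the
    window.
    """

    at: np.ndarray
    rt: np.ndarray
    grid: TissueGrid
    window: tuple[float, float]
    rvi: np.ndarray | None = None

    @property
    def apd(self) -> np.ndarray:
        return self.rt - self.at


class OutcomeClass(str, Enum):
    NO_BLOCK = "NO_BLOCK"
    BLOCK_NO_REENTRY = "BLOCK_NO_REENTRY"
    REENTRY_NONSUSTAINED = "REENTRY_NONSUSTAINED"
    REENTRY_SUSTAINED = "REENTRY_SUSTAINED"
    INEXCITABLE = "INEXCITABLE"


@dataclass
class Outcome:
    """Classified result of one S1-S2 run."""

    category: OutcomeClass
    n_cycles: int = 0
    mean_apd: float = float("nan")
    min_rvi: float = float("nan")
    s2_transits: bool = False
    rvi_block: bool = False
    details: dict = field(default_factory=dict)

    def __post_init__(self):
        sustained = self.category == OutcomeClass.REENTRY_SUSTAINED
        if sustained != (self.n_cycles > 1):
            raise ValueError("REENTRY_SUSTAINED iff n_cycles > 1")


# ---------------------------------------------------------------------------
# Maps
# ---------------------------------------------------------------------------

def _window_slice(rec: VmRecording, window: tuple[float, float]) -> slice:
    t0, t1 = window
    i0 = int(np.searchsorted(rec.times, t0 - 1e-9))
    i1 = int(np.searchsorted(rec.times, t1 + 1e-9))
    if i1 - i0 < 3:
        raise ConfigurationError("beat window contains fewer than 3 samples")
    return slice(i0, i1)


def activation_repolarization_maps(
        rec: VmRecording, window: tuple[float, float],
        threshold: float = ACTIVATION_THRESHOLD,
        repol_fraction: float = REPOL_FRACTION) -> FieldMaps:
    """AT/RT maps for the beat bracketed by ``window`` (ms).

    AT interpolates the first upward threshold crossing; RT the first
    downward crossing of the per-node level
    ``vrest + (1 - repol_fraction) * (vpeak - vrest)`` after activation.
    Nodes that never cross the threshold are NaN-masked in both maps.
    """
    sl = _window_slice(rec, window)
    t = rec.times[sl]
    nyn, nxn = rec.vm.shape[1:]
    v = rec.vm[sl].reshape(t.size, -1).astype(np.float64)

    with np.errstate(invalid="ignore"):
        above = v > threshold
        up = above[1:] & ~above[:-1]
    has_at = up.any(axis=0)
    k_at = np.argmax(up, axis=0)  # crossing between k_at and k_at+1

    cols = np.arange(v.shape[1])
    v0 = v[k_at, cols]
    v1 = v[k_at + 1, cols]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(has_at, (threshold - v0) / (v1 - v0), np.nan)
    at = t[k_at] + frac * (t[k_at + 1] - t[k_at])

    # per-node repolarization level from the beat amplitude
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        vrest = np.nanmin(v, axis=0)
        vpeak = np.nanmax(v, axis=0)
        level = vrest + (1.0 - repol_fraction) * (vpeak - vrest)
        below = v <= level[None, :]
        down = below[1:] & ~below[:-1]
    # only crossings after activation
    after = np.arange(down.shape[0])[:, None] >= k_at[None, :]
    down &= after
    has_rt = down.any(axis=0) & has_at
    k_rt = np.argmax(down, axis=0)
    v0 = v[k_rt, cols]
    v1 = v[k_rt + 1, cols]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(has_rt, (level - v0) / (v1 - v0), np.nan)
    rt = t[k_rt] + frac * (t[k_rt + 1] - t[k_rt])

    at = np.where(has_at, at, np.nan).reshape(nyn, nxn)
    rt = np.where(has_rt, rt, np.nan).reshape(nyn, nxn)
    return FieldMaps(at=at, rt=rt, grid=rec.grid,
                     window=(float(t[0]), float(t[-1])))


def conduction_velocity(maps: FieldMaps, p1: tuple[int, int],
                        p2: tuple[int, int]) -> float:
    """CV (m/s) between (row, col) node pairs along the propagation path."""
    at1 = float(maps.at[p1])
    at2 = float(maps.at[p2])
    if np.isnan(at1) or np.isnan(at2):
        raise ConfigurationError("both probe nodes must be activated")
    if at2 <= at1:
        raise ConfigurationError("non-causal pair: at(p2) <= at(p1)")
    h = maps.grid.h_mm
    dist = h * float(np.hypot(p2[0] - p1[0], p2[1] - p1[1]))  # mm
    return dist / (at2 - at1)  # mm/ms == m/s


def rvi_map(maps: FieldMaps, pairing_radius_mm: float = 2.0) -> np.ndarray:
    """Per-node RVI (ms): minimum over proximal neighbors within the pairing
    radius (activated strictly earlier) of RT(p) - AT(d).

    Nodes without a qualifying proximal neighbor are NaN-masked.  The result
    is also stored on ``maps.rvi``.
    """
    h = maps.grid.h_mm
    r = int(np.floor(pairing_radius_mm / h))
    if r < 1:
        raise ConfigurationError("pairing radius smaller than node spacing")
    at = maps.at
    rt = maps.rt
    nyn, nxn = at.shape
    best = np.full((nyn, nxn), np.inf)
    found = np.zeros((nyn, nxn), dtype=bool)
    for dy in range(-r, r + 1):
        for dx in range(-r, r + 1):
            if dy == 0 and dx == 0:
                continue
            if dy * dy + dx * dx > r * r + 1e-9:
                continue
            # distal nodes d; proximal candidates p = d + (dy, dx)
            dst = (slice(max(0, -dy), nyn - max(0, dy)),
                   slice(max(0, -dx), nxn - max(0, dx)))
            src = (slice(max(0, dy), nyn - max(0, -dy)),
                   slice(max(0, dx), nxn - max(0, -dx)))
            at_d = at[dst]
            at_p = at[src]
            rt_p = rt[src]
            with np.errstate(invalid="ignore"):
                ok = (at_p < at_d) & ~np.isnan(rt_p)
                cand = np.where(ok, rt_p - at_d, np.inf)
            b = best[dst]
            np.copyto(b, np.minimum(b, cand))
            found[dst] |= ok
    rvi = np.where(found, best, np.nan)
    maps.rvi = rvi
    return rvi


def mean_tissue_apd(maps: FieldMaps, healthy_only: bool = True) -> float:
    """Mean APD (ms) over activated nodes, by default restricted to nodes
    touching only healthy elements."""
    apd = maps.apd
    if healthy_only:
        g = maps.grid
        mask = g.active_nodes() & ~g.bz_nodes()
        apd = np.where(mask, apd, np.nan)
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return float(np.nanmean(apd))


# ---------------------------------------------------------------------------
# Outcome classification
# ---------------------------------------------------------------------------

def upward_crossing_times(rec: VmRecording, node: tuple[int, int],
                          t_after: float = -np.inf,
                          threshold: float = ACTIVATION_THRESHOLD,
                          reset_level: float = -60.0) -> np.ndarray:
    """Times of upward threshold crossings at one node after ``t_after``.

    Hysteresis: after a crossing, the voltage must fall below ``reset_level``
    before another crossing is counted, so sub-threshold wiggle of a slow
    upstroke is not mistaken for a re-activation.
    """
    v = rec.vm[:, node[0], node[1]].astype(np.float64)
    times = []
    armed = v[0] <= threshold
    for k in range(1, v.size):
        if armed and v[k] > threshold and v[k - 1] <= threshold:
            frac = (threshold - v[k - 1]) / (v[k] - v[k - 1])
            tc = rec.times[k - 1] + frac * (rec.times[k] - rec.times[k - 1])
            if tc > t_after:
                times.append(tc)
            armed = False
        elif not armed and v[k] < reset_level:
            armed = True
    return np.asarray(times)


def sentinel_nodes(grid: TissueGrid, offset_mm: float = 5.0
                   ) -> tuple[tuple[int, int], tuple[int, int]]:
    """Healthy-tissue sentinel nodes ``offset_mm`` below and above the
    isthmus, on the channel axis (re-entrant cycles are counted here)."""
    x_lo, x_hi, y_lo, y_hi = grid.channel_bounds_mm()
    h = grid.h_mm
    sheet_y = grid.ny * h
    cx = 0.5 * (x_lo + x_hi)
    col = int(round(cx / h))
    # keep sentinels out of the stimulus electrode and inside the sheet
    y_below = max(y_lo - offset_mm, 1.6)
    y_above = min(y_hi + offset_mm, sheet_y - 1.6)
    row_below = int(round(y_below / h))
    row_above = int(round(y_above / h))
    return (row_below, col), (row_above, col)


def count_sentinel_activations(rec: VmRecording, t_after: float,
                               offset_mm: float = 5.0) -> tuple[int, int]:
    """(n_below, n_above): upward crossings at the two sentinels after
    ``t_after``."""
    below, above = sentinel_nodes(rec.grid, offset_mm)
    return (upward_crossing_times(rec, below, t_after).size,
            upward_crossing_times(rec, above, t_after).size)


#: A sentinel crossing within this window after S2 counts as the direct,
#: stimulus-driven activation; later crossings mark re-entrant cycles.  The
#: proximal (below) sentinel sits next to the electrode and activates within
#: tens of ms when the premature wave captures at all; the distal (above)
#: sentinel is reached by the wave around the scar within ~150-200 ms, while
#: the earliest re-entrant exit takes > 200 ms (below) / > 350 ms (above).
DIRECT_WINDOW_BELOW_MS = 150.0
DIRECT_WINDOW_ABOVE_MS = 300.0


def count_reentry_cycles(rec: VmRecording, s2_time: float,
                         offset_mm: float = 5.0) -> int:
    """Number of re-entrant cycles observed at the sentinel nodes after S2.

    The direct S2-driven crossing of each sentinel (at most one, inside its
    direct window) is discounted; every later crossing is one completed
    circuit.  A decremental S2 response may fail to cross threshold at the
    proximal sentinel, in which case all its post-window crossings are
    re-entrant.
    """
    below, above = sentinel_nodes(rec.grid, offset_mm)
    cycles = []
    for node, win in ((below, DIRECT_WINDOW_BELOW_MS),
                      (above, DIRECT_WINDOW_ABOVE_MS)):
        t = upward_crossing_times(rec, node, s2_time)
        n_direct = int(np.any(t <= s2_time + win)) if t.size else 0
        cycles.append(t.size - n_direct)
    return max(0, *cycles)


def _channel_row_activation(maps: FieldMaps) -> tuple[np.ndarray, np.ndarray]:
    """Earliest AT per interior channel row (NaN where a row never
    activates), and the row indices used."""
    g = maps.grid
    x_lo, x_hi, y_lo, y_hi = g.channel_bounds_mm()
    h = g.h_mm
    c_lo = int(np.ceil(x_lo / h))
    c_hi = int(np.floor(x_hi / h))
    r_lo = int(np.ceil(y_lo / h))
    r_hi = int(np.floor(y_hi / h))
    rows = np.arange(r_lo + 1, r_hi)        # interior rows
    sub = maps.at[rows, c_lo + 1:c_hi]      # interior columns
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        row_at = np.nanmin(sub, axis=1)
    return row_at, rows


def s2_transits_isthmus(maps: FieldMaps, min_coverage: float = 0.8,
                        entry_third: float = 1 / 3) -> bool:
    """Whether the S2 beat conducted into and through the channel without
    proximal block.

    True iff most channel rows activate during the S2 window and the
    earliest-activated row lies in the bottom third (the wave entered through
    the proximal mouth).  A head-on collision with the around-scar wave
    inside the channel still counts as conducted -- there is no
    unidirectional block in that case.  Retrograde invasion through the
    distal mouth (re-entry after proximal block) has its earliest activation
    at the top and returns False, as does a wave that dies inside the
    channel (coverage shortfall).
    """
    row_at, _rows = _channel_row_activation(maps)
    act = ~np.isnan(row_at)
    if act.mean() < min_coverage:
        return False
    entry_row = int(np.nanargmin(row_at))
    return bool(entry_row < entry_third * row_at.size)


def s2_enters_isthmus(maps: FieldMaps, quarter: float = 0.25,
                      min_coverage: float = 0.8) -> bool:
    """Whether the S2 wave entered through the proximal (bottom) mouth."""
    row_at, _ = _channel_row_activation(maps)
    n = row_at.size
    low = row_at[:max(2, int(n * quarter))]
    return bool((~np.isnan(low)).mean() >= min_coverage)


def classify_outcome(rec: VmRecording, s1_times: tuple[float, ...],
                     s2_time: float,
                     rvi_block_fraction: float = RVI_BLOCK_FRACTION,
                     pairing_radius_mm: float = 2.0,
                     sentinel_offset_mm: float = 5.0) -> Outcome:
    """Classify one S1-S2 run of the idealized infarct sheet.

    INEXCITABLE        -- no border-zone node activates during the last S1
    NO_BLOCK           -- the S2 wave transits the isthmus, no extra beats
    BLOCK_NO_REENTRY   -- S2 fails to transit and no tissue re-excitation
    REENTRY_*          -- >= 1 post-S2 re-activation of a sentinel node;
                          SUSTAINED iff more than one cycle
    """
    last_s1 = max(s1_times)
    t_end = float(rec.times[-1])
    s1_maps = activation_repolarization_maps(rec, (last_s1, s2_time))

    bz = rec.grid.bz_nodes()
    bz_at = np.where(bz, s1_maps.at, np.nan)
    if bool(np.all(np.isnan(bz_at))):
        return Outcome(category=OutcomeClass.INEXCITABLE,
                       details={"reason": "no BZ activation during last S1"})

    mean_apd = mean_tissue_apd(s1_maps)
    s2_maps = activation_repolarization_maps(rec, (s2_time, t_end))
    rvi = rvi_map(s2_maps, pairing_radius_mm)
    with np.errstate(all="ignore"):
        min_rvi = (float(np.nanmin(rvi))
                   if not bool(np.all(np.isnan(rvi))) else float("nan"))
    rvi_block = bool(min_rvi < rvi_block_fraction * mean_apd)
    transits = s2_transits_isthmus(s2_maps)

    n_below, n_above = count_sentinel_activations(rec, s2_time,
                                                  sentinel_offset_mm)
    n_cycles = count_reentry_cycles(rec, s2_time, sentinel_offset_mm)

    details = {"sentinel_below": n_below, "sentinel_above": n_above,
               "s2_enters": s2_enters_isthmus(s2_maps)}
    if n_cycles > 1:
        cat = OutcomeClass.REENTRY_SUSTAINED
    elif n_cycles == 1:
        cat = OutcomeClass.REENTRY_NONSUSTAINED
    elif transits:
        cat = OutcomeClass.NO_BLOCK
    else:
        cat = OutcomeClass.BLOCK_NO_REENTRY
    return Outcome(category=cat, n_cycles=n_cycles, mean_apd=mean_apd,
                   min_rvi=min_rvi, s2_transits=transits, rvi_block=rvi_block,
                   details=details)
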