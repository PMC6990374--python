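"""Parameter sweeps over remodeling severity and the block/re-entry
probability statistics.

Three conduction-slowing factors are swept on the idealized infarct sheet:
the sodium-current scale (functional remodeling), the border-zone
conductivity scale (gap-junction remodeling) and the fibrosis density
(structural remodeling), each combined with an S1-S2 run at a fixed coupling
interval and classified into block/re-entry outcomes.  The block probability
P_B = n/N is computed over fibrosis topologies (seeds), excluding runs whose
isthmus was completely inexcitable.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .cellmodel import CellParams, RemodelingSpec
from .exceptions import ConfigurationError
from .geometry import (Label, ScarSpec, TissueGrid, add_idealized_scar,
                       build_sheet, generate_fibrosis)
from .metrics import OutcomeClass, classify_outcome
from .monodomain import ConductivityField, SimulationConfig, StimulusSpec, run
from .protocols import DEFAULT_CI, S1S2Spec, run_s1s2

__all__ = [
    "SweepSpec", "run_sweep", "compute_pb", "derive_seed",
    "s1_traverses_isthmus", "isthmus_traversal_scan",
]

#: Outcomes counting as conduction block of the S2 beat (re-entry implies a
#: preceding block).
BLOCK_OUTCOMES = (OutcomeClass.BLOCK_NO_REENTRY,
                  OutcomeClass.REENTRY_NONSUSTAINED,
                  OutcomeClass.REENTRY_SUSTAINED)
REENTRY_OUTCOMES = (OutcomeClass.REENTRY_NONSUSTAINED,
                    OutcomeClass.REENTRY_SUSTAINED)


def derive_seed(root_seed: int, *key: int) -> int:
    """Deterministic per-run seed: spawn of ``root_seed`` keyed by integer
    coordinates (density index, replicate, ...); reproducible in isolation."""
    ss = np.random.SeedSequence(root_seed, spawn_key=tuple(int(k) for k in key))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class SweepSpec:
    """Sweep axes and study conditions.

    The defaults are a reduced grid sized for a workstation; the full-study
    axes (0.05 steps over scales, 0-0.90 fibrosis in 0.05 steps, 10 seeds)
    are available via :meth:`full`.
    """

    ina_scales: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0)
    sigma_scales: tuple[float, ...] = (0.1, 0.25, 0.5, 1.0)
    fib_densities: tuple[float, ...] = (0.0, 0.25, 0.5)
    n_seeds: int = 3
    root_seed: int = 1234
    mode: str = "reduced_ina"        #: or "prolonged_apd"
    ci: float = DEFAULT_CI
    h_um: float = 200.0
    sheet_mm: float = 40.0
    scar: ScarSpec = field(default_factory=ScarSpec)
    post_s2_ms: float = 1500.0

    def __post_init__(self):
        if not (self.ina_scales and self.sigma_scales and self.fib_densities):
            raise ConfigurationError("sweep axes must be non-empty")
        if self.mode not in ("reduced_ina", "prolonged_apd"):
            raise ConfigurationError("mode must be reduced_ina or "
                                     "prolonged_apd")

    @classmethod
    def full(cls, **kw) -> "SweepSpec":
        """The full-resolution study grid (thousands of tissue runs)."""
        scales = tuple(np.round(np.arange(0.10, 1.0001, 0.05), 2))
        dens = tuple(np.round(np.arange(0.0, 0.9001, 0.05), 2))
        kw.setdefault("ina_scales", scales)
        kw.setdefault("sigma_scales", scales)
        kw.setdefault("fib_densities", dens)
        kw.setdefault("n_seeds", 10)
        return cls(**kw)

    def remodeling(self, ina_scale: float) -> RemodelingSpec:
        if self.mode == "prolonged_apd":
            return RemodelingSpec(mode="prolonged_apd")
        if ina_scale == 1.0:
            return RemodelingSpec(mode="none")
        return RemodelingSpec(mode="reduced_ina", ina_scale=ina_scale)


def _row_key(ina, sigma, fib, seed_idx) -> str:
    return f"{ina:.4f}|{sigma:.4f}|{fib:.4f}|{seed_idx}"


def run_sweep(spec: SweepSpec | None = None,
              config: SimulationConfig | None = None,
              cache_path: str | Path | None = None,
              verbose: bool = False) -> pd.DataFrame:
    """One classified S1-S2 outcome per parameter combination.

    Returns a table with one row per (ina_scale, sigma_scale, fib_density,
    seed); rows already present in ``cache_path`` (keyed by the full
    parameter tuple) are not recomputed, making interrupted sweeps
    resumable.  Individual run failures are recorded in the ``error`` column
    without aborting the sweep.
    """
    spec = spec or SweepSpec()
    config = config or SimulationConfig()
    cache: dict[str, dict] = {}
    cache_path = Path(cache_path) if cache_path else None
    if cache_path and cache_path.exists():
        for _, row in pd.read_csv(cache_path).iterrows():
            cache[_row_key(row.ina_scale, row.sigma_scale, row.fib_density,
                           int(row.seed_index))] = row.to_dict()

    base = add_idealized_scar(build_sheet(spec.sheet_mm, spec.h_um), spec.scar)
    s1s2 = S1S2Spec()
    rows = []
    combos = list(itertools.product(spec.ina_scales, spec.sigma_scales,
                                    enumerate(spec.fib_densities)))
    for ina, sigma, (k_fib, fib) in combos:
        n_seeds = spec.n_seeds if fib > 0 else 1  # fib = 0 is deterministic
        for k_seed in range(n_seeds):
            key = _row_key(ina, sigma, fib, k_seed)
            if key in cache:
                rows.append(cache[key])
                continue
            seed = derive_seed(spec.root_seed, k_fib, k_seed)
            row = {"ina_scale": ina, "sigma_scale": sigma,
                   "fib_density": fib, "seed_index": k_seed, "seed": seed,
                   "outcome": None, "n_cycles": 0, "mean_apd": np.nan,
                   "min_rvi": np.nan, "error": ""}
            try:
                g = generate_fibrosis(base, fib, seed) if fib > 0 else base
                cond = ConductivityField.from_grid(g, sigma_scale_bz=sigma)
                rec = run_s1s2(g, cond, ci=spec.ci, spec=s1s2,
                               remodeling=spec.remodeling(ina),
                               config=config, post_s2_ms=spec.post_s2_ms)
                out = classify_outcome(rec, rec.meta["s1_times"],
                                       rec.meta["s2_time"])
                row.update(outcome=out.category.value, n_cycles=out.n_cycles,
                           mean_apd=out.mean_apd, min_rvi=out.min_rvi)
            except Exception as exc:  # row-level failure, sweep continues
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
            if verbose:
                print(f"ina={ina} sigma={sigma} fib={fib} seed#{k_seed}: "
                      f"{row['outcome'] or row['error']}")
            if cache_path:
                pd.DataFrame(rows).to_csv(cache_path, index=False)
    return pd.DataFrame(rows)


def compute_pb(table: pd.DataFrame,
               axes: tuple[str, ...] = ("ina_scale", "sigma_scale")
               ) -> pd.DataFrame:
    """Block and re-entry probabilities per sweep cell.

    P_block = n_block / N and P_reentry = n_reentry / N, with INEXCITABLE
    runs removed from both numerator and denominator; cells whose runs are
    all inexcitable carry NaN.  Rows with errors are excluded.
    """
    if table.empty:
        raise ConfigurationError("empty vulnerability table")
    if len(axes) > 2:
        raise ConfigurationError("at most two axes per heatmap")
    t = table[(table.error.fillna("") == "") & table.outcome.notna()].copy()
    t["inexc"] = t.outcome == OutcomeClass.INEXCITABLE.value
    t["block"] = t.outcome.isin([o.value for o in BLOCK_OUTCOMES])
    t["reentry"] = t.outcome.isin([o.value for o in REENTRY_OUTCOMES])

    def agg(g: pd.DataFrame) -> pd.Series:
        n = int((~g.inexc).sum())
        return pd.Series({
            "N": n,
            "n_inexcitable": int(g.inexc.sum()),
            "p_block": g.block[~g.inexc].mean() if n else np.nan,
            "p_reentry": g.reentry[~g.inexc].mean() if n else np.nan,
        })

    out = t.groupby(list(axes)).apply(agg, include_groups=False).reset_index()
    return out


def pb_heatmap(pb: pd.DataFrame, value: str = "p_block",
               axes: tuple[str, str] = ("ina_scale", "sigma_scale")
               ) -> pd.DataFrame:
    """Pivot a :func:`compute_pb` table into a (rows=axes[0], cols=axes[1])
    probability matrix."""
    return pb.pivot(index=axes[0], columns=axes[1], values=value)


# ---------------------------------------------------------------------------
# S1 isthmus-traversal experiment (fibrotic disconnection)
# ---------------------------------------------------------------------------

def _isolate_isthmus(grid: TissueGrid, margin_mm: float = 2.0) -> TissueGrid:
    """Make everything outside a vertical band around the channel inert.

    This removes the conduction route around the scar so that activation
    above the isthmus can only arrive through it; the band keeps a healthy
    margin on either side of the channel mouth.
    """
    g = grid.copy()
    x_lo, x_hi, _, _ = g.channel_bounds_mm()
    xc = (np.arange(g.nx) + 0.5) * g.h_mm
    outside = (xc < x_lo - margin_mm) | (xc > x_hi + margin_mm)
    g.labels[:, outside] = Label.SCAR
    return g


def s1_traverses_isthmus(grid: TissueGrid,
                         sigma_scale_bz: float = 1.0,
                         remodeling: RemodelingSpec | None = None,
                         config: SimulationConfig | None = None,
                         window_ms: float = 400.0,
                         isolate: bool = True) -> bool:
    """Whether a single S1 beat from the bottom edge reaches tissue above the
    isthmus within ``window_ms``.

    With ``isolate=True`` the lateral corridors around the scar are made
    inert, so the isthmus is the only available route (the question asked is
    specifically whether the channel conducts).  The run exits early once
    tissue above the channel activates or all activity has died out.
    """
    remodeling = remodeling or RemodelingSpec()
    config = config or SimulationConfig()
    g = _isolate_isthmus(grid) if isolate else grid
    cond = ConductivityField.from_grid(g, sigma_scale_bz=sigma_scale_bz)

    active = g.active_nodes()
    active_flat = np.flatnonzero(active.ravel())
    nxn = g.nx + 1
    rr = active_flat // nxn
    _, _, _, y_hi = g.channel_bounds_mm()
    above_rows = rr > int(np.ceil(y_hi / g.h_mm))
    hit = {"traversed": False}

    def stop(t, vm):
        if (vm[above_rows] > -20.0).any():
            hit["traversed"] = True
            return True
        return t > 30.0 and float(vm.max()) < -70.0  # activity extinguished

    cfg = replace(config, t_end=window_ms, sample_interval=5.0)
    stim = StimulusSpec.bottom_edge(g, onsets=(0.0,))
    run(g, cond, remodeling=remodeling, stimuli=[stim], config=cfg,
        init="steady", stop_when=stop)
    return hit["traversed"]


def isthmus_traversal_scan(densities, n_seeds: int = 10,
                           root_seed: int = 1234,
                           scar: ScarSpec | None = None,
                           sheet_mm: float = 40.0, h_um: float = 200.0,
                           config: SimulationConfig | None = None,
                           verbose: bool = False) -> pd.DataFrame:
    """For each fibrosis density, test ``n_seeds`` seeded patterns for S1
    traversal of the isthmus; returns one row per (density, seed)."""
    base = add_idealized_scar(build_sheet(sheet_mm, h_um),
                              scar or ScarSpec())
    rows = []
    for k_fib, dens in enumerate(densities):
        for k_seed in range(n_seeds):
            seed = derive_seed(root_seed, k_fib, k_seed)
            g = generate_fibrosis(base, dens, seed) if dens > 0 else base
            ok = s1_traverses_isthmus(g, config=config)
            rows.append({"density": dens, "seed_index": k_seed,
                         "seed": seed, "traversed": ok})
            if verbose:
                print(f"FIB={dens:.2f} seed#{k_seed}: "
                      f"{'traversed' if ok else 'blocked'}")
    return pd.DataFrame(rows)
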