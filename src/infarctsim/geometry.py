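"""Idealized infarct geometry and synthetic fibrosis textures.

The reference geometry is a 4 x 4 cm sheet of myocardium at 200 um element
spacing containing a non-conducting scar made of two mirror-image segments
separated by a 4 mm conducting isthmus of border-zone (BZ) tissue.  Fibrosis
is modeled by turning a seeded random subset of BZ elements non-conducting
(no-flux), with exact density control.

Conventions (also documented in the README): the origin is the bottom-left
node, x grows rightward and y upward, all lengths in mm unless suffixed
``_um``; elements are indexed row-major from the bottom-left, i.e. the flat
index of element (row i, column j) is ``i * nx + j``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError

__all__ = [
    "Label", "TissueGrid", "ScarSpec", "FibrosisPattern",
    "build_sheet", "build_strip", "add_idealized_scar", "generate_fibrosis",
    "bz_percolates",
]


class Label(IntEnum):
    HEALTHY = 0
    SCAR = 1
    BZ = 2
    FIBROTIC = 3


#: Labels that conduct current (scar and fibrosis are electrically inert).
CONDUCTING_LABELS = (Label.HEALTHY, Label.BZ)


@dataclass(frozen=True)
class ScarSpec:
    """Idealized scar: two mirror elliptical half-segments flanking a
    vertical conducting channel (the isthmus).

    ``isthmus_width``    -- width of the conducting channel (mm)
    ``scar_half_length`` -- vertical half-extent of each scar segment (mm);
                            also the half-length of the channel
    ``scar_depth``       -- horizontal extent of each segment away from the
                            channel wall (mm)
    ``center``           -- channel center in sheet coordinates (mm); sheet
                            center when omitted

    The default radii (16 mm in a 40 mm sheet) are calibrated so that the
    premature-beat re-entrant circuit (around one scar segment plus the
    isthmus) is long enough for the blocked S2 wave to find recovered tissue
    at the distal mouth; see docs/methods.md.
    """

    isthmus_width: float = 4.0
    scar_half_length: float = 16.0
    scar_depth: float = 16.0
    center: tuple[float, float] | None = None

    def __post_init__(self):
        if self.isthmus_width <= 0:
            raise ConfigurationError("isthmus_width must be > 0")
        if self.scar_half_length <= 0 or self.scar_depth <= 0:
            raise ConfigurationError("scar dimensions must be > 0")


@dataclass(frozen=True)
class FibrosisPattern:
    """A seeded random fibrosis mask over BZ elements."""

    seed: int
    density: float
    mask: np.ndarray  # flat element indices turned FIBROTIC

    def __post_init__(self):
        object.__setattr__(self, "mask",
                           np.asarray(self.mask, dtype=np.int64))


@dataclass
class TissueGrid:
    """Regular 2-D element grid with per-element tissue labels.

    ``labels`` has shape (ny, nx) with row 0 at the bottom; the node grid is
    (ny + 1, nx + 1).
    """

    nx: int
    ny: int
    h_um: float
    labels: np.ndarray
    scar: ScarSpec | None = None
    fibrosis: FibrosisPattern | None = None

    # -- basic derived quantities ------------------------------------------
    @property
    def h_mm(self) -> float:
        return self.h_um / 1000.0

    @property
    def n_elements(self) -> int:
        return self.nx * self.ny

    @property
    def shape_nodes(self) -> tuple[int, int]:
        return (self.ny + 1, self.nx + 1)

    @property
    def conducting(self) -> np.ndarray:
        """Boolean (ny, nx) mask of conducting elements."""
        return (self.labels == Label.HEALTHY) | (self.labels == Label.BZ)

    def count(self, label: Label) -> int:
        return int(np.count_nonzero(self.labels == label))

    def copy(self) -> "TissueGrid":
        return TissueGrid(self.nx, self.ny, self.h_um, self.labels.copy(),
                          self.scar, self.fibrosis)

    # -- node helpers -------------------------------------------------------
    def node_touch_counts(self, mask: np.ndarray) -> np.ndarray:
        """Number of elements from boolean element ``mask`` touching each node."""
        acc = np.zeros(self.shape_nodes, dtype=np.int8)
        m = mask.astype(np.int8)
        acc[:-1, :-1] += m
        acc[:-1, 1:] += m
        acc[1:, :-1] += m
        acc[1:, 1:] += m
        return acc

    def active_nodes(self) -> np.ndarray:
        """Boolean (ny+1, nx+1) mask: node touches >= 1 conducting element."""
        return self.node_touch_counts(self.conducting) > 0

    def bz_nodes(self) -> np.ndarray:
        """Nodes touching >= 1 BZ element (remodeling is applied here)."""
        return self.node_touch_counts(self.labels == Label.BZ) > 0

    def node_x_mm(self) -> np.ndarray:
        return np.arange(self.nx + 1) * self.h_mm

    def node_y_mm(self) -> np.ndarray:
        return np.arange(self.ny + 1) * self.h_mm

    # -- channel helpers (valid once a scar has been added) -----------------
    def _require_scar(self) -> ScarSpec:
        if self.scar is None:
            raise ConfigurationError("grid has no scar/isthmus")
        return self.scar

    def channel_bounds_mm(self) -> tuple[float, float, float, float]:
        """(x_lo, x_hi, y_lo, y_hi) of the isthmus channel in mm."""
        s = self._require_scar()
        cx, cy = s.center if s.center is not None else (
            self.nx * self.h_mm / 2.0, self.ny * self.h_mm / 2.0)
        return (cx - s.isthmus_width / 2.0, cx + s.isthmus_width / 2.0,
                cy - s.scar_half_length, cy + s.scar_half_length)

    def channel_element_mask(self) -> np.ndarray:
        x_lo, x_hi, y_lo, y_hi = self.channel_bounds_mm()
        xc = (np.arange(self.nx) + 0.5) * self.h_mm
        yc = (np.arange(self.ny) + 0.5) * self.h_mm
        inx = (xc > x_lo) & (xc < x_hi)
        iny = (yc > y_lo) & (yc < y_hi)
        return np.outer(iny, inx)


def build_sheet(size_mm: float = 40.0, h_um: float = 200.0) -> TissueGrid:
    """All-healthy square sheet of side ``size_mm`` at spacing ``h_um``."""
    return build_strip(size_mm, size_mm, h_um)


def build_strip(length_mm: float, width_mm: float,
                h_um: float = 200.0) -> TissueGrid:
    """All-healthy rectangular strip: ``length_mm`` along x, ``width_mm``
    along y."""
    h_mm = h_um / 1000.0
    nx = length_mm / h_mm
    ny = width_mm / h_mm
    if abs(nx - round(nx)) > 1e-9 or abs(ny - round(ny)) > 1e-9:
        raise ConfigurationError(
            f"sheet size ({length_mm} x {width_mm} mm) is not divisible by "
            f"the element spacing ({h_um} um)")
    nx, ny = int(round(nx)), int(round(ny))
    labels = np.full((ny, nx), Label.HEALTHY, dtype=np.int8)
    return TissueGrid(nx=nx, ny=ny, h_um=h_um, labels=labels)


def add_idealized_scar(grid: TissueGrid,
                       spec: ScarSpec | None = None) -> TissueGrid:
    """Label two mirror scar segments and the conducting BZ channel between
    them.

    Each segment is the half of an ellipse (semi-axes ``scar_depth``,
    ``scar_half_length``) lying outward of the channel wall.  The channel
    elements between the segments are labeled BZ; a conducting path from the
    bottom edge to the top edge of the sheet exists through the channel.
    """
    spec = spec or ScarSpec()
    g = grid.copy()
    h = g.h_mm
    sx, sy = g.nx * h, g.ny * h
    cx, cy = spec.center if spec.center is not None else (sx / 2.0, sy / 2.0)

    if spec.isthmus_width < 2 * h:
        raise ConfigurationError(
            "isthmus narrower than two elements cannot represent a "
            "conduction path")
    margin = 2.0
    if (cx - spec.isthmus_width / 2 - spec.scar_depth < margin
            or cx + spec.isthmus_width / 2 + spec.scar_depth > sx - margin
            or cy - spec.scar_half_length < margin
            or cy + spec.scar_half_length > sy - margin):
        raise ConfigurationError(
            "scar does not fit in the sheet with a 2 mm healthy margin")

    xc = (np.arange(g.nx) + 0.5) * h
    yc = (np.arange(g.ny) + 0.5) * h
    X, Y = np.meshgrid(xc, yc)

    x_wall_l = cx - spec.isthmus_width / 2.0
    x_wall_r = cx + spec.isthmus_width / 2.0
    left = (X <= x_wall_l) & (
        ((X - x_wall_l) / spec.scar_depth) ** 2
        + ((Y - cy) / spec.scar_half_length) ** 2 <= 1.0)
    right = (X >= x_wall_r) & (
        ((X - x_wall_r) / spec.scar_depth) ** 2
        + ((Y - cy) / spec.scar_half_length) ** 2 <= 1.0)
    channel = (X > x_wall_l) & (X < x_wall_r) & (np.abs(Y - cy)
                                                 <= spec.scar_half_length)

    g.labels[left | right] = Label.SCAR
    g.labels[channel] = Label.BZ
    g.scar = ScarSpec(spec.isthmus_width, spec.scar_half_length,
                      spec.scar_depth, (cx, cy))
    g.fibrosis = None
    return g


def generate_fibrosis(grid: TissueGrid, density: float, seed: int,
                      allow_extreme: bool = False) -> TissueGrid:
    """Relabel a seeded uniform random subset of BZ elements as FIBROTIC.

    Exactly ``round(density * n_BZ)`` elements are drawn without replacement;
    the same (seed, density, grid) always yields the same mask.  Densities
    above 0.9 require ``allow_extreme=True``.
    """
    if density < 0 or density > 1:
        raise ConfigurationError("density must lie in [0, 1]")
    if density > 0.9 and not allow_extreme:
        raise ConfigurationError(
            "density > 0.9 is outside the studied range; pass "
            "allow_extreme=True to override")
    g = grid.copy()
    bz_flat = np.flatnonzero(g.labels.ravel() == Label.BZ)
    n_pick = int(round(density * bz_flat.size))
    rng = np.random.default_rng(seed)
    picked = rng.choice(bz_flat, size=n_pick, replace=False) if n_pick else \
        np.empty(0, dtype=np.int64)
    picked = np.sort(picked)
    lab = g.labels.ravel()
    lab[picked] = Label.FIBROTIC
    g.labels = lab.reshape(g.ny, g.nx)
    g.fibrosis = FibrosisPattern(seed=seed, density=density, mask=picked)
    return g


def bz_percolates(grid: TissueGrid, connectivity: int = 4) -> bool:
    """Whether the surviving (BZ) myocyte subgraph of the channel connects its
    bottom row to its top row.

    ``connectivity`` is 4 (edge-sharing elements) or 8 (corner-sharing); the
    node-based diffusion stencil effectively couples corner-sharing elements,
    but the 4-neighbor graph is the conservative structural check.
    """
    if connectivity not in (4, 8):
        raise ConfigurationError("connectivity must be 4 or 8")
    channel = grid.channel_element_mask()
    alive = channel & (grid.labels == Label.BZ)
    rows = np.flatnonzero(channel.any(axis=1))
    if rows.size == 0:
        return False
    structure = ndimage.generate_binary_structure(2, 1 if connectivity == 4
                                                  else 2)
    lab, _ = ndimage.label(alive, structure=structure)
    bottom = set(np.unique(lab[rows[0]])) - {0}
    top = set(np.unique(lab[rows[-1]])) - {0}
    return bool(bottom & top)
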