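"""Resistor-network hydraulics of the soil--root system.

The rasterized root sketch is interpreted as a lattice of hydraulic
resistors, in direct analogy with an electrical circuit: each cell carries a
resistivity, adjacent cells are joined by an edge whose resistance is the
mean of the two cell resistivities (two half-cells in series,
4-neighbourhood), and the total effective resistance between the bulk soil
and the shoot exit follows from Ohm's and Kirchhoff's laws, i.e. from a
two-point effective-resistance solve of the graph Laplacian.

Resistivity assignment
----------------------
* soil cells: the reciprocal of the Van Genuchten relative conductivity
  ``Kr(theta) = theta^(1/2) * (1 - (1 - theta^m)^m)^2`` with ``m = 1 - 1/n``
  and ``n = 2`` by default.  Near zero saturation ``Kr`` is floored at 1e-9
  (resistivity ceiling 1e9) to keep the linear system finite.
* cortex cells: a linear resistivity gradient declining with depth (younger,
  deeper root segments take up water more easily).
* stele cells: a linear gradient increasing with depth, which favours an
  upward axial flow towards the shoot.
* cap cells: infinite (impermeable surface); only the exit cell penetrates
  the cap.

The total resistance at a given saturation is the physical work the shoot
must do to extract soil water; its normalized inverse is the plant's
"vitality" (see :mod:`rhizocomp.vitality`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph, linalg as sparse_linalg

from .raster import CellClass, ConfigurationError, RasterGeometry, RootRaster, build_root_sketch

__all__ = [
    "VanGenuchtenParams",
    "ResistivityGradients",
    "ResistanceField",
    "ResistanceCurve",
    "NoHydraulicPathError",
    "RESISTIVITY_CEILING",
    "relative_conductivity",
    "soil_resistivity",
    "assign_resistivities",
    "effective_resistance",
    "resistance_curve",
]

#: resistivity ceiling applied to bone-dry soil (Kr floored at its inverse)
RESISTIVITY_CEILING = 1e9


class NoHydraulicPathError(RuntimeError):
    """Source and exit are not connected through finite-resistivity cells."""


@dataclass(frozen=True)
class VanGenuchtenParams:
    """Shape parameter of the unsaturated-conductivity model; ``m = 1 - 1/n``."""

    n: float = 2.0

    def __post_init__(self) -> None:
        if self.n <= 1:
            raise ConfigurationError("Van Genuchten n must exceed 1")

    @property
    def m(self) -> float:
        return 1.0 - 1.0 / self.n


@dataclass(frozen=True)
class ResistivityGradients:
    """Linear depth gradients of relative root-tissue resistivities.

    Cortex resistivity declines with depth (older, shallower cortex is less
    permeable); stele resistivity increases with depth (drives axial flow
    upward).  Units are relative: rescaling all resistivities rescales the
    total resistance by the same factor and cancels in the vitality
    normalization.
    """

    cortex_surface: float = 10.0
    cortex_bottom: float = 1.0
    stele_surface: float = 0.1
    stele_bottom: float = 1.0

    def __post_init__(self) -> None:
        if min(self.cortex_surface, self.cortex_bottom,
               self.stele_surface, self.stele_bottom) <= 0:
            raise ConfigurationError("gradient endpoints must be positive")
        if not self.cortex_surface > self.cortex_bottom:
            raise ConfigurationError("cortex resistivity must decline with depth")
        if not self.stele_surface < self.stele_bottom:
            raise ConfigurationError("stele resistivity must increase with depth")


@dataclass
class ResistanceField:
    """Per-cell resistivities plus the source/exit wiring of the network.

    ``source_mode`` selects how the virtual source is attached:

    * ``"virtual"`` -- a single virtual node joined to every listed source
      cell by an edge carrying that cell's own resistivity (water entering
      from the surrounding bulk soil);
    * ``"direct"`` -- the single listed source cell is itself the source
      terminal (used for hand-built series/parallel checks).
    """

    geometry: RasterGeometry
    resistivity: np.ndarray
    source_cells: np.ndarray  # (k, 2) row/col indices
    exit_cell: tuple[int, int]
    source_mode: str = "virtual"

    def __post_init__(self) -> None:
        finite = self.resistivity[np.isfinite(self.resistivity)]
        if finite.size and finite.min() <= 0:
            raise ConfigurationError("finite resistivities must be positive")
        if self.source_mode not in ("virtual", "direct"):
            raise ConfigurationError(f"unknown source mode {self.source_mode!r}")
        if self.source_mode == "direct" and len(self.source_cells) != 1:
            raise ConfigurationError("direct source mode requires one source cell")


@dataclass
class ResistanceCurve:
    """Total effective resistance sampled over saturation configurations."""

    samples: list[tuple[object, float]]
    architecture: str
    stage: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for cfg, r_total in self.samples:
            if np.isscalar(cfg):
                rows.append({"theta_total": float(cfg), "R_total": r_total})
            else:
                top, sub = cfg
                rows.append({"theta_top": float(top), "theta_sub": float(sub),
                             "R_total": r_total})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def relative_conductivity(theta, params: VanGenuchtenParams | None = None):
    """Van Genuchten relative hydraulic conductivity ``Kr(theta)`` in [0, 1].

    ``Kr = theta^(1/2) * (1 - (1 - theta^m)^m)^2`` with ``m = 1 - 1/n``.
    Accepts scalars or arrays; saturation outside [0, 1] is a domain error.
    """
    params = params or VanGenuchtenParams()
    th = np.asarray(theta, dtype=float)
    if np.any(th < 0) or np.any(th > 1):
        raise ValueError("saturation must lie in [0, 1]")
    m = params.m
    kr = np.sqrt(th) * (1.0 - (1.0 - th**m) ** m) ** 2
    return kr if kr.ndim else float(kr)


def soil_resistivity(theta, params: VanGenuchtenParams | None = None):
    """Soil cell resistivity ``1/Kr``, capped at :data:`RESISTIVITY_CEILING`."""
    kr = np.asarray(relative_conductivity(theta, params), dtype=float)
    with np.errstate(divide="ignore"):
        rho = np.minimum(1.0 / kr, RESISTIVITY_CEILING)
    return rho if rho.ndim else float(rho)


def _boundary_source_cells(soil_mask: np.ndarray) -> np.ndarray:
    """Soil cells on the bottom row and the two lateral boundary columns."""
    n_rows, n_cols = soil_mask.shape
    sel = np.zeros_like(soil_mask)
    sel[-1, :] = True
    sel[:, 0] = True
    sel[:, -1] = True
    sel &= soil_mask
    return np.argwhere(sel)


def assign_resistivities(
    raster: RootRaster,
    saturation,
    gradients: ResistivityGradients | None = None,
    vg: VanGenuchtenParams | None = None,
    source_spec: str = "boundary",
) -> ResistanceField:
    """Map a saturation state onto per-cell resistivities.

    ``saturation`` is either a single value applied uniformly or a
    ``(theta_top, theta_sub)`` pair applied above and below the topsoil
    boundary -- the hydrophobic case, where a dry topsoil pins soil
    resistivities at the ceiling while the subsoil stays conductive.

    ``source_spec`` picks the cells wired to the virtual source node:
    ``"boundary"`` (bottom row plus the lateral columns, water arriving from
    the surrounding bulk soil) or ``"all_soil"``.
    """
    gradients = gradients or ResistivityGradients()
    vg = vg or VanGenuchtenParams()
    cells = raster.cells
    n_rows, n_cols = cells.shape
    rho = np.empty((n_rows, n_cols), dtype=float)

    if np.isscalar(saturation):
        theta_grid = np.full(n_rows, float(saturation))
    else:
        top, sub = saturation
        theta_grid = np.where(
            np.arange(n_rows) < raster.geometry.topsoil_rows, float(top), float(sub)
        )
    rho_soil_by_row = soil_resistivity(theta_grid, vg)

    soil = cells == CellClass.SOIL
    rho[:] = rho_soil_by_row[:, None]

    stele_rows = np.nonzero(cells == CellClass.STELE)[0]
    max_root_row = int(stele_rows.max()) if stele_rows.size else 1
    depth_frac = np.arange(n_rows) / max(max_root_row, 1)
    cortex_by_row = gradients.cortex_surface + (
        gradients.cortex_bottom - gradients.cortex_surface
    ) * depth_frac
    stele_by_row = gradients.stele_surface + (
        gradients.stele_bottom - gradients.stele_surface
    ) * depth_frac

    cortex = cells == CellClass.CORTEX
    stele = cells == CellClass.STELE
    rho[cortex] = np.broadcast_to(cortex_by_row[:, None], rho.shape)[cortex]
    rho[stele] = np.broadcast_to(stele_by_row[:, None], rho.shape)[stele]
    rho[cells == CellClass.CAP] = np.inf
    exit_cell = raster.exit_cell
    rho[exit_cell] = gradients.stele_surface  # stele tissue penetrating the cap

    if source_spec == "boundary":
        source_cells = _boundary_source_cells(soil)
    elif source_spec == "all_soil":
        source_cells = np.argwhere(soil)
    else:
        raise ConfigurationError(f"unknown source spec {source_spec!r}")
    if source_cells.size == 0:
        raise ConfigurationError("no soil cells available as source")

    return ResistanceField(
        geometry=raster.geometry,
        resistivity=rho,
        source_cells=source_cells,
        exit_cell=exit_cell,
    )


def _build_network(field: ResistanceField):
    """Index finite cells, build edge lists, and return (n_nodes, edges, src, exit)."""
    rho = field.resistivity
    finite = np.isfinite(rho)
    n_rows, n_cols = rho.shape
    index = -np.ones((n_rows, n_cols), dtype=np.int64)
    n_cells = int(finite.sum())
    index[finite] = np.arange(n_cells)

    ii, jj, cc = [], [], []

    def add_pairs(mask_a, idx_a, mask_b, idx_b, rho_a, rho_b):
        ok = mask_a & mask_b
        if not ok.any():
            return
        ii.append(idx_a[ok])
        jj.append(idx_b[ok])
        cc.append(2.0 / (rho_a[ok] + rho_b[ok]))

    # horizontal edges
    add_pairs(finite[:, :-1], index[:, :-1], finite[:, 1:], index[:, 1:],
              rho[:, :-1], rho[:, 1:])
    # vertical edges
    add_pairs(finite[:-1, :], index[:-1, :], finite[1:, :], index[1:, :],
              rho[:-1, :], rho[1:, :])

    exit_idx = int(index[field.exit_cell])
    if exit_idx < 0:
        raise NoHydraulicPathError("exit cell has infinite resistivity")

    src_rc = np.asarray(field.source_cells)
    src_idx_cells = index[src_rc[:, 0], src_rc[:, 1]]
    if np.any(src_idx_cells < 0):
        raise ConfigurationError("source cells must have finite resistivity")

    if field.source_mode == "virtual":
        source_idx = n_cells
        n_nodes = n_cells + 1
        ii.append(np.full(len(src_rc), source_idx, dtype=np.int64))
        jj.append(src_idx_cells.astype(np.int64))
        cc.append(1.0 / rho[src_rc[:, 0], src_rc[:, 1]])
    else:
        source_idx = int(src_idx_cells[0])
        n_nodes = n_cells

    if ii:
        i = np.concatenate(ii)
        j = np.concatenate(jj)
        c = np.concatenate(cc)
    else:
        i = j = np.empty(0, dtype=np.int64)
        c = np.empty(0)
    return n_nodes, i, j, c, source_idx, exit_idx


def effective_resistance(field: ResistanceField) -> float:
    """Two-point effective resistance between the source and the shoot exit.

    Solves the grounded graph Laplacian of the lattice network with a unit
    current injected at the source; the source potential is the resistance.
    Raises :class:`NoHydraulicPathError` when no finite-resistivity path
    connects source and exit.
    """
    n_nodes, i, j, c, source_idx, exit_idx = _build_network(field)
    if source_idx == exit_idx:
        return 0.0
    adj = sparse.coo_matrix((c, (i, j)), shape=(n_nodes, n_nodes))
    adj = adj + adj.T
    n_comp, labels = csgraph.connected_components(adj, directed=False)
    if labels[source_idx] != labels[exit_idx]:
        raise NoHydraulicPathError("no hydraulic path between source and exit")

    lap = sparse.diags(np.asarray(adj.sum(axis=1)).ravel()) - adj
    keep = np.ones(n_nodes, dtype=bool)
    keep[exit_idx] = False
    # restrict to the component containing source/exit to keep the system SPD
    keep &= labels == labels[source_idx]
    sub = lap.tocsr()[keep][:, keep].tocsc()
    reduced_index = np.cumsum(keep) - 1
    b = np.zeros(int(keep.sum()))
    b[reduced_index[source_idx]] = 1.0
    # MMD ordering suits the symmetric lattice Laplacian far better than COLAMD
    v = sparse_linalg.spsolve(sub, b, permc_spec="MMD_AT_PLUS_A")
    return float(v[reduced_index[source_idx]])


def resistance_curve(
    architecture_or_raster,
    stage: int | None = None,
    saturation_grid: Sequence | None = None,
    gradients: ResistivityGradients | None = None,
    vg: VanGenuchtenParams | None = None,
    geometry: RasterGeometry | None = None,
    total_length_cm: float | None = None,
    source_spec: str = "boundary",
) -> ResistanceCurve:
    """Sweep saturation configurations and solve the network at each point.

    The first argument is either a prepared :class:`RootRaster` (with cortex
    already derived) or an architecture name, in which case the canonical
    sketch for ``stage`` is built and its cortex derived.  The default grid
    is 21 uniform saturation steps of 0.05.
    """
    from .raster import derive_cortex  # local import to avoid cycle at module load

    if isinstance(architecture_or_raster, RootRaster):
        raster = architecture_or_raster
    else:
        raster = derive_cortex(
            build_root_sketch(architecture_or_raster, stage, geometry,
                              total_length_cm=total_length_cm)
        )
    if saturation_grid is None:
        saturation_grid = np.round(np.linspace(0.0, 1.0, 21), 10)
    samples = []
    for cfg in saturation_grid:
        cfg_val = float(cfg) if np.isscalar(cfg) else (float(cfg[0]), float(cfg[1]))
        fld = assign_resistivities(raster, cfg_val, gradients, vg, source_spec)
        samples.append((cfg_val, effective_resistance(fld)))
    return ResistanceCurve(samples=samples, architecture=raster.architecture,
                           stage=raster.stage)
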