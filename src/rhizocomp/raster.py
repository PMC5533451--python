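"""Rasterized root-system sketches.

Two contrasting root architectures are drawn as one-cell-wide skeletons on a
1 mm-resolution grid of a vertical soil cross-section (60 cm wide, 100 cm
deep by default):

* **fibrous** -- many adventitious branches fanning out from the shoot axis,
  confined to the topsoil (monocot-typical, e.g. maize);
* **tap** -- one vertical primary root reaching the bottom of the profile
  plus pairs of lateral branches, denser in the topsoil (dicot-typical).

Each architecture is drawn at two developmental stages with a fixed total
skeleton length per stage (intermediate stage: 129.7 cm, fully developed:
391.9 cm), identical across architectures so that their hydraulic
resistances are comparable.  During the germination stage (first week) no
water uptake is assumed and no sketch exists.

Cell classes: soil, stele (the one-cell-wide root skeleton carrying axial
flow), cortex (one-cell sheath around the stele), cap (impermeable soil
surface), and a single exit cell in the cap row connecting the stele to the
shoot.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "CellClass",
    "RasterGeometry",
    "RootRaster",
    "ConfigurationError",
    "STAGE_LENGTH_CM",
    "FIBROUS_BRANCH_COUNT",
    "TAP_LATERAL_PAIRS",
    "build_root_sketch",
    "total_root_length",
    "derive_cortex",
    "count_branches",
    "to_ascii",
    "from_ascii",
    "to_json",
    "from_json",
]


class ConfigurationError(ValueError):
    """Raised for invalid architecture/stage/geometry combinations."""


class CellClass:
    """Integer codes for raster cell classes."""

    SOIL = 0
    STELE = 1
    CORTEX = 2
    CAP = 3
    EXIT = 4


CLASS_CHARS = {
    CellClass.SOIL: ".",
    CellClass.STELE: "S",
    CellClass.CORTEX: "C",
    CellClass.CAP: "#",
    CellClass.EXIT: "E",
}
CHARS_CLASS = {v: k for k, v in CLASS_CHARS.items()}

#: canonical total skeleton length per growth stage, cm
STAGE_LENGTH_CM = {2: 129.7, 3: 391.9}
#: adventitious branches of the fibrous system per stage
FIBROUS_BRANCH_COUNT = {2: 7, 3: 13}
#: lateral branch pairs of the tap system per stage
TAP_LATERAL_PAIRS = {2: 1, 3: 7}
#: lateral origin depths as fractions of profile depth (topsoil-dense)
TAP_LATERAL_DEPTH_FRACTIONS = {
    2: (0.03,),
    3: (0.03, 0.09, 0.16, 0.24, 0.33, 0.56, 0.80),
}
#: half-opening angle of the fibrous fan, degrees from vertical
FIBROUS_FAN_HALF_ANGLE_DEG = 40.0
#: downward dip of tap laterals, degrees below horizontal
TAP_LATERAL_DIP_DEG = 10.0

ARCHITECTURES = ("fibrous", "tap")
STAGES = (2, 3)


@dataclass(frozen=True)
class RasterGeometry:
    """Soil cross-section geometry (all lengths in cm)."""

    width_cm: float = 60.0
    depth_cm: float = 100.0
    cell_size_cm: float = 0.1
    topsoil_boundary_cm: float = 50.0

    def __post_init__(self) -> None:
        for name in ("width_cm", "depth_cm", "cell_size_cm"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.topsoil_boundary_cm < self.depth_cm:
            raise ConfigurationError("topsoil boundary must lie inside the profile")
        for name in ("width_cm", "depth_cm"):
            ratio = getattr(self, name) / self.cell_size_cm
            if abs(ratio - round(ratio)) > 1e-9:
                raise ConfigurationError(f"{name} must be a multiple of cell_size_cm")

    @property
    def n_cols(self) -> int:
        return round(self.width_cm / self.cell_size_cm)

    @property
    def n_rows(self) -> int:
        return round(self.depth_cm / self.cell_size_cm)

    @property
    def topsoil_rows(self) -> int:
        """Number of raster rows belonging to the topsoil."""
        return round(self.topsoil_boundary_cm / self.cell_size_cm)


@dataclass
class RootRaster:
    """Cell-class grid of one root system at one growth stage."""

    geometry: RasterGeometry
    cells: np.ndarray
    architecture: str
    stage: int

    @property
    def exit_cell(self) -> tuple[int, int]:
        rows, cols = np.nonzero(self.cells == CellClass.EXIT)
        if rows.size != 1:
            raise ValueError("raster must contain exactly one exit cell")
        return int(rows[0]), int(cols[0])

    def stele_mask(self) -> np.ndarray:
        return self.cells == CellClass.STELE


def _spread(total: int, parts: int) -> list[int]:
    """Split ``total`` cells into ``parts`` near-equal integer quotas."""
    base, rem = divmod(total, parts)
    return [base + (1 if i < rem else 0) for i in range(parts)]


def _walk_ray(
    start: tuple[int, int],
    direction: tuple[float, float],
    quota: int,
    stele: set[tuple[int, int]],
    n_rows: int,
    n_cols: int,
    max_row: int,
) -> None:
    """Add ``quota`` new skeleton cells along a ray, sharing cells already drawn.

    The ray is sampled at half-cell steps and rounded to the grid, which keeps
    successive cells 8-adjacent.  Cells already occupied (e.g. near a common
    branching point) do not count towards the quota; the ray simply extends
    until its quota of fresh cells is met.  Running out of admissible grid
    before the quota is filled is a configuration error: the requested total
    root length does not fit the geometry.
    """
    r0, c0 = start
    dr, dc = direction
    added = 0
    if (r0, c0) not in stele:
        stele.add((r0, c0))
        added += 1
    t = 0.0
    max_t = 4.0 * (n_rows + n_cols)  # hard stop, never reached for valid layouts
    while added < quota:
        t += 0.5
        r = round(r0 + t * dr)
        c = round(c0 + t * dc)
        if not (1 <= r < min(n_rows, max_row) and 0 <= c < n_cols):
            raise ConfigurationError(
                "root sketch does not fit the raster geometry; "
                "reduce total length or enlarge the profile"
            )
        if (r, c) not in stele:
            stele.add((r, c))
            added += 1
        if t > max_t:  # pragma: no cover - defensive
            raise ConfigurationError("ray walk failed to terminate")


def build_root_sketch(
    architecture: str,
    stage: int,
    geometry: RasterGeometry | None = None,
    total_length_cm: float | None = None,
) -> RootRaster:
    """Draw the canonical skeleton sketch of a root system.

    Parameters
    ----------
    architecture : {"fibrous", "tap"}
    stage : {2, 3}
        Intermediate (2) or fully developed (3) growth stage.  The
        germination stage has no sketch because no uptake is assumed.
    geometry : RasterGeometry, optional
    total_length_cm : float, optional
        Override of the canonical total skeleton length; mainly useful for
        drawing reduced sketches on small test geometries.

    The exact branch angles and spacings of the original hand-drawn sketches
    are not published; the generator uses a deterministic parametric layout
    (a symmetric fan for the fibrous system, depth-graded lateral pairs for
    the tap system) whose per-branch cell quotas are balanced so that the
    total skeleton cell count times the cell size matches the stage total
    exactly.  Both architectures therefore have identical total length at
    each stage by construction.
    """
    if architecture not in ARCHITECTURES:
        raise ConfigurationError(f"unknown architecture {architecture!r}")
    if stage not in STAGES:
        raise ConfigurationError(f"unknown growth stage {stage!r}")
    geometry = geometry or RasterGeometry()
    target_cm = STAGE_LENGTH_CM[stage] if total_length_cm is None else total_length_cm
    n_cells = round(target_cm / geometry.cell_size_cm)
    if n_cells < 1:
        raise ConfigurationError("total root length must cover at least one cell")

    n_rows, n_cols = geometry.n_rows, geometry.n_cols
    exit_col = n_cols // 2
    cells = np.full((n_rows, n_cols), CellClass.SOIL, dtype=np.uint8)
    cells[0, :] = CellClass.CAP
    cells[0, exit_col] = CellClass.EXIT

    stele: set[tuple[int, int]] = set()
    origin = (1, exit_col)

    if architecture == "fibrous":
        n_branches = FIBROUS_BRANCH_COUNT[stage]
        half = math.radians(FIBROUS_FAN_HALF_ANGLE_DEG)
        angles = np.linspace(-half, half, n_branches)
        quotas = _spread(n_cells, n_branches)
        for angle, quota in zip(angles, quotas):
            direction = (math.cos(angle), math.sin(angle))
            _walk_ray(origin, direction, quota, stele, n_rows, n_cols,
                      max_row=geometry.topsoil_rows)
    else:
        # principal vertical root reaches final depth at both stages
        for r in range(1, n_rows):
            stele.add((r, exit_col))
        remaining = n_cells - (n_rows - 1)
        if remaining < 0:
            raise ConfigurationError(
                "total root length shorter than the vertical root; "
                "tap sketch cannot reach the bottom of the profile"
            )
        fractions = TAP_LATERAL_DEPTH_FRACTIONS[stage]
        n_laterals = 2 * TAP_LATERAL_PAIRS[stage]
        quotas = _spread(remaining, n_laterals)
        dip = math.radians(TAP_LATERAL_DIP_DEG)
        i = 0
        for frac in fractions:
            row = max(1, round(frac * n_rows))
            for sign in (-1, 1):
                quota = quotas[i]
                i += 1
                if quota == 0:
                    continue
                direction = (math.sin(dip), sign * math.cos(dip))
                _walk_ray((row, exit_col), direction, quota, stele,
                          n_rows, n_cols, max_row=n_rows)

    rows = np.fromiter((r for r, _ in stele), dtype=np.intp, count=len(stele))
    cols = np.fromiter((c for _, c in stele), dtype=np.intp, count=len(stele))
    cells[rows, cols] = CellClass.STELE
    return RootRaster(geometry=geometry, cells=cells,
                      architecture=architecture, stage=stage)


def total_root_length(raster: RootRaster) -> float:
    """Total skeleton length in cm: stele cell count times cell size."""
    return int(np.count_nonzero(raster.stele_mask())) * raster.geometry.cell_size_cm


def derive_cortex(raster: RootRaster) -> RootRaster:
    """Wrap the stele in a one-cell cortex sheath (8-neighbourhood dilation).

    Every non-stele cell 8-adjacent to a stele cell becomes cortex.  The cap
    row stays impermeable except immediately around the exit, where the
    sheath follows the stele through the surface.  Returns a new raster; the
    input is not modified.
    """
    cells = raster.cells.copy()
    stele = cells == CellClass.STELE
    if not stele.any():
        return RootRaster(raster.geometry, cells, raster.architecture, raster.stage)
    dilated = ndimage.binary_dilation(stele, structure=np.ones((3, 3), bool))
    sheath = dilated & ~stele & ~(cells == CellClass.EXIT)
    exit_row, exit_col = raster.exit_cell
    cap_row = sheath[exit_row]
    near_exit = np.zeros_like(cap_row)
    lo, hi = max(0, exit_col - 1), min(cells.shape[1], exit_col + 2)
    near_exit[lo:hi] = True
    sheath[exit_row] = cap_row & near_exit
    cells[sheath] = CellClass.CORTEX
    return RootRaster(raster.geometry, cells, raster.architecture, raster.stage)


def count_branches(raster: RootRaster, exclusion_radius: int = 25) -> int:
    """Count root branches by skeleton-graph component analysis.

    For the fibrous system, all branches emanate from the shoot origin and
    may share their first few cells; cells within ``exclusion_radius`` of the
    origin are removed and the remaining 8-connected stele components are
    counted.  For the tap system the exit column (the vertical root) is
    removed and the remaining components are the individual laterals, so the
    returned count is twice the number of lateral pairs.
    """
    stele = raster.stele_mask().copy()
    _, exit_col = raster.exit_cell
    if raster.architecture == "tap":
        stele[:, exit_col] = False
    else:
        rr, cc = np.mgrid[0 : stele.shape[0], 0 : stele.shape[1]]
        near = (rr - 1) ** 2 + (cc - exit_col) ** 2 <= exclusion_radius**2
        stele[near] = False
    _, n = ndimage.label(stele, structure=np.ones((3, 3), int))
    return int(n)


# ---------------------------------------------------------------------------
# plain-text export / import

def to_ascii(raster: RootRaster) -> str:
    lut = np.array([CLASS_CHARS[k] for k in range(5)])
    return "\n".join("".join(row) for row in lut[raster.cells])


def from_ascii(
    text: str,
    cell_size_cm: float = 0.1,
    topsoil_boundary_cm: float | None = None,
    architecture: str = "fibrous",
    stage: int = 2,
) -> RootRaster:
    lines = [ln for ln in text.strip("\n").split("\n") if ln]
    cells = np.array([[CHARS_CLASS[ch] for ch in ln] for ln in lines], dtype=np.uint8)
    depth = cells.shape[0] * cell_size_cm
    geometry = RasterGeometry(
        width_cm=cells.shape[1] * cell_size_cm,
        depth_cm=depth,
        cell_size_cm=cell_size_cm,
        topsoil_boundary_cm=topsoil_boundary_cm if topsoil_boundary_cm is not None else depth / 2,
    )
    return RootRaster(geometry, cells, architecture, stage)


def to_json(raster: RootRaster) -> str:
    """Run-length-encoded JSON document (row-major)."""
    flat = raster.cells.ravel()
    boundaries = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [flat.size]))
    rle = [[CLASS_CHARS[int(flat[s])], int(e - s)] for s, e in zip(starts, ends)]
    g = raster.geometry
    doc = {
        "geometry": {
            "width_cm": g.width_cm,
            "depth_cm": g.depth_cm,
            "cell_size_cm": g.cell_size_cm,
            "topsoil_boundary_cm": g.topsoil_boundary_cm,
        },
        "architecture": raster.architecture,
        "stage": raster.stage,
        "rle": rle,
    }
    return json.dumps(doc)


def from_json(doc: str) -> RootRaster:
    data = json.loads(doc)
    geometry = RasterGeometry(**data["geometry"])
    flat = np.empty(geometry.n_rows * geometry.n_cols, dtype=np.uint8)
    pos = 0
    for char, count in data["rle"]:
        flat[pos : pos + count] = CHARS_CLASS[char]
        pos += count
    if pos != flat.size:
        raise ValueError("run-length data does not match geometry")
    cells = flat.reshape(geometry.n_rows, geometry.n_cols)
    return RootRaster(geometry, cells, data["architecture"], data["stage"])
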