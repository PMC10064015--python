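"""Unbiased terminal sampling (UTS) over an annotated label stack.

A sampling array consists of several square stereology grids of counting
frames placed on regularly spaced reference sections of the stack.  Each
frame is a classical unbiased counting frame: the right and top edges are
inclusion lines, the left and bottom edges are exclusion (forbidden) lines
with the standard infinite extensions beyond the corners (upward from the
top-left corner and downward from the bottom-right corner).  A synapse whose
footprint on the reference section intersects the frame and does not touch
the forbidden line is sampled; with frames tiling the plane this gives every
object exactly one chance of being counted.

Coordinates are 0-based and frames are half-open ``[x0, x0+w) x [y0, y0+w)``
in voxel units, so counting is reproducible bit-exactly.  In voxel terms the
forbidden line of a frame lies between the frame and the neighboring voxel
columns/rows; a footprint touches it when it contains a voxel in

* column ``x0 - 1`` at rows ``>= y0 - 1``  (left line and upward extension),
* row ``y0 - 1`` at columns ``x0 - 1 .. x0 + w - 1``  (bottom line),
* column ``x0 + w - 1`` at rows ``<= y0 - 1``  (downward extension).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataIntegrityError, GeometryError

logger = logging.getLogger(__name__)

STATUSES = ("not_examined", "empty", "soma", "synapse_sampled", "excluded")


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a stereology grid array.

    Defaults follow the published design: six 15 x 15 grids of 2.5 um
    frames on reference sections 33 sections (2.475 um at 75 nm thickness)
    apart, yielding 1,350 sequentially numbered locations.
    """

    grids_per_array: int = 6
    cells_per_side: int = 15
    frame_side_um: float = 2.5
    grid_z_spacing: int = 33
    section_thickness_nm: float = 75.0
    reference_sections: tuple = ()
    origin_xy: tuple = (0, 0)

    def __post_init__(self):
        if self.grids_per_array < 1 or self.cells_per_side < 1:
            raise ConfigurationError("grid counts must be >= 1")
        if self.frame_side_um <= 0:
            raise ConfigurationError("frame side must be positive")
        if self.grid_z_spacing < 1:
            raise ConfigurationError("grid z-spacing must be >= 1 section")
        if self.reference_sections and len(self.reference_sections) != self.grids_per_array:
            raise ConfigurationError(
                "reference_sections must list one section per grid"
            )

    @property
    def total_locations(self) -> int:
        return self.grids_per_array * self.cells_per_side**2

    @property
    def inter_grid_distance_um(self) -> float:
        return self.grid_z_spacing * self.section_thickness_nm / 1000.0

    def reference_planes(self) -> tuple:
        if self.reference_sections:
            return tuple(self.reference_sections)
        return tuple(g * self.grid_z_spacing for g in range(self.grids_per_array))


@dataclass
class LocationSample:
    """One counting-frame location of the sampling array."""

    location_id: int  # sequential, 1-based
    grid: int
    cell: tuple  # (row, col)
    status: str = "not_examined"
    sampled_synapse_ids: list = field(default_factory=list)


@dataclass(frozen=True)
class FrameGeometry:
    """Half-open counting frame [x0, x0+w) x [y0, y0+w) on section z."""

    x0: int
    y0: int
    width: int
    z: int


def frame_width_voxels(grid: GridSpec, voxel_xy_nm: float) -> int:
    w = grid.frame_side_um * 1000.0 / voxel_xy_nm
    if abs(w - round(w)) > 1e-6:
        raise ConfigurationError(
            f"frame side {grid.frame_side_um} um is not an integer number of "
            f"{voxel_xy_nm} nm voxels"
        )
    return int(round(w))


def build_array(
    grid: GridSpec,
    stack_shape: tuple,
    voxel_xy_nm: float = 5.0,
) -> tuple[list, dict]:
    """Lay out all counting frames; returns (locations, frames-by-location).

    ``stack_shape`` is (nx, ny, nz) voxels.  Adjacent frames share boundary
    lines (inclusion lines of neighboring frames are one frame side apart).
    Raises :class:`GeometryError` reporting the minimum required dimensions
    when the stack cannot host the full array.
    """
    nx, ny, nz = stack_shape
    w = frame_width_voxels(grid, voxel_xy_nm)
    ox, oy = grid.origin_xy
    need_xy = grid.cells_per_side * w
    planes = grid.reference_planes()
    need_z = max(planes) + 1
    if ox + need_xy > nx or oy + need_xy > ny or need_z > nz:
        raise GeometryError(
            f"stack {stack_shape} too small for the array: needs at least "
            f"({ox + need_xy}, {oy + need_xy}, {need_z}) voxels"
        )
    locations = []
    frames = {}
    loc_id = 1
    for g in range(grid.grids_per_array):
        z = planes[g]
        for row in range(grid.cells_per_side):
            for col in range(grid.cells_per_side):
                locations.append(LocationSample(loc_id, g, (row, col)))
                frames[loc_id] = FrameGeometry(
                    x0=ox + col * w, y0=oy + row * w, width=w, z=z
                )
                loc_id += 1
    return locations, frames


def select_locations(locations: list, fraction: float, seed: int | None = None) -> list:
    """Uniform selection without replacement of round(fraction * total) ids."""
    if not 0.0 < fraction <= 1.0:
        raise ConfigurationError("fraction must lie in (0, 1]")
    ids = np.array([loc.location_id for loc in locations])
    n_pick = int(round(fraction * len(ids)))
    rng = np.random.default_rng(seed)
    chosen = rng.choice(ids, size=n_pick, replace=False)
    return sorted(int(i) for i in chosen)


def test_inclusion(footprint, frame: FrameGeometry) -> str:
    """Counting-frame decision for a synapse footprint on the frame's section.

    ``footprint`` is an (n, 2) array-like of (x, y) voxel coordinates.
    Returns ``"included"``, ``"excluded"`` (touches the forbidden line) or
    ``"outside"`` (no contact with the frame).
    """
    fp = np.atleast_2d(np.asarray(footprint, dtype=int))
    if fp.size == 0:
        raise DataIntegrityError("empty synapse footprint")
    x, y = fp[:, 0], fp[:, 1]
    x0, y0, w = frame.x0, frame.y0, frame.width
    x1 = x0 + w
    forbidden = (
        ((x == x0 - 1) & (y >= y0 - 1))
        | ((y == y0 - 1) & (x >= x0 - 1) & (x <= x1 - 1))
        | ((x == x1 - 1) & (y <= y0 - 1))
    )
    if forbidden.any():
        return "excluded"
    in_region = (x >= x0) & (x < x1) & (y >= y0) & (y < y0 + w)
    return "included" if in_region.any() else "outside"


def _footprints_on_plane(labels_plane: np.ndarray) -> dict:
    """Map synapse id -> (n, 2) array of (x, y) voxels on one section."""
    out = {}
    for sid in np.unique(labels_plane):
        if sid == 0:
            continue
        yy, xx = np.nonzero(labels_plane == sid)
        out[int(sid)] = np.column_stack([xx, yy])
    return out


def run_uts(
    stack: np.ndarray,
    synapse_table: pd.DataFrame,
    population: pd.DataFrame,
    grid: GridSpec,
    fraction: float = 0.5,
    seed: int | None = None,
    voxel_xy_nm: float = 5.0,
    soma_mask: np.ndarray | None = None,
) -> tuple[pd.DataFrame, dict, list]:
    """Run the full unbiased sampling over a label stack.

    ``stack`` is a ``[z, y, x]`` label volume; ``synapse_table`` maps
    synapse ids to bouton ids; ``population`` holds the bouton records.
    Returns ``(sampled_boutons, tally, locations)`` where ``tally`` counts
    location statuses over the examined subset.  A synapse intersecting two
    reference sections is credited to the lower-index grid only; every
    sampled synapse contributes its bouton's volume exactly once.
    """
    nz, ny, nx = stack.shape
    locations, frames = build_array(grid, (nx, ny, nz), voxel_xy_nm)
    chosen = set(select_locations(locations, fraction, seed))
    planes = grid.reference_planes()
    plane_footprints = {z: _footprints_on_plane(stack[z]) for z in set(planes)}

    bouton_by_id = population.set_index("bouton_id")
    syn_to_bouton = dict(
        zip(synapse_table["synapse_id"], synapse_table["bouton_id"])
    )

    # lower-grid-only assignment for synapses spanning two reference planes
    first_grid_of_synapse: dict[int, int] = {}
    for g in range(grid.grids_per_array):
        for sid in plane_footprints[planes[g]]:
            if sid not in first_grid_of_synapse:
                first_grid_of_synapse[sid] = g
            elif first_grid_of_synapse[sid] != g:
                logger.warning(
                    "synapse %d intersects reference sections of grids %d and %d; "
                    "assigned to grid %d",
                    sid, first_grid_of_synapse[sid], g, first_grid_of_synapse[sid],
                )

    sampled_rows = []
    sampled_ids = set()
    for loc in locations:
        if loc.location_id not in chosen:
            continue
        fr = frames[loc.location_id]
        if soma_mask is not None:
            region = soma_mask[fr.z, fr.y0 : fr.y0 + fr.width, fr.x0 : fr.x0 + fr.width]
            if region.all():
                loc.status = "soma"
                continue
        footprints = plane_footprints[fr.z]
        included, excluded = [], []
        for sid, fp in footprints.items():
            if first_grid_of_synapse.get(sid) != loc.grid:
                continue
            verdict = test_inclusion(fp, fr)
            if verdict == "included":
                included.append(sid)
            elif verdict == "excluded":
                excluded.append(sid)
        if included:
            loc.status = "synapse_sampled"
            loc.sampled_synapse_ids = sorted(included)
            for sid in included:
                if sid in sampled_ids:
                    continue
                sampled_ids.add(sid)
                if sid not in syn_to_bouton:
                    raise DataIntegrityError(
                        f"synapse {sid} has no bouton link in the synapse table"
                    )
                bid = syn_to_bouton[sid]
                if bid not in bouton_by_id.index:
                    raise DataIntegrityError(
                        f"synapse {sid} links to unknown bouton {bid}"
                    )
                rec = bouton_by_id.loc[bid]
                sampled_rows.append((sid, bid, *rec.drop("segment_id", errors="ignore")))
        elif excluded:
            loc.status = "excluded"
        else:
            loc.status = "empty"

    cols = ["synapse_id", "bouton_id"] + [
        c for c in population.columns if c not in ("bouton_id", "segment_id")
    ]
    sampled = pd.DataFrame(sampled_rows, columns=cols)
    tally = {s: 0 for s in STATUSES}
    for loc in locations:
        tally[loc.status] += 1
    return sampled, tally, locations
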