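"""Rectangular cell-grid geometry of a young lateral root.

The organ is discretized as an ``n_cols x n_rows`` grid of quadrilateral
cells. Every cell wall is a linear spring connecting two vertices, and each
cell additionally exerts turgor pressure on its own walls (see
:mod:`lrbend.mechanics`). Conventions, fixed once for the whole package:

* x increases from the organ tip (x = 0) toward the base, where the lateral
  root joins the parent root; the base column of vertices is clamped in x.
* y increases upward; gravity points along ``(0, -1)``. Row 0 is the lower
  (gravity-side) flank, row ``n_rows - 1`` the upper flank.
* A lateral root emerges horizontally, so the initial base-to-tip axis makes
  a 90 degree angle with the gravity vector.

The tissue is stored struct-of-arrays (positions, wall endpoint indices,
resting lengths, ...) so force evaluation vectorizes; the ``Vertex`` /
``Wall`` / ``Cell`` record types of the conceptual model correspond to rows
of those arrays.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np

SCHEMA_VERSION = 1


@dataclasses.dataclass
class Tissue:
    """State of the cell grid evolved by the simulator.

    Vertices
    --------
    positions, velocities, forces : (n_vertices, 2) float arrays, um and
        um per model-hour; ``fixed_x`` marks the base boundary column whose
        x-coordinates never change.

    Walls
    -----
    ``wall_vertices[w] = (u, v)`` indexes the two endpoint vertices,
    ``wall_rest`` the resting (stress-free) length in um, ``wall_axial``
    whether the wall runs along the organ axis, ``wall_level`` the row level
    ``0..n_rows`` of an axial wall (-1 for transverse walls) and
    ``wall_stiffness`` the spring constant.

    Cells
    -----
    ``cell_walls[c]`` lists the four wall ids counter-clockwise
    (bottom, right, top, left); ``cell_edges[c]`` the corresponding directed
    vertex pairs, used for outward pressure normals and the shoelace area.
    ``cell_tip`` marks non-growing tip-zone cells, ``elongating`` the cells
    whose axial walls extend their resting length.
    """

    positions: np.ndarray
    velocities: np.ndarray
    forces: np.ndarray
    fixed_x: np.ndarray
    wall_vertices: np.ndarray
    wall_rest: np.ndarray
    wall_axial: np.ndarray
    wall_level: np.ndarray
    wall_stiffness: np.ndarray
    cell_walls: np.ndarray
    cell_edges: np.ndarray
    cell_row: np.ndarray
    cell_col: np.ndarray
    cell_tip: np.ndarray
    elongating: np.ndarray
    n_cols: int
    n_rows: int
    cell_width: float
    cell_height: float
    gravity_direction: np.ndarray = dataclasses.field(
        default_factory=lambda: np.array([0.0, -1.0]))
    sim_time: float = 0.0
    relaxed: bool = False
    tip_zone_length: float | None = None

    # ---- derived quantities -------------------------------------------------

    @property
    def n_vertices(self) -> int:
        return self.positions.shape[0]

    @property
    def n_walls(self) -> int:
        return self.wall_vertices.shape[0]

    @property
    def n_cells(self) -> int:
        return self.cell_walls.shape[0]

    def vertex_id(self, col: int, row: int) -> int:
        """Vertex index of grid node (col in 0..n_cols, row in 0..n_rows)."""
        return col * (self.n_rows + 1) + row

    def cell_id(self, col: int, row: int) -> int:
        return col * self.n_rows + row

    def wall_lengths(self) -> np.ndarray:
        d = self.positions[self.wall_vertices[:, 0]] - \
            self.positions[self.wall_vertices[:, 1]]
        return np.linalg.norm(d, axis=1)

    def cell_areas(self) -> np.ndarray:
        """Signed shoelace area per cell (> 0 for a healthy CCW cell)."""
        a = self.positions[self.cell_edges[:, :, 0]]
        b = self.positions[self.cell_edges[:, :, 1]]
        return 0.5 * np.sum(a[:, :, 0] * b[:, :, 1] - b[:, :, 0] * a[:, :, 1],
                            axis=1)

    def cell_axial_lengths(self) -> np.ndarray:
        """Current axial length per cell: mean of its two axial wall lengths."""
        lengths = self.wall_lengths()
        bottom = lengths[self.cell_walls[:, 0]]
        top = lengths[self.cell_walls[:, 2]]
        return 0.5 * (bottom + top)

    def copy(self) -> "Tissue":
        return dataclasses.replace(
            self,
            positions=self.positions.copy(),
            velocities=self.velocities.copy(),
            forces=self.forces.copy(),
            fixed_x=self.fixed_x.copy(),
            wall_vertices=self.wall_vertices.copy(),
            wall_rest=self.wall_rest.copy(),
            wall_axial=self.wall_axial.copy(),
            wall_level=self.wall_level.copy(),
            wall_stiffness=self.wall_stiffness.copy(),
            cell_walls=self.cell_walls.copy(),
            cell_edges=self.cell_edges.copy(),
            cell_row=self.cell_row.copy(),
            cell_col=self.cell_col.copy(),
            cell_tip=self.cell_tip.copy(),
            elongating=self.elongating.copy(),
            gravity_direction=np.array(self.gravity_direction, dtype=float),
        )

    # ---- serialization ------------------------------------------------------

    def to_json_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "units": "um",
            "n_cols": self.n_cols,
            "n_rows": self.n_rows,
            "cell_width": self.cell_width,
            "cell_height": self.cell_height,
            "gravity_direction": list(map(float, self.gravity_direction)),
            "sim_time": self.sim_time,
            "tip_zone_length": self.tip_zone_length,
            "vertices": {
                "positions": self.positions.tolist(),
                "velocities": self.velocities.tolist(),
                "fixed_x": self.fixed_x.astype(int).tolist(),
            },
            "walls": {
                "vertices": self.wall_vertices.tolist(),
                "resting_length": self.wall_rest.tolist(),
                "axial": self.wall_axial.astype(int).tolist(),
                "level": self.wall_level.tolist(),
                "stiffness": self.wall_stiffness.tolist(),
            },
            "cells": {
                "walls": self.cell_walls.tolist(),
                "edges": self.cell_edges.tolist(),
                "row": self.cell_row.tolist(),
                "col": self.cell_col.tolist(),
                "tip": self.cell_tip.astype(int).tolist(),
                "elongating": self.elongating.astype(int).tolist(),
            },
        }

    @classmethod
    def from_json_dict(cls, d: dict) -> "Tissue":
        if d.get("schema_version") != SCHEMA_VERSION:
            raise ValueError(f"unsupported tissue schema: {d.get('schema_version')!r}")
        v, w, c = d["vertices"], d["walls"], d["cells"]
        tissue = cls(
            positions=np.asarray(v["positions"], dtype=float),
            velocities=np.asarray(v["velocities"], dtype=float),
            forces=np.zeros((len(v["positions"]), 2)),
            fixed_x=np.asarray(v["fixed_x"], dtype=bool),
            wall_vertices=np.asarray(w["vertices"], dtype=np.int64),
            wall_rest=np.asarray(w["resting_length"], dtype=float),
            wall_axial=np.asarray(w["axial"], dtype=bool),
            wall_level=np.asarray(w["level"], dtype=np.int64),
            wall_stiffness=np.asarray(w["stiffness"], dtype=float),
            cell_walls=np.asarray(c["walls"], dtype=np.int64),
            cell_edges=np.asarray(c["edges"], dtype=np.int64),
            cell_row=np.asarray(c["row"], dtype=np.int64),
            cell_col=np.asarray(c["col"], dtype=np.int64),
            cell_tip=np.asarray(c["tip"], dtype=bool),
            elongating=np.asarray(c["elongating"], dtype=bool),
            n_cols=int(d["n_cols"]),
            n_rows=int(d["n_rows"]),
            cell_width=float(d["cell_width"]),
            cell_height=float(d["cell_height"]),
            gravity_direction=np.asarray(d["gravity_direction"], dtype=float),
            sim_time=float(d["sim_time"]),
            tip_zone_length=d.get("tip_zone_length"),
        )
        return tissue

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json_dict()))

    @classmethod
    def from_json(cls, path: str | Path) -> "Tissue":
        return cls.from_json_dict(json.loads(Path(path).read_text()))


def build_lr_grid(n_cols: int, n_rows: int, cell_width: float,
                  cell_height: float, *, stiffness: float = 0.9,
                  gravity_direction=(0.0, -1.0)) -> Tissue:
    """Build the lateral-root tissue as a rectangular grid of cells at rest.

    Parameters
    ----------
    n_cols, n_rows
        Cell columns along the organ axis (>= 2 each).
    cell_width, cell_height
        Initial cell dimensions in um; every wall's resting length equals
        its built length, so all springs start stress-free.
    stiffness
        Spring constant shared by all walls.

    The tip sits at minimum x, the base column of vertices (maximum x) is
    clamped in x to represent the attachment to the parent root. Velocities
    start at zero and ``sim_time`` at 0.
    """
    if n_cols < 2 or n_rows < 2:
        raise ValueError(f"grid must be at least 2x2, got {n_cols}x{n_rows}")
    if cell_width <= 0 or cell_height <= 0:
        raise ValueError("cell dimensions must be positive")

    nvc, nvr = n_cols + 1, n_rows + 1  # vertex columns / rows
    cols, rows = np.meshgrid(np.arange(nvc), np.arange(nvr), indexing="ij")
    positions = np.stack([cols.ravel() * float(cell_width),
                          rows.ravel() * float(cell_height)], axis=1)
    fixed_x = np.zeros(nvc * nvr, dtype=bool)
    fixed_x[n_cols * nvr:] = True  # right-most vertex column

    def vid(i, j):
        return i * nvr + j

    # axial walls: (i, j) -> (i + 1, j), i in 0..n_cols-1, level j in 0..n_rows
    aw_i, aw_j = np.meshgrid(np.arange(n_cols), np.arange(nvr), indexing="ij")
    aw_i, aw_j = aw_i.ravel(), aw_j.ravel()
    axial_pairs = np.stack([vid(aw_i, aw_j), vid(aw_i + 1, aw_j)], axis=1)
    # transverse walls: (i, j) -> (i, j + 1), i in 0..n_cols, j in 0..n_rows-1
    tw_i, tw_j = np.meshgrid(np.arange(nvc), np.arange(n_rows), indexing="ij")
    tw_i, tw_j = tw_i.ravel(), tw_j.ravel()
    trans_pairs = np.stack([vid(tw_i, tw_j), vid(tw_i, tw_j + 1)], axis=1)

    n_axial = axial_pairs.shape[0]
    wall_vertices = np.concatenate([axial_pairs, trans_pairs])
    wall_axial = np.zeros(wall_vertices.shape[0], dtype=bool)
    wall_axial[:n_axial] = True
    wall_level = np.full(wall_vertices.shape[0], -1, dtype=np.int64)
    wall_level[:n_axial] = aw_j
    wall_rest = np.where(wall_axial, float(cell_width), float(cell_height))
    wall_stiffness = np.full(wall_vertices.shape[0], float(stiffness))

    def aw(i, j):  # axial wall id
        return i * nvr + j

    def tw(i, j):  # transverse wall id
        return n_axial + i * n_rows + j

    c_i, c_j = np.meshgrid(np.arange(n_cols), np.arange(n_rows), indexing="ij")
    c_i, c_j = c_i.ravel(), c_j.ravel()
    # CCW wall cycle: bottom, right, top, left
    cell_walls = np.stack(
        [aw(c_i, c_j), tw(c_i + 1, c_j), aw(c_i, c_j + 1), tw(c_i, c_j)],
        axis=1)
    # directed CCW edges (outward normal of edge a->b is (dy, -dx))
    v00, v10 = vid(c_i, c_j), vid(c_i + 1, c_j)
    v11, v01 = vid(c_i + 1, c_j + 1), vid(c_i, c_j + 1)
    cell_edges = np.stack([
        np.stack([v00, v10], axis=1),
        np.stack([v10, v11], axis=1),
        np.stack([v11, v01], axis=1),
        np.stack([v01, v00], axis=1),
    ], axis=1)

    return Tissue(
        positions=positions,
        velocities=np.zeros_like(positions),
        forces=np.zeros_like(positions),
        fixed_x=fixed_x,
        wall_vertices=wall_vertices.astype(np.int64),
        wall_rest=wall_rest,
        wall_axial=wall_axial,
        wall_level=wall_level,
        wall_stiffness=wall_stiffness,
        cell_walls=cell_walls.astype(np.int64),
        cell_edges=cell_edges.astype(np.int64),
        cell_row=c_j.astype(np.int64),
        cell_col=c_i.astype(np.int64),
        cell_tip=np.zeros(c_i.shape[0], dtype=bool),
        elongating=np.ones(c_i.shape[0], dtype=bool),
        n_cols=int(n_cols),
        n_rows=int(n_rows),
        cell_width=float(cell_width),
        cell_height=float(cell_height),
        gravity_direction=np.asarray(gravity_direction, dtype=float),
    )


def assign_zones(tissue: Tissue, tip_zone_length: float) -> Tissue:
    """Split the organ into a non-growing tip zone and an elongation zone.

    A cell belongs to the tip zone when its built center lies closer than
    ``tip_zone_length`` to the tip (minimum-x) end; all remaining cells
    elongate. The split uses the material column index, so it is idempotent
    and unaffected by later deformation. Scenario modifiers may afterwards
    clear individual ``elongating`` flags.
    """
    organ_length = tissue.n_cols * tissue.cell_width
    if not 0 <= tip_zone_length < organ_length:
        raise ValueError(
            f"tip_zone_length must lie in [0, {organ_length}), got {tip_zone_length}")
    centers = (tissue.cell_col + 0.5) * tissue.cell_width
    tip = centers < tip_zone_length
    tissue.cell_tip = tip
    tissue.elongating = ~tip
    tissue.tip_zone_length = float(tip_zone_length)
    return tissue
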