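"""Anisotropic growth law and perturbation scenarios.

Growth extends the *resting length* of axial wall springs:

    dL/dt = L * gamma(d),      gamma(d) = r(d) / reference_length,

where ``r(d) = r_min + d * (r_max - r_min)`` linearly interpolates the
measured flank elongation rates (5 um/h on the lower flank, 15 um/h on the
upper flank) across the relative flank coordinate ``d`` in [0, 1], and
``reference_length`` converts the measured absolute rates (um/h) into
relative resting-length growth rates (1/h). ``d`` is a material
(Lagrangian) coordinate — the axial wall level divided by ``n_rows``,
assigned at build time — so bending does not feed back into the rate
field. Transverse walls never grow (anisotropic growth), and neither do
walls all of whose flanking cells are non-elongating (tip zone or cells
cleared by a scenario mask).

Scenarios reproduce the perturbation experiments: a 10% reduction of the
upper-flank elongation rate, removal of elongating cells from the upper
flank only, a cell-number gradient from the top row down (asymmetric
meristem input), and a symmetric control with no rate gradient.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import InvalidStateError
from .geometry import Tissue

SCENARIOS = ("wildtype", "reduced_upper_elongation", "fewer_upper_cells",
             "graded_cell_number", "symmetric")

RELATIVE = "relative"
ABSOLUTE = "absolute"


@dataclasses.dataclass(frozen=True)
class GrowthField:
    """Growth-rate field and its perturbation switches.

    r_min, r_max : flank elongation rates in um/h at d=0 (lower) and d=1
        (upper); defaults 5 and 15 (three-fold upper/lower asymmetry).
    dt_growth : growth time step in hours (default 0.003).
    reference_length : um; length scale converting r(d) into the relative
        growth rate gamma = r/reference_length (1/h). Calibrated once
        against the wild-type bending trajectory and frozen (see
        docs/methods.md); per-run logs record the value used.
    upper_flank_scale : multiplies the rate of the top flank wall level(s);
        0.9 reproduces the "10% reduced upper elongation" scenario.
    upper_flank_levels : how many of the top axial wall levels the scale
        applies to (default 1: only the uppermost wall, i.e. r_max).
    elongating_mask : optional per-cell boolean AND-mask over the tissue's
        own elongating flags (set by scenario builders).
    mode : "relative" (default, the growth law above) or "absolute"
        (dL/dt = r(d), sensitivity-analysis variant).
    """

    r_min: float = 5.0
    r_max: float = 15.0
    dt_growth: float = 0.003
    reference_length: float = 95.0
    upper_flank_scale: float = 1.0
    upper_flank_levels: int = 1
    elongating_mask: np.ndarray | None = None
    mode: str = RELATIVE

    def __post_init__(self):
        if not self.r_max >= self.r_min > 0:
            raise ValueError("need r_max >= r_min > 0")
        if self.dt_growth <= 0:
            raise ValueError("dt_growth must be > 0")
        if self.reference_length <= 0:
            raise ValueError("reference_length must be > 0")
        if not 0 < self.upper_flank_scale <= 1:
            raise ValueError("upper_flank_scale must lie in (0, 1]")
        if self.upper_flank_levels < 1:
            raise ValueError("upper_flank_levels must be >= 1")
        if self.mode not in (RELATIVE, ABSOLUTE):
            raise ValueError(f"unknown growth mode {self.mode!r}")


def elongation_rate(d: float, field: GrowthField, row_is_top: bool = False) -> float:
    """Interpolated elongation rate r(d) in um/h at flank coordinate d.

    ``row_is_top`` applies the upper-flank scale factor (perturbation
    scenarios); with defaults the scale is 1 and has no effect.
    """
    if not 0 <= d <= 1:
        raise ValueError(f"flank coordinate d must lie in [0, 1], got {d}")
    r = field.r_min + d * (field.r_max - field.r_min)
    if row_is_top:
        r *= field.upper_flank_scale
    return r


def effective_elongating(tissue: Tissue, field: GrowthField) -> np.ndarray:
    """Per-cell elongating flags after applying the scenario mask."""
    el = tissue.elongating.copy()
    if field.elongating_mask is not None:
        if field.elongating_mask.shape[0] != tissue.n_cells:
            raise ValueError("elongating_mask size does not match cell count")
        el &= field.elongating_mask
    return el


def growth_wall_arrays(tissue: Tissue, field: GrowthField) -> tuple[np.ndarray, np.ndarray]:
    """Per-wall (rate um/h, grows?) arrays; static over a run.

    An axial wall grows when at least one of its flanking cells elongates;
    its rate is r(level / n_rows), scaled on the top flank level(s).
    """
    n_rows = tissue.n_rows
    el = effective_elongating(tissue, field)
    # cell id = col * n_rows + row
    cell_of = np.full((tissue.n_cols, n_rows), -1, dtype=np.int64)
    cell_of[tissue.cell_col, tissue.cell_row] = np.arange(tissue.n_cells)

    rates = np.zeros(tissue.n_walls)
    grows = np.zeros(tissue.n_walls, dtype=bool)
    axial = np.nonzero(tissue.wall_axial)[0]
    levels = tissue.wall_level[axial]
    # axial wall id layout from build_lr_grid: w = col * (n_rows + 1) + level
    cols = axial // (n_rows + 1)
    below = levels > 0
    above = levels < n_rows
    g = np.zeros(axial.shape[0], dtype=bool)
    g[below] |= el[cell_of[cols[below], levels[below] - 1]]
    g[above] |= el[cell_of[cols[above], levels[above]]]
    d = levels / n_rows
    r = field.r_min + d * (field.r_max - field.r_min)
    top = levels > n_rows - field.upper_flank_levels
    r[top] *= field.upper_flank_scale
    rates[axial] = r
    grows[axial] = g
    return rates, grows


def apply_growth_step(tissue: Tissue, field: GrowthField,
                      rates: np.ndarray | None = None,
                      grows: np.ndarray | None = None,
                      require_relaxed: bool = True) -> Tissue:
    """Extend resting lengths of growing axial walls by one growth step.

    Relative mode: ``L <- L * (1 + gamma(d) * dt_growth)`` with
    ``gamma = r(d)/reference_length``; absolute mode:
    ``L <- L + r(d) * dt_growth``. Requires a relaxed tissue (growth
    alternates with mechanical equilibration); advances ``sim_time``.
    """
    if require_relaxed and not tissue.relaxed:
        raise InvalidStateError(
            "apply_growth_step requires a relaxed tissue; call "
            "relax_to_equilibrium first (or pass require_relaxed=False)")
    if rates is None or grows is None:
        rates, grows = growth_wall_arrays(tissue, field)
    if field.mode == RELATIVE:
        tissue.wall_rest[grows] *= 1.0 + rates[grows] / field.reference_length * field.dt_growth
    else:
        tissue.wall_rest[grows] += rates[grows] * field.dt_growth
    tissue.sim_time += field.dt_growth
    tissue.relaxed = False
    return tissue


def make_scenario_field(scenario: str, base: GrowthField, tissue: Tissue,
                        k: int = 1) -> GrowthField:
    """Derive the growth field for a named perturbation scenario.

    wildtype : base field unchanged.
    reduced_upper_elongation : upper-flank rate scaled by 0.9.
    fewer_upper_cells : the ``k`` tip-most elongation-zone cells of the top
        row stop elongating.
    graded_cell_number : cleared cell count decreases linearly from ``k``
        in the top row to 0 in the bottom row.
    symmetric : r_max = r_min (control; no rate gradient, no bending).
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if scenario == "wildtype":
        return base
    if scenario == "reduced_upper_elongation":
        return dataclasses.replace(base, upper_flank_scale=0.9)
    if scenario == "symmetric":
        return dataclasses.replace(base, r_max=base.r_min)

    if k < 0:
        raise ValueError("k must be >= 0")
    mask = np.ones(tissue.n_cells, dtype=bool) if base.elongating_mask is None \
        else base.elongating_mask.copy()
    n_rows = tissue.n_rows

    def clear_row(row: int, count: int) -> None:
        in_row = np.nonzero((tissue.cell_row == row) & tissue.elongating)[0]
        order = in_row[np.argsort(tissue.cell_col[in_row])]  # tip-most first
        mask[order[:count]] = False

    if scenario == "fewer_upper_cells":
        clear_row(n_rows - 1, k)
    else:  # graded_cell_number
        for row in range(n_rows):
            count = int(round(k * row / (n_rows - 1)))
            clear_row(row, count)
    return dataclasses.replace(base, elongating_mask=mask)
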