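"""Mechanics of the wall-spring / turgor-pressure tissue.

Forces on a vertex u are the sum of

* linear spring forces ``k * (L - |p_u - p_v|) * (p_u - p_v)/|p_u - p_v|``
  from every incident wall (positive magnitude under compression), and
* turgor pressure ``p_const * n_hat * |p_u - p_v|`` per cell wall, directed
  along the wall's outward normal with respect to that cell and lumped
  half-and-half onto the wall's endpoints. Pressure on interior walls
  cancels between the two flanking cells; the net load acts on the tissue
  boundary and keeps cells inflated.

Positions evolve by damped Newtonian dynamics,

    dVel/dt = F/m - beta * Vel,      dp/dt = Vel,

integrated with a (semi-implicit by default) forward Euler scheme. Between
growth increments the mesh is relaxed until force and velocity residuals
drop below tolerance ("transient equilibrium"). The fixed-x boundary is
enforced by zeroing the x-components of force and velocity of clamped
vertices, which injects no energy.

A numba-compiled kernel (:mod:`lrbend._kernels`) runs the relaxation loop;
the numpy implementations here are the reference the kernel is tested
against.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .errors import (DegenerateGeometryError, NonConvergenceError,
                     NumericalBlowupError)
from .geometry import Tissue

SEMI_IMPLICIT = "semi_implicit"
FORWARD = "forward"


@dataclasses.dataclass(frozen=True)
class MechanicsParams:
    """Mechanical constants of the model.

    k_x : spring stiffness shared by all walls (model force / um).
    p_const : turgor pressure per unit wall length.
    beta : velocity damping constant (1 / model-hour).
    mass : vertex point mass.
    dt_mech : mechanics time step in model-hours. Must satisfy the
        conservative stability bound ``dt < 2 * min(beta / k_x, 1 / beta)``.
    equilibrium_tol : residual (max |F|/m and max |Vel|) below which the
        mesh counts as relaxed.
    max_relax_iters : iteration cap per relaxation.
    euler_order : ``"semi_implicit"`` updates velocity before position
        (default, better stability); ``"forward"`` is the pure explicit
        variant.
    """

    k_x: float = 0.9
    p_const: float = 0.05
    beta: float = 0.2
    mass: float = 1.0
    dt_mech: float = 0.4
    equilibrium_tol: float = 1e-5
    max_relax_iters: int = 100_000
    euler_order: str = SEMI_IMPLICIT

    def __post_init__(self):
        for name in ("k_x", "p_const", "beta", "mass", "dt_mech"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.equilibrium_tol < 0:
            raise ValueError("equilibrium_tol must be >= 0")
        if self.max_relax_iters < 1:
            raise ValueError("max_relax_iters must be >= 1")
        if self.euler_order not in (SEMI_IMPLICIT, FORWARD):
            raise ValueError(f"unknown euler_order {self.euler_order!r}")
        bound = 2.0 * min(self.beta / self.k_x, 1.0 / self.beta)
        if self.dt_mech >= bound:
            raise ValueError(
                f"dt_mech={self.dt_mech} violates the stability bound {bound:.4g}")


def spring_force(p_u, p_v, resting_length: float, stiffness: float) -> np.ndarray:
    """Force exerted on vertex u by the spring (u, v).

    Magnitude ``stiffness * (resting_length - |p_u - p_v|)`` along
    ``(p_u - p_v)/|p_u - p_v|``: positive (pushing u away from v) under
    compression, pulling u toward v under extension. The equal and opposite
    force applies to v.
    """
    p_u = np.asarray(p_u, dtype=float)
    p_v = np.asarray(p_v, dtype=float)
    d = p_u - p_v
    dist = float(np.hypot(d[0], d[1]))
    if dist < 1e-12:
        raise DegenerateGeometryError("spring endpoints coincide")
    return stiffness * (resting_length - dist) / dist * d


def cell_pressure_forces(tissue: Tissue, cell: int, p_const: float) -> dict[int, np.ndarray]:
    """Per-vertex turgor-pressure contributions of one cell.

    Each wall contributes a force of magnitude ``p_const * wall_length``
    along the wall's outward normal (outward w.r.t. this cell), split
    equally between its two endpoint vertices. The vector sum over a closed
    cell is exactly zero.
    """
    edges = tissue.cell_edges[cell]
    a = tissue.positions[edges[:, 0]]
    b = tissue.positions[edges[:, 1]]
    area = 0.5 * float(np.sum(a[:, 0] * b[:, 1] - b[:, 0] * a[:, 1]))
    if area <= 0:
        raise DegenerateGeometryError(
            f"cell {cell} has non-positive area {area:.3g}")
    d = b - a
    # for a CCW polygon, (dy, -dx) is the outward normal scaled by |wall|
    f = p_const * np.stack([d[:, 1], -d[:, 0]], axis=1)
    out: dict[int, np.ndarray] = {}
    for (u, v), fw in zip(edges, f):
        out[int(u)] = out.get(int(u), np.zeros(2)) + 0.5 * fw
        out[int(v)] = out.get(int(v), np.zeros(2)) + 0.5 * fw
    return out


def total_forces(tissue: Tissue, params: MechanicsParams) -> np.ndarray:
    """Fill ``tissue.forces`` with spring + pressure forces on every vertex.

    The x-component of clamped (fixed_x) vertices is zeroed. Raises
    :class:`DegenerateGeometryError` on coincident wall endpoints or
    non-positive cell areas.
    """
    pos = tissue.positions
    uv = tissue.wall_vertices
    d = pos[uv[:, 0]] - pos[uv[:, 1]]
    dist = np.hypot(d[:, 0], d[:, 1])
    if np.any(dist < 1e-12):
        raise DegenerateGeometryError("coincident wall endpoints")
    fvec = (tissue.wall_stiffness * (tissue.wall_rest - dist) / dist)[:, None] * d
    F = np.zeros_like(pos)
    np.add.at(F, uv[:, 0], fvec)
    np.add.at(F, uv[:, 1], -fvec)

    areas = tissue.cell_areas()
    if np.any(areas <= 0):
        bad = int(np.argmin(areas))
        raise DegenerateGeometryError(
            f"cell {bad} has non-positive area {areas[bad]:.3g}")
    ea = tissue.cell_edges[:, :, 0].ravel()
    eb = tissue.cell_edges[:, :, 1].ravel()
    ed = pos[eb] - pos[ea]
    pf = 0.5 * params.p_const * np.stack([ed[:, 1], -ed[:, 0]], axis=1)
    np.add.at(F, ea, pf)
    np.add.at(F, eb, pf)

    F[tissue.fixed_x, 0] = 0.0
    tissue.forces = F
    return F


def integrate_step(tissue: Tissue, params: MechanicsParams,
                   step_index: int | None = None) -> Tissue:
    """One damped-Newton Euler step using the current force accumulators.

    Semi-implicit order (default): velocity is updated first, the position
    then advances with the new velocity. Clamped vertices keep their
    x-coordinate and have x-velocity zeroed.
    """
    dt, beta, m = params.dt_mech, params.beta, params.mass
    v, F = tissue.velocities, tissue.forces
    if params.euler_order == SEMI_IMPLICIT:
        v += dt * (F / m - beta * v)
        v[tissue.fixed_x, 0] = 0.0
        tissue.positions += dt * v
    else:
        v_new = v + dt * (F / m - beta * v)
        v_new[tissue.fixed_x, 0] = 0.0
        tissue.positions += dt * v
        tissue.velocities = v_new
    if not np.all(np.isfinite(tissue.positions)):
        raise NumericalBlowupError(
            f"non-finite positions after integration step {step_index}",
            step=step_index)
    tissue.relaxed = False
    return tissue


def residuals(tissue: Tissue, params: MechanicsParams) -> tuple[float, float]:
    """(max |F|/m, max |Vel|) for the current accumulators."""
    fres = float(np.max(np.hypot(tissue.forces[:, 0], tissue.forces[:, 1]))) / params.mass
    vres = float(np.max(np.hypot(tissue.velocities[:, 0], tissue.velocities[:, 1])))
    return fres, vres


def relax_to_equilibrium(tissue: Tissue, params: MechanicsParams,
                         use_kernel: bool = True) -> tuple[Tissue, int]:
    """Iterate force evaluation + Euler steps until transient equilibrium.

    Stops when ``max |F|/m < equilibrium_tol`` and
    ``max |Vel| < equilibrium_tol``; raises :class:`NonConvergenceError`
    with the residual if ``max_relax_iters`` steps do not suffice. Returns
    the relaxed tissue and the number of integration steps taken.

    ``use_kernel`` routes the loop through the numba-compiled kernel
    (identical update rule, much faster); the numpy path below is the
    reference implementation.
    """
    if use_kernel:
        from ._kernels import relax_kernel
        iters, fres, vres, status = relax_kernel(
            tissue.positions, tissue.velocities,
            tissue.wall_vertices[:, 0], tissue.wall_vertices[:, 1],
            tissue.wall_rest, tissue.wall_stiffness, tissue.fixed_x,
            tissue.cell_edges[:, :, 0].ravel().copy(),
            tissue.cell_edges[:, :, 1].ravel().copy(),
            params.p_const, params.beta, params.mass, params.dt_mech,
            params.equilibrium_tol, params.max_relax_iters,
            params.euler_order == SEMI_IMPLICIT)
        if status == 2:
            raise NumericalBlowupError(
                f"non-finite state after {iters} relaxation steps", step=iters)
        if status == 3:
            raise DegenerateGeometryError("coincident wall endpoints during relaxation")
        if status == 1:
            raise NonConvergenceError(
                f"no equilibrium after {iters} steps "
                f"(|F|/m={fres:.3g}, |Vel|={vres:.3g}, tol={params.equilibrium_tol})",
                residual=max(fres, vres), iterations=iters)
        tissue.relaxed = True
        return tissue, int(iters)

    tol = params.equilibrium_tol
    for it in range(params.max_relax_iters + 1):
        total_forces(tissue, params)
        fres, vres = residuals(tissue, params)
        if fres < tol and vres < tol:
            tissue.relaxed = True
            return tissue, it
        if it == params.max_relax_iters:
            break
        integrate_step(tissue, params, step_index=it)
    raise NonConvergenceError(
        f"no equilibrium after {params.max_relax_iters} steps "
        f"(|F|/m={fres:.3g}, |Vel|={vres:.3g}, tol={tol})",
        residual=max(fres, vres), iterations=params.max_relax_iters)


def mechanical_energy(tissue: Tissue, params: MechanicsParams) -> float:
    """Spring elastic energy + kinetic energy - pressure work (p * area).

    Diagnostic only; along an undriven relaxation this decreases (up to
    first-order Euler error).
    """
    stretch = tissue.wall_lengths() - tissue.wall_rest
    elastic = 0.5 * float(np.sum(tissue.wall_stiffness * stretch ** 2))
    kinetic = 0.5 * params.mass * float(np.sum(tissue.velocities ** 2))
    pressure_work = params.p_const * float(np.sum(tissue.cell_areas()))
    return elastic + kinetic - pressure_work
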