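"""Numba-compiled relaxation loop.

Implements exactly the update of :func:`lrbend.mechanics.total_forces` +
:func:`lrbend.mechanics.integrate_step`; the test suite asserts step-level
agreement with the numpy reference. Residual maxima are tracked as squared
norms to avoid per-vertex square roots. Status codes: 0 converged,
1 iteration cap reached, 2 non-finite state, 3 degenerate wall.
"""

import numba
import numpy as np


@numba.njit(cache=True, fastmath=True)
def relax_kernel(pos, vel, wall_u, wall_v, rest, stiff, fixed,
                 edge_a, edge_b, p_const, beta, mass, dt, tol, max_iters,
                 semi_implicit):  # pragma: no cover - exercised via mechanics
    n = pos.shape[0]
    n_walls = wall_u.shape[0]
    n_edges = edge_a.shape[0]
    F = np.zeros((n, 2))
    ftol2 = (tol * mass) ** 2
    vtol2 = tol * tol
    fres2 = 0.0
    vres2 = 0.0
    for it in range(max_iters + 1):
        # ---- forces ----
        for i in range(n):
            F[i, 0] = 0.0
            F[i, 1] = 0.0
        for w in range(n_walls):
            u = wall_u[w]
            v = wall_v[w]
            dx = pos[u, 0] - pos[v, 0]
            dy = pos[u, 1] - pos[v, 1]
            dist = np.sqrt(dx * dx + dy * dy)
            if dist < 1e-12:
                return it, np.sqrt(fres2) / mass, np.sqrt(vres2), 3
            s = stiff[w] * (rest[w] - dist) / dist
            F[u, 0] += s * dx
            F[u, 1] += s * dy
            F[v, 0] -= s * dx
            F[v, 1] -= s * dy
        for e in range(n_edges):
            a = edge_a[e]
            b = edge_b[e]
            dx = pos[b, 0] - pos[a, 0]
            dy = pos[b, 1] - pos[a, 1]
            F[a, 0] += 0.5 * p_const * dy
            F[a, 1] -= 0.5 * p_const * dx
            F[b, 0] += 0.5 * p_const * dy
            F[b, 1] -= 0.5 * p_const * dx
        fres2 = 0.0
        vres2 = 0.0
        for i in range(n):
            if fixed[i]:
                F[i, 0] = 0.0
            f2 = F[i, 0] * F[i, 0] + F[i, 1] * F[i, 1]
            if f2 > fres2:
                fres2 = f2
            v2 = vel[i, 0] * vel[i, 0] + vel[i, 1] * vel[i, 1]
            if v2 > vres2:
                vres2 = v2
        if not (np.isfinite(fres2) and np.isfinite(vres2)):
            return it, np.sqrt(fres2) / mass, np.sqrt(vres2), 2
        if fres2 < ftol2 and vres2 < vtol2:
            return it, np.sqrt(fres2) / mass, np.sqrt(vres2), 0
        if it == max_iters:
            return it, np.sqrt(fres2) / mass, np.sqrt(vres2), 1
        # ---- Euler step ----
        if semi_implicit:
            for i in range(n):
                vel[i, 0] += dt * (F[i, 0] / mass - beta * vel[i, 0])
                vel[i, 1] += dt * (F[i, 1] / mass - beta * vel[i, 1])
                if fixed[i]:
                    vel[i, 0] = 0.0
                pos[i, 0] += dt * vel[i, 0]
                pos[i, 1] += dt * vel[i, 1]
        else:
            for i in range(n):
                vx = vel[i, 0] + dt * (F[i, 0] / mass - beta * vel[i, 0])
                vy = vel[i, 1] + dt * (F[i, 1] / mass - beta * vel[i, 1])
                if fixed[i]:
                    vx = 0.0
                pos[i, 0] += dt * vel[i, 0]
                pos[i, 1] += dt * vel[i, 1]
                vel[i, 0] = vx
                vel[i, 1] = vy
    return max_iters, np.sqrt(fres2) / mass, np.sqrt(vres2), 1
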