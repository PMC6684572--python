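"""Independent oracles and fixtures shared by the unit and acceptance suites.

Everything here recomputes a quantity by the most transparent route
available (per-element loops, exhaustive maxima, closed forms) and stays
free of the vectorized / compiled code paths it checks.
"""

import numpy as np

import lrbend as lb


def pair_tissue(stretch: float = 2.0) -> lb.Tissue:
    """Two free vertices joined by one spring of rest length 1 (no cells)."""
    return lb.Tissue(
        positions=np.array([[0.0, 0.0], [stretch, 0.0]]),
        velocities=np.zeros((2, 2)),
        forces=np.zeros((2, 2)),
        fixed_x=np.zeros(2, dtype=bool),
        wall_vertices=np.array([[0, 1]], dtype=np.int64),
        wall_rest=np.array([1.0]),
        wall_axial=np.array([True]),
        wall_level=np.array([0], dtype=np.int64),
        wall_stiffness=np.array([0.9]),
        cell_walls=np.zeros((0, 4), dtype=np.int64),
        cell_edges=np.zeros((0, 4, 2), dtype=np.int64),
        cell_row=np.zeros(0, dtype=np.int64),
        cell_col=np.zeros(0, dtype=np.int64),
        cell_tip=np.zeros(0, dtype=bool),
        elongating=np.zeros(0, dtype=bool),
        n_cols=1, n_rows=1, cell_width=1.0, cell_height=1.0,
        gravity_direction=np.array([0.0, -1.0]),
    )


def brute_force_total_forces(tissue, params):
    """Per-vertex force by explicit summation over walls and cells."""
    F = np.zeros_like(tissue.positions)
    for w in range(tissue.n_walls):
        u, v = tissue.wall_vertices[w]
        f = lb.spring_force(tissue.positions[u], tissue.positions[v],
                            tissue.wall_rest[w], tissue.wall_stiffness[w])
        F[u] += f
        F[v] -= f
    for c in range(tissue.n_cells):
        for vid, f in lb.cell_pressure_forces(tissue, c, params.p_const).items():
            F[vid] += f
    F[tissue.fixed_x, 0] = 0.0
    return F


def ks_statistic_bruteforce(a, b):
    """sup |ECDF_a - ECDF_b| over the pooled support, O(n^2)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return max(abs(np.mean(a <= x) - np.mean(b <= x))
               for x in np.concatenate([a, b]))


def ks_type_i_error_rate(n_reps=2000, n=50, alpha=0.05, seed=20240915):
    """Null rejection rate of the KS test: both samples from one truncated
    normal on [0, 180] (mean 62, sd 12), n per group."""
    from scipy import stats as sps

    rng = np.random.default_rng(seed)
    dist = sps.truncnorm((0 - 62) / 12, (180 - 62) / 12, loc=62, scale=12)
    draws = dist.rvs((n_reps, 2 * n), random_state=rng)
    hits = sum(
        lb.ks_two_sample(row[:n], row[n:]).p_value < alpha for row in draws)
    return hits / n_reps


def relax_pair_positions(beta, tol=1e-8, dt=0.02, stretch=2.0):
    """Relax a free stretched spring pair; return final positions."""
    t = pair_tissue(stretch)
    params = lb.MechanicsParams(beta=beta, dt_mech=dt, equilibrium_tol=tol)
    lb.relax_to_equilibrium(t, params, use_kernel=False)
    return t.positions.copy()
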