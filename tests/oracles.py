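"""Independent reference computations used to validate the simulators.

Each oracle solves the same physical question as the implementation by a
different route: damped fixed-point iteration for the competing-ligand
equilibrium, an explicit Brownian random walk among absorbing spheres for
the encounter probability, and an exact stochastic (Gillespie) simulation
of the surface reaction scheme for the bond ODE.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree


def fixed_point_equilibrium(kd_a, kd_b, a_tot, b_tot, y_tot,
                            tol=1e-14, max_iter=200_000):
    """Damped fixed-point iteration for the free-ligand concentration.

    Iterates Y <- Y_tot / (1 + A_free/KD_A + B_free/KD_B) with the free
    antigens recomputed from conservation at the current Y.  All arguments
    may be arrays.
    """
    kd_a, kd_b, a_tot, b_tot, y_tot = np.broadcast_arrays(
        *[np.asarray(x, dtype=float) for x in (kd_a, kd_b, a_tot, b_tot, y_tot)])
    y = np.array(y_tot, dtype=float)
    for _ in range(max_iter):
        a_free = a_tot * kd_a / (kd_a + y)
        b_free = b_tot * kd_b / (kd_b + y)
        y_new = y_tot / (1.0 + a_free / kd_a + b_free / kd_b)
        y_next = 0.5 * (y + y_new)  # damping for heavy-depletion regimes
        if np.all(np.abs(y_next - y) <= tol * np.maximum(y_tot, 1e-300)):
            y = y_next
            break
        y = y_next
    a_free = a_tot * kd_a / (kd_a + y)
    b_free = b_tot * kd_b / (kd_b + y)
    return {"Y_free": y, "A_free": a_free, "B_free": b_free,
            "AY": a_tot * y / (kd_a + y), "YB": b_tot * y / (kd_b + y)}


def single_ligand_quadratic(kd, b_tot, y_tot):
    """Closed-form bound complex for one ligand + one receptor."""
    s = b_tot + y_tot + kd
    return 0.5 * (s - np.sqrt(s * s - 4.0 * b_tot * y_tot))


def brownian_hit_fraction(density_per_ml, params, dt_total, n_walkers, seed,
                          n_steps=120, box_um=300.0):
    """Fraction of Brownian walkers absorbed by immotile spheres in dt.

    Spheres of radius r_E + r_T are placed uniformly at the matched number
    density in a periodic box; walkers start uniformly outside the spheres
    and are absorbed on first entry.
    """
    rng = np.random.default_rng(seed)
    radius = params.cell_radius_E + params.cell_radius_T
    n_spheres = int(round(density_per_ml * 1e-12 * box_um ** 3))
    centers = rng.uniform(0, box_um, size=(n_spheres, 3))
    tree = cKDTree(centers, boxsize=box_um)
    pos = rng.uniform(0, box_um, size=(n_walkers, 3))
    d, _ = tree.query(pos)
    inside = d < radius
    while inside.any():
        pos[inside] = rng.uniform(0, box_um, size=(int(inside.sum()), 3))
        d, _ = tree.query(pos)
        inside = d < radius
    alive = np.ones(n_walkers, bool)
    step_sd = np.sqrt(2 * params.diffusion_coefficient * dt_total / n_steps)
    for _ in range(n_steps):
        idx = np.flatnonzero(alive)
        pos[idx] = (pos[idx] + rng.normal(0, step_sd, size=(len(idx), 3))) % box_um
        d, _ = tree.query(pos[idx])
        alive[idx] = d >= radius
    return 1.0 - alive.mean()


def gillespie_bond_mean(rho, area, duration, k2d, n_runs, seed):
    """Mean final AYB bond count from exact stochastic simulation.

    rho = (rho_A, rho_AY, rho_B, rho_YB) in molecules/um^2; returns
    (mean, standard error) over n_runs trajectories.
    """
    rng = np.random.default_rng(seed)
    n_a0, n_ay0, n_b0, n_yb0 = [int(round(r * area)) for r in rho]
    kon_a, kon_b = k2d.kon2D_A / area, k2d.kon2D_B / area
    koff_a, koff_b = k2d.koff2D_A, k2d.koff2D_B
    finals = np.empty(n_runs)
    for i in range(n_runs):
        n_a, n_ay, n_b, n_yb, n = n_a0, n_ay0, n_b0, n_yb0, 0
        t = 0.0
        while True:
            a1 = kon_a * n_a * n_yb
            a2 = kon_b * n_ay * n_b
            a3 = koff_a * n
            a4 = koff_b * n
            total = a1 + a2 + a3 + a4
            if total == 0.0:
                break
            t += rng.exponential(1.0 / total)
            if t > duration:
                break
            u = rng.random() * total
            if u < a1:
                n_a -= 1; n_yb -= 1; n += 1
            elif u < a1 + a2:
                n_ay -= 1; n_b -= 1; n += 1
            elif u < a1 + a2 + a3:
                n_a += 1; n_yb += 1; n -= 1
            else:
                n_ay += 1; n_b += 1; n -= 1
        finals[i] = n
    return float(finals.mean()), float(finals.std(ddof=1) / np.sqrt(n_runs))
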