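"""Soluble-phase ("3D") binding equilibrium of a bispecific ligand.

A bispecific T-cell engager (BiTE) Y carries one anti-CD3 arm and one
anti-CD19 arm.  Before any cell-scale event, the drug equilibrates in the
co-incubation medium against the two competing antigen pools — CD3 (A) on
effector cells and CD19 (B) on target cells — forming the binary complexes
AY and YB.  Membrane antigens are treated as well-mixed solutes for this
step; the ternary membrane bond AYB forms only later, at a cell–cell
contact, and is handled by :mod:`synapse_sim.contact`.

The equilibrium is fixed by two mass-action laws and three conservation
laws::

    AY = [A][Y] / KD_A          YB = [B][Y] / KD_B
    A_tot = [A] + AY            B_tot = [B] + YB
    Y_tot = [Y] + AY + YB

Eliminating [A] and [B] leaves a cubic in the free ligand [Y]; we solve it
as a bracketed monotone scalar root on [0, Y_tot], polished by Newton
iterations, which is unconditionally stable for extreme KD ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

AVOGADRO = 6.02214076e23

#: Molar mass of blinatumomab (kDa); used only for ng/mL <-> M conversion.
DEFAULT_BITE_MW_KDA = 54.0


class EquilibriumError(RuntimeError):
    """Raised when the equilibrium solver cannot produce a physical root."""


@dataclass(frozen=True)
class BindingConstants:
    """3D kinetic rate constants for the two BiTE arms.

    Parameters
    ----------
    kon_A, koff_A
        Association (M^-1 s^-1) and dissociation (s^-1) rates of the
        BiTE–CD3 arm.
    kon_B, koff_B
        Same for the BiTE–CD19 arm.

    Equilibrium constants are always derived from the rates
    (``KD = koff / kon``), never stored independently.
    """

    kon_A: float
    koff_A: float
    kon_B: float
    koff_B: float

    def __post_init__(self) -> None:
        for name in ("kon_A", "koff_A", "kon_B", "koff_B"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)}")

    @property
    def KD_A(self) -> float:
        return self.koff_A / self.kon_A

    @property
    def KD_B(self) -> float:
        return self.koff_B / self.kon_B


@dataclass(frozen=True)
class EquilibriumState:
    """Molar concentrations at binding equilibrium."""

    A_tot: float
    B_tot: float
    Y_tot: float
    A_free: float
    B_free: float
    Y_free: float
    AY: float
    YB: float

    @property
    def cd3_occupancy(self) -> float:
        """Fraction of total CD3 bound in binary complex."""
        return self.AY / self.A_tot if self.A_tot > 0 else 0.0

    @property
    def cd19_occupancy(self) -> float:
        """Fraction of total CD19 bound in binary complex."""
        return self.YB / self.B_tot if self.B_tot > 0 else 0.0


def counts_to_molar(receptors_per_cell: float, cell_density_per_ml: float) -> float:
    """Convert a per-cell surface count at a cell density to mol/L.

    The co-incubation volume is the reference volume: ``receptors/cell ×
    cells/mL`` gives receptors per mL, ×1000 per litre, /N_A for moles.
    """
    if receptors_per_cell < 0 or cell_density_per_ml < 0:
        raise ValueError("receptor count and cell density must be non-negative")
    return receptors_per_cell * cell_density_per_ml * 1e3 / AVOGADRO


def ng_per_ml_to_molar(conc_ng_per_ml: float, mw_kda: float = DEFAULT_BITE_MW_KDA) -> float:
    """Convert a drug concentration in ng/mL to mol/L."""
    if conc_ng_per_ml < 0:
        raise ValueError("concentration must be non-negative")
    return conc_ng_per_ml * 1e-6 / (mw_kda * 1e3)  # ng/mL -> g/L -> mol/L


def molar_to_ng_per_ml(conc_molar: float, mw_kda: float = DEFAULT_BITE_MW_KDA) -> float:
    return conc_molar * mw_kda * 1e3 * 1e6


def _residual(y_free: float, constants: BindingConstants, a_tot: float,
              b_tot: float, y_tot: float) -> float:
    # Monotone increasing in y_free on [0, inf): total ligand implied by a
    # trial free-ligand value minus the true total.
    ka, kb = constants.KD_A, constants.KD_B
    return y_free * (1.0 + a_tot / (ka + y_free) + b_tot / (kb + y_free)) - y_tot


def solve_equilibrium(constants: BindingConstants, A_tot: float, B_tot: float,
                      Y_tot: float, rel_tol: float = 1e-12) -> EquilibriumState:
    """Solve the two-competing-ligand equilibrium.

    Returns the unique physical root of the cubic in the free ligand
    concentration.  Conservation holds to better than 1e-9 relative; a
    failure to bracket or converge raises :class:`EquilibriumError` rather
    than clamping.
    """
    if min(A_tot, B_tot, Y_tot) < 0:
        raise ValueError("total concentrations must be non-negative")

    if Y_tot == 0.0:
        return EquilibriumState(A_tot, B_tot, 0.0, A_tot, B_tot, 0.0, 0.0, 0.0)
    if A_tot == 0.0 and B_tot == 0.0:
        return EquilibriumState(0.0, 0.0, Y_tot, 0.0, 0.0, Y_tot, 0.0, 0.0)

    ka, kb = constants.KD_A, constants.KD_B
    f = lambda y: _residual(y, constants, A_tot, B_tot, Y_tot)
    lo, hi = 0.0, Y_tot
    if f(hi) < 0:  # cannot happen analytically; guard against rounding
        raise EquilibriumError("no root bracketed in [0, Y_tot]")
    y = brentq(f, lo, hi, xtol=1e-30, rtol=8.9e-16, maxiter=200)

    # Newton polish: f'(y) = 1 + A_tot*ka/(ka+y)^2 + B_tot*kb/(kb+y)^2
    for _ in range(3):
        fy = f(y)
        dfy = 1.0 + A_tot * ka / (ka + y) ** 2 + B_tot * kb / (kb + y) ** 2
        step = fy / dfy
        y_new = y - step
        if 0.0 <= y_new <= Y_tot:
            y = y_new

    a_free = A_tot * ka / (ka + y)
    b_free = B_tot * kb / (kb + y)
    ay = A_tot * y / (ka + y)
    yb = B_tot * y / (kb + y)
    state = EquilibriumState(A_tot, B_tot, Y_tot, a_free, b_free, y, ay, yb)

    scale = max(Y_tot, A_tot, B_tot)
    if abs(y + ay + yb - Y_tot) > 1e-9 * scale:
        raise EquilibriumError("ligand conservation violated beyond tolerance")
    if not (0.0 <= y <= Y_tot):
        raise EquilibriumError(f"free ligand {y} outside [0, Y_tot]")
    return state


def crosslink_potential(state: EquilibriumState) -> float:
    """Proxy for ternary-complex (AYB) formation potential.

    A membrane bond needs a binary complex on one cell and a free antigen on
    the opposing cell, so the proxy weighs each binary-complex pool by the
    free fraction of its co-partner.  Over a wide ligand grid this rises and
    then falls: at high BiTE both antigens are singly occupied and
    crosslinking collapses.
    """
    b_avail = state.B_free / state.B_tot if state.B_tot > 0 else 0.0
    a_avail = state.A_free / state.A_tot if state.A_tot > 0 else 0.0
    return state.AY * b_avail + state.YB * a_avail


def occupancy_curve(constants: BindingConstants, A_tot: float, B_tot: float,
                    Y_grid) -> pd.DataFrame:
    """Tabulate equilibrium composition across an ascending ligand grid."""
    y_grid = np.asarray(Y_grid, dtype=float)
    if y_grid.size == 0:
        raise ValueError("Y_grid must be non-empty")
    if np.any(np.diff(y_grid) < 0):
        raise ValueError("Y_grid must be ascending")
    rows = []
    for y_tot in y_grid:
        st = solve_equilibrium(constants, A_tot, B_tot, float(y_tot))
        rows.append({
            "Y_tot": st.Y_tot, "A_free": st.A_free, "B_free": st.B_free,
            "Y_free": st.Y_free, "AY": st.AY, "YB": st.YB,
            "crosslink_potential": crosslink_potential(st),
        })
    return pd.DataFrame(rows)
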