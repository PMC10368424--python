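"""Heterogeneous effector/target cell populations and receptor dynamics.

Effector (CD3+ Jurkat-like) and target (CD19+ Raji-like) populations are
generated with log-normal per-cell surface receptor counts, the
flow-cytometry convention for antigen-expression histograms.  The bulk
binding equilibrium is then distributed to cells: effector cells carry the
free CD3 and CD3–BiTE pools ([A]' and [AY]'), target cells the CD19 pools
([B]' and [YB]'), each in proportion to the cell's own total expression.

Two receptor processes run during an incubation:

* **CD3 downregulation** — engagement of CD3 by the drug removes surface
  CD3.  The removal is modelled as a first-order approach to a saturable
  plateau set by the surface binary-complex abundance [AY]',
  ``D_max = f_max · A_tot' · [AY]'/(K_half + [AY]')``, with approach rate
  chosen so the trajectory is essentially flat after ~60 min of constant
  engagement.
* **CD19 internalization** — the bound CD19–BiTE pool decays exponentially
  at 0.002 /min (short-incubation context only).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .equilibrium import EquilibriumState

ROLE_EFFECTOR = "effector"
ROLE_TARGET = "target"

STATE_FREE = "free"
STATE_ENGAGED = "engaged"
STATE_LYSED = "lysed"

#: Default CD19 internalization rate constant (per minute).
CD19_INTERNALIZATION_PER_MIN = 0.002


@dataclass(frozen=True)
class ExpressionSpec:
    """Log-normal antigen expression: arithmetic mean and log-space SD."""

    mean: float
    dispersion: float = 0.4
    label: str = "M"

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError(f"expression mean must be > 0, got {self.mean}")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


@dataclass
class CellAgent:
    id: int
    role: str
    antigen_total: float          # current receptors/cell (CD3 or CD19)
    free_antigen: float = 0.0     # [A]' or [B]'
    binary_complex: float = 0.0   # [AY]' or [YB]'
    state: str = STATE_FREE
    entity_id: int | None = None
    organ: str | None = None
    antigen_initial: float = 0.0  # expression before downregulation
    downregulated: float = 0.0    # cumulative CD3 removed (effectors)

    def __post_init__(self) -> None:
        if self.antigen_initial == 0.0:
            self.antigen_initial = self.antigen_total


@dataclass(frozen=True)
class CD3DownregParams:
    """Constants of the CD3 downregulation law (exposed via config).

    f_max : maximal fraction of surface CD3 removable.
    k_approach : first-order rate (s^-1) of approach to the plateau; the
        default leaves <5% of the total change to occur after 60 min.
    K_half : [AY]' (complexes/cell) at half-maximal plateau depth.
    """

    f_max: float = 0.8
    k_approach: float = 1.2e-3
    K_half: float = 200.0


def generate_population(n: int, role: str, spec: ExpressionSpec,
                        rng: np.random.Generator | int) -> list[CellAgent]:
    """Draw ``n`` cells with log-normal antigen totals around ``spec.mean``.

    The log-normal is parameterised so its *arithmetic* mean equals
    ``spec.mean`` (mu = ln mean - sigma^2/2).  Reproducible for a given
    generator state or integer seed.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if role not in (ROLE_EFFECTOR, ROLE_TARGET):
        raise ValueError(f"unknown role {role!r}")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    sigma = spec.dispersion
    if sigma == 0.0:
        totals = np.full(n, spec.mean)
    else:
        mu = math.log(spec.mean) - 0.5 * sigma * sigma
        totals = rng.lognormal(mean=mu, sigma=sigma, size=n)
    return [CellAgent(id=i, role=role, antigen_total=float(t)) for i, t in enumerate(totals)]


def allocate_binary_complexes(cells: list[CellAgent], eq: EquilibriumState,
                              rng: np.random.Generator | None = None,
                              binomial: bool = False) -> list[CellAgent]:
    """Distribute the bulk binary-complex pools onto individual cells.

    Each cell receives the bulk occupancy fraction of its own total
    (deterministic proportional allocation); with ``binomial=True`` the
    per-cell complex count is instead drawn binomially at that fraction.
    Summed per-cell complexes match the bulk pool to within rounding.
    """
    occ_e = eq.cd3_occupancy
    occ_t = eq.cd19_occupancy
    for occ in (occ_e, occ_t):
        if not (0.0 <= occ <= 1.0 + 1e-12):
            raise ValueError(f"bulk occupancy {occ} outside [0, 1]")
    if binomial and rng is None:
        raise ValueError("binomial allocation requires an RNG")
    for cell in cells:
        occ = occ_e if cell.role == ROLE_EFFECTOR else occ_t
        if binomial:
            bound = float(rng.binomial(int(round(cell.antigen_total)), min(occ, 1.0)))
        else:
            bound = cell.antigen_total * occ
        cell.binary_complex = bound
        cell.free_antigen = max(cell.antigen_total - bound, 0.0)
    return cells


def cd3_downregulation_step(antigen_initial: float, downregulated: float,
                            ay_prime: float, dt_s: float,
                            params: CD3DownregParams = CD3DownregParams()) -> float:
    """Advance the cumulative downregulated CD3 amount by ``dt_s`` seconds.

    dD/dt = k_approach * (D_max([AY]') - D), integrated exactly over the
    step with [AY]' held at its current value.  D never decreases and never
    exceeds the plateau for the current engagement level.
    """
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    d_max = params.f_max * antigen_initial * ay_prime / (params.K_half + ay_prime) \
        if ay_prime > 0 else 0.0
    if d_max <= downregulated:
        return downregulated
    return d_max - (d_max - downregulated) * math.exp(-params.k_approach * dt_s)


def update_cd3_downregulation(cell: CellAgent, dt_s: float,
                              params: CD3DownregParams = CD3DownregParams()) -> CellAgent:
    """Apply CD3 downregulation to one effector cell over ``dt_s`` seconds.

    Both the free and bound pools shrink in proportion so the occupancy
    fraction is preserved while total surface CD3 falls.
    """
    if cell.role != ROLE_EFFECTOR:
        raise ValueError("CD3 downregulation applies to effector cells only")
    d_new = cd3_downregulation_step(cell.antigen_initial, cell.downregulated,
                                    cell.binary_complex, dt_s, params)
    old_total = cell.antigen_total
    new_total = max(cell.antigen_initial - d_new, 0.0)
    cell.downregulated = d_new
    if old_total > 0:
        scale = new_total / old_total
        cell.free_antigen *= scale
        cell.binary_complex *= scale
    cell.antigen_total = new_total
    return cell


def update_cd19_internalization(cell: CellAgent, dt_min: float,
                                rate_per_min: float = CD19_INTERNALIZATION_PER_MIN) -> CellAgent:
    """Exponential decay of the bound CD19–BiTE pool at ``rate_per_min``."""
    if dt_min < 0:
        raise ValueError("dt must be >= 0")
    if cell.role != ROLE_TARGET:
        raise ValueError("CD19 internalization applies to target cells only")
    lost = cell.binary_complex * (1.0 - math.exp(-rate_per_min * dt_min))
    cell.binary_complex -= lost
    cell.antigen_total = max(cell.antigen_total - lost, 0.0)
    return cell


def population_to_frame(cells: list[CellAgent]):
    """Snapshot a population as a table, one row per cell (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame([{
        "id": c.id, "role": c.role, "antigen_total": c.antigen_total,
        "free_antigen": c.free_antigen, "binary_complex": c.binary_complex,
        "state": c.state, "entity_id": c.entity_id, "organ": c.organ,
    } for c in cells])


def population_mean_antigen(cells: list[CellAgent], alive_only: bool = True) -> float:
    """Mean current antigen total, by default over non-lysed cells."""
    pool = [c.antigen_total for c in cells if not (alive_only and c.state == STATE_LYSED)]
    return float(np.mean(pool)) if pool else float("nan")
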