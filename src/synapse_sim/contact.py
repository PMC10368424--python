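"""Cell-scale probabilities: encounter and adhesion.

Two independent cellular processes gate synapse formation after the bulk
binding step:

* **Encounter** (step 2): a free effector cell in Brownian motion meets at
  least one immotile target within a round.  With a diffusion-limited
  Smoluchowski rate ``k_enc = 4 pi D_E (r_E + r_T)`` and target density C,
  the per-round probability is ``P_e = 1 - exp(-s k_enc C dt)`` where s is
  a unitless spatial coefficient per encountering-entity class.
* **Adhesion** (step 3): during a brief contact (0.1–5 s) ternary
  CD3–BiTE–CD19 bonds (AYB) form on the contact patch by 2D mass action
  from either binary complex plus the opposing free antigen.  Stable
  adhesion requires enough bonds: ``P_a = 1 - exp(-alpha N)`` with the
  sensitivity coefficient alpha the model's single calibrated parameter.

2D rate constants come from the 3D ones by a single-step model: the 3D
on-rate converted to molecular units and divided by a confinement length;
off-rates are unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .equilibrium import AVOGADRO, BindingConstants

#: Default unitless spatial multipliers per encountering-entity class.
#: A free effector is the reference class (1.0 by convention).
DEFAULT_SPATIAL_COEFFICIENTS = {
    "free_effector": 1.0,
    "ET": 1.0, "ETE": 1.0, "ETT": 1.0, "ETET": 1.0, "ETEE": 1.0, "ETTT": 1.0,
}

CONTACT_DURATION_RANGE_S = (0.1, 5.0)


@dataclass(frozen=True)
class EncounterParams:
    """Geometry and motility inputs of the encounter-rate kernel."""

    diffusion_coefficient: float = 0.2   # um^2/s, effector Brownian motion
    cell_radius_E: float = 5.5           # um (Jurkat-like)
    cell_radius_T: float = 5.0           # um (Raji-like)
    round_duration: float = 60.0         # s
    spatial_coefficients: dict = field(
        default_factory=lambda: dict(DEFAULT_SPATIAL_COEFFICIENTS))

    def __post_init__(self) -> None:
        for name in ("diffusion_coefficient", "cell_radius_E", "cell_radius_T",
                     "round_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def rate_constant_ml_per_s(self) -> float:
        """Steady-state Smoluchowski kernel 4 pi D (r_E + r_T), in mL/s."""
        k_um3 = 4.0 * math.pi * self.diffusion_coefficient * (
            self.cell_radius_E + self.cell_radius_T)
        return k_um3 * 1e-12  # 1 um^3 = 1e-12 mL

    def swept_volume_ml(self, dt_s: float) -> float:
        """Expected encounter volume cleared in ``dt_s`` seconds.

        Time-integrated diffusion-limited flux to an absorbing sphere of
        radius r_E + r_T: 4 pi D R (t + 2 R sqrt(t / (pi D))).  At cell
        scale D*t is comparable to R^2, so the transient sqrt-t term
        dominates a 60-s round and must not be dropped.
        """
        d = self.diffusion_coefficient
        r = self.cell_radius_E + self.cell_radius_T
        v_um3 = 4.0 * math.pi * d * r * (
            dt_s + 2.0 * r * math.sqrt(dt_s / (math.pi * d)))
        return v_um3 * 1e-12


@dataclass(frozen=True)
class TwoDConstants:
    """Membrane ("2D") kinetic constants on the contact patch."""

    kon2D_A: float   # (molecules um^-2)^-1 s^-1
    koff2D_A: float  # s^-1
    kon2D_B: float
    koff2D_B: float
    confinement_length: float  # nm

    def __post_init__(self) -> None:
        if self.confinement_length <= 0:
            raise ValueError("confinement_length must be > 0")
        if self.kon2D_A < 0 or self.kon2D_B < 0:
            raise ValueError("2D on-rates must be >= 0")


@dataclass(frozen=True)
class ContactEvent:
    """Surface state of one brief effector–target contact."""

    rho_A: float      # free CD3 density on effector patch, molecules/um^2
    rho_AY: float     # CD3-BiTE binary complex density
    rho_B: float      # free CD19 density on target patch
    rho_YB: float     # CD19-BiTE binary complex density
    contact_area: float  # um^2
    duration: float      # s, drawn uniformly from CONTACT_DURATION_RANGE_S

    def __post_init__(self) -> None:
        if min(self.rho_A, self.rho_AY, self.rho_B, self.rho_YB) < 0:
            raise ValueError("surface densities must be >= 0")
        if self.contact_area <= 0:
            raise ValueError("contact_area must be > 0")
        if not (CONTACT_DURATION_RANGE_S[0] <= self.duration <= CONTACT_DURATION_RANGE_S[1]):
            raise ValueError("contact duration outside the allowed range")


def encounter_probability(target_entity_density_per_ml: float,
                          params: EncounterParams,
                          entity_class: str = "free_effector") -> float:
    """Probability that one mover meets >=1 immotile partner in a round."""
    if target_entity_density_per_ml < 0:
        raise ValueError("density must be >= 0")
    try:
        s = params.spatial_coefficients[entity_class]
    except KeyError:
        raise KeyError(
            f"unknown encountering-entity class {entity_class!r}; configured "
            f"classes: {sorted(params.spatial_coefficients)}") from None
    lam = s * params.swept_volume_ml(params.round_duration) \
        * target_entity_density_per_ml
    return -math.expm1(-lam)


def derive_2d_constants(constants3d: BindingConstants,
                        confinement_length_nm: float = 20.0) -> TwoDConstants:
    """Single-step conversion of 3D rates to membrane rates.

    kon2D = kon3D / (N_A * sigma) after converting L to um^3; koff2D equals
    the 3D off-rate, so the 2D affinity is the 3D affinity divided by the
    confinement length sigma.
    """
    if confinement_length_nm <= 0:
        raise ValueError("confinement length must be > 0")
    sigma_um = confinement_length_nm * 1e-3
    to_2d = 1e15 / (AVOGADRO * sigma_um)  # (M^-1 s^-1) -> (um^-2 molecules)^-1 s^-1
    return TwoDConstants(
        kon2D_A=constants3d.kon_A * to_2d,
        koff2D_A=constants3d.koff_A,
        kon2D_B=constants3d.kon_B * to_2d,
        koff2D_B=constants3d.koff_B,
        confinement_length=confinement_length_nm,
    )


def bond_counts_batch(rho_A, rho_AY, rho_B, rho_YB, contact_area, duration,
                      k2d: TwoDConstants, n_steps: int = 60) -> np.ndarray:
    """Vectorised AYB bond formation over many contacts.

    Mass-action surface scheme with reactant depletion::

        A + YB -> AYB   (kon2D_A)      AYB -> A + YB   (koff2D_A)
        AY + B -> AYB   (kon2D_B)      AYB -> AY + B   (koff2D_B)

    integrated by fixed-step RK4 from zero bonds over each contact's
    duration.  Returns bond *counts* (density x contact area).
    """
    a = np.asarray(rho_A, dtype=float).copy()
    ay = np.asarray(rho_AY, dtype=float).copy()
    b = np.asarray(rho_B, dtype=float).copy()
    yb = np.asarray(rho_YB, dtype=float).copy()
    area = np.asarray(contact_area, dtype=float)
    dur = np.asarray(duration, dtype=float)
    n = np.zeros_like(a)

    kon_a, koff_a = k2d.kon2D_A, k2d.koff2D_A
    kon_b, koff_b = k2d.kon2D_B, k2d.koff2D_B

    def rhs(state):
        a_, ay_, b_, yb_, n_ = state
        f1 = kon_a * a_ * yb_ - koff_a * n_   # net flux through the CD3 arm
        f2 = kon_b * ay_ * b_ - koff_b * n_   # net flux through the CD19 arm
        return (-f1, -f2, -f2, -f1, f1 + f2)

    state = (a, ay, b, yb, n)
    dt = dur / n_steps
    for _ in range(n_steps):
        k1 = rhs(state)
        k2 = rhs(tuple(s + 0.5 * dt * k for s, k in zip(state, k1)))
        k3 = rhs(tuple(s + 0.5 * dt * k for s, k in zip(state, k2)))
        k4 = rhs(tuple(s + dt * k for s, k in zip(state, k3)))
        state = tuple(
            np.maximum(s + dt / 6.0 * (u1 + 2 * u2 + 2 * u3 + u4), 0.0)
            for s, u1, u2, u3, u4 in zip(state, k1, k2, k3, k4))
    n_final = state[4]
    if np.any(~np.isfinite(n_final)):
        raise FloatingPointError("bond ODE integration produced non-finite values")
    return n_final * area


def simulate_bond_formation(contact: ContactEvent, k2d: TwoDConstants,
                            n_steps: int = 60) -> float:
    """AYB bond count formed on one contact patch (see bond_counts_batch)."""
    out = bond_counts_batch(
        np.array([contact.rho_A]), np.array([contact.rho_AY]),
        np.array([contact.rho_B]), np.array([contact.rho_YB]),
        np.array([contact.contact_area]), np.array([contact.duration]),
        k2d, n_steps=n_steps)
    return float(out[0])


def bond_count_fast(rho_a: float, rho_ay: float, rho_b: float, rho_yb: float,
                    contact_area: float, duration: float, k2d: TwoDConstants,
                    n_steps: int = 40) -> float:
    """Scalar fast path of :func:`bond_counts_batch` (same reaction scheme).

    Used by the round loop, where contacts arrive one at a time.  With
    negligible dissociation the two production channels consume disjoint
    species, so each decouples into a bimolecular pair whose scarce partner
    decays pseudo-first-order against the abundant one:
    ``N_i = s0 (1 - exp(-kon * A0 * t))``.  That closed form is exact up to
    the perturbation of the abundant pool; it is used whenever dissociation
    and the abundant-side consumption are both below 2% over the contact,
    and the RK4 scheme of the batch integrator runs otherwise.
    """
    kon_a, koff_a = k2d.kon2D_A, k2d.koff2D_A
    kon_b, koff_b = k2d.kon2D_B, k2d.koff2D_B

    if kon_a * rho_a * rho_yb + kon_b * rho_ay * rho_b == 0.0:
        return 0.0
    if (koff_a + koff_b) * duration < 0.02:
        n_total = 0.0
        ok = True
        for kon, x0, y0 in ((kon_a, rho_a, rho_yb), (kon_b, rho_ay, rho_b)):
            scarce, abundant = min(x0, y0), max(x0, y0)
            if scarce == 0.0 or kon == 0.0:
                continue
            n_i = scarce * -math.expm1(-kon * abundant * duration)
            if n_i >= 0.02 * abundant:
                ok = False
                break
            n_total += n_i
        if ok:
            return n_total * contact_area

    a, ay, b, yb, n = rho_a, rho_ay, rho_b, rho_yb, 0.0
    dt = duration / n_steps

    def rhs(a_, ay_, b_, yb_, n_):
        f1 = kon_a * a_ * yb_ - koff_a * n_
        f2 = kon_b * ay_ * b_ - koff_b * n_
        return -f1, -f2, -f2, -f1, f1 + f2

    for _ in range(n_steps):
        k1 = rhs(a, ay, b, yb, n)
        k2 = rhs(a + 0.5 * dt * k1[0], ay + 0.5 * dt * k1[1],
                 b + 0.5 * dt * k1[2], yb + 0.5 * dt * k1[3], n + 0.5 * dt * k1[4])
        k3 = rhs(a + 0.5 * dt * k2[0], ay + 0.5 * dt * k2[1],
                 b + 0.5 * dt * k2[2], yb + 0.5 * dt * k2[3], n + 0.5 * dt * k2[4])
        k4 = rhs(a + dt * k3[0], ay + dt * k3[1],
                 b + dt * k3[2], yb + dt * k3[3], n + dt * k3[4])
        a = max(a + dt / 6.0 * (k1[0] + 2 * k2[0] + 2 * k3[0] + k4[0]), 0.0)
        ay = max(ay + dt / 6.0 * (k1[1] + 2 * k2[1] + 2 * k3[1] + k4[1]), 0.0)
        b = max(b + dt / 6.0 * (k1[2] + 2 * k2[2] + 2 * k3[2] + k4[2]), 0.0)
        yb = max(yb + dt / 6.0 * (k1[3] + 2 * k2[3] + 2 * k3[3] + k4[3]), 0.0)
        n = max(n + dt / 6.0 * (k1[4] + 2 * k2[4] + 2 * k3[4] + k4[4]), 0.0)
    return n * contact_area


def adhesion_probability(bond_count: float, alpha: float) -> float:
    """Small-system adhesion frequency P_a = 1 - exp(-alpha N)."""
    if bond_count < 0:
        raise ValueError("bond count must be >= 0")
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    return -math.expm1(-alpha * bond_count)


def surface_density(count_per_cell: float, cell_radius_um: float) -> float:
    """Uniform surface density (molecules/um^2) of a per-cell count."""
    return count_per_cell / (4.0 * math.pi * cell_radius_um ** 2)
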