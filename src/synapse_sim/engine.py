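"""Base-model round loop: encounters, adhesions, and synapse variants (<=1 h).

Each 60-second round runs, in order:

1. encounter probabilities are recomputed from current free-entity densities;
2. every free effector gets one chance to encounter a free target; on
   encounter, a contact event (random duration 0.1-5 s) is simulated on the
   two cells' current surface pools and adhesion accepted with
   ``P_a = 1 - exp(-alpha N_bonds)``;
3. every existing 2-3-cell synapse entity may recruit one additional free
   cell (effector vs target in proportion to the free pools), passing the
   same adhesion test against one of its exposed members; 4-cell entities
   recruit nothing;
4. surface receptors update (CD3 downregulation; CD19 internalization in
   the base-model context).

The simulated system is a configurable subvolume (default 0.1 uL) of the
co-incubation, so probabilities are driven by densities, not agent counts.
Within the hour the bulk binding equilibrium is frozen and formed synapses
are unbreakable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import contact as ct
from . import population as pop
from .config import RunConfig, spawn_rngs
from .equilibrium import (BindingConstants, counts_to_molar, ng_per_ml_to_molar,
                          solve_equilibrium)

ENTITY_LABELS = {
    (1, 1): "ET", (2, 1): "ETE", (1, 2): "ETT",
    (2, 2): "ETET", (3, 1): "ETEE", (1, 3): "ETTT",
}
VARIANT_LABELS = ("ETE", "ETT", "ETET", "ETEE", "ETTT")
MAX_ENTITY_SIZE = 4


class ClassificationError(ValueError):
    pass


class InvariantError(RuntimeError):
    """Internal bookkeeping inconsistency; fail fast."""


def classify_entity(e_count: int, t_count: int, join_order=None) -> str:
    """Label a 2-4-cell synapse entity by its composition.

    Compositions must be reachable by single-cell accretion from a typical
    ET synapse, so e.g. (4, 0) is rejected.
    """
    try:
        return ENTITY_LABELS[(e_count, t_count)]
    except KeyError:
        raise ClassificationError(
            f"composition E={e_count}, T={t_count} is not reachable from ET "
            "by single-cell accretion (2-4 cells)") from None


@dataclass
class SynapseEntity:
    id: int
    member_ids: list[int]
    e_count: int
    t_count: int
    formed_at: float  # s

    @property
    def label(self) -> str:
        return classify_entity(self.e_count, self.t_count)

    @property
    def size(self) -> int:
        return self.e_count + self.t_count


class _FreePool:
    """Cell-id pool with O(1) add/remove and uniform random draw."""

    def __init__(self, ids=()):
        self._items: list[int] = list(ids)
        self._pos: dict[int, int] = {v: i for i, v in enumerate(self._items)}

    def __len__(self) -> int:
        return len(self._items)

    def __contains__(self, item: int) -> bool:
        return item in self._pos

    def add(self, item: int) -> None:
        if item in self._pos:
            raise InvariantError(f"cell {item} already free")
        self._pos[item] = len(self._items)
        self._items.append(item)

    def remove(self, item: int) -> None:
        i = self._pos.pop(item)
        last = self._items.pop()
        if i < len(self._items):
            self._items[i] = last
            self._pos[last] = i

    def pick(self, rng: np.random.Generator) -> int:
        return self._items[int(rng.integers(len(self._items)))]

    def sample(self, rng: np.random.Generator, k: int) -> list[int]:
        k = min(k, len(self._items))
        idx = rng.choice(len(self._items), size=k, replace=False)
        return [self._items[int(i)] for i in idx]


@dataclass
class SimState:
    """Agents, synapses, clock, and RNG streams of one replicate."""

    cells: list[pop.CellAgent]
    scaled_volume_ml: float
    rng: np.random.Generator
    clock_s: float = 0.0
    entities: dict[int, SynapseEntity] = field(default_factory=dict)
    free_effectors: _FreePool = field(default_factory=_FreePool)
    free_targets: _FreePool = field(default_factory=_FreePool)
    events: list[dict] = field(default_factory=list)
    _next_entity_id: int = 0

    @property
    def n_effectors(self) -> int:
        return sum(1 for c in self.cells if c.role == pop.ROLE_EFFECTOR)

    @property
    def n_targets(self) -> int:
        return sum(1 for c in self.cells if c.role == pop.ROLE_TARGET)

    def engaged_fraction(self, role: str) -> float:
        """Fraction of cells of ``role`` currently or terminally in a synapse.

        Targets lysed inside a synapse remain counted as engaged."""
        total = n_in = 0
        for c in self.cells:
            if c.role != role:
                continue
            total += 1
            if c.entity_id is not None or c.state == pop.STATE_LYSED:
                n_in += 1
        return n_in / total if total else 0.0

    def new_entity(self, eff_id: int, tgt_id: int) -> SynapseEntity:
        ent = SynapseEntity(id=self._next_entity_id, member_ids=[eff_id, tgt_id],
                            e_count=1, t_count=1, formed_at=self.clock_s)
        self._next_entity_id += 1
        self.entities[ent.id] = ent
        for cid in (eff_id, tgt_id):
            cell = self.cells[cid]
            if cell.entity_id is not None:
                raise InvariantError(f"cell {cid} already engaged")
            cell.entity_id = ent.id
            cell.state = pop.STATE_ENGAGED
        self.free_effectors.remove(eff_id)
        self.free_targets.remove(tgt_id)
        return ent


@dataclass(frozen=True)
class EngineParams:
    """Resolved physical parameters for the round loop."""

    binding: BindingConstants
    encounter: ct.EncounterParams
    k2d: ct.TwoDConstants
    alpha: float
    contact_area_um2: float
    downreg: pop.CD3DownregParams
    cd19_internalization_per_min: float = 0.002
    internalization_on: bool = True
    downreg_on: bool = True
    #: per-round membership audit; O(cells), switched off in the organ loop
    invariant_checks: bool = True


def engine_params_from_config(cfg: RunConfig) -> EngineParams:
    p = cfg.params
    binding = BindingConstants(kon_A=p.binding.kon_A, koff_A=p.binding.koff_A,
                               kon_B=p.binding.kon_B, koff_B=p.binding.koff_B)
    enc = ct.EncounterParams(
        diffusion_coefficient=p.encounter.diffusion_coefficient_um2_s,
        cell_radius_E=p.encounter.cell_radius_E_um,
        cell_radius_T=p.encounter.cell_radius_T_um,
        round_duration=p.encounter.round_duration_s,
        spatial_coefficients=dict(p.encounter.spatial_coefficients))
    k2d = ct.derive_2d_constants(binding, p.adhesion.confinement_length_nm)
    return EngineParams(
        binding=binding, encounter=enc, k2d=k2d, alpha=p.adhesion.alpha,
        contact_area_um2=p.adhesion.contact_area_um2,
        downreg=pop.CD3DownregParams(f_max=p.downreg.f_max,
                                     k_approach=p.downreg.k_approach_per_s,
                                     K_half=p.downreg.K_half),
        cd19_internalization_per_min=p.population.cd19_internalization_per_min)


def initialize_state(cfg: RunConfig, rng_pop: np.random.Generator,
                     rng_contacts: np.random.Generator,
                     params: EngineParams) -> SimState:
    """Build populations in the scaled subvolume and allocate complexes."""
    vol = cfg.scaled_volume_ml
    n_eff = int(round(cfg.effector_density_per_ml * vol))
    n_tgt = int(round(cfg.target_density_per_ml * vol))
    effs = pop.generate_population(n_eff, pop.ROLE_EFFECTOR, cfg.cd3_spec(), rng_pop)
    tgts = pop.generate_population(n_tgt, pop.ROLE_TARGET, cfg.cd19_spec(), rng_pop)
    cells: list[pop.CellAgent] = []
    for c in effs + tgts:
        c.id = len(cells)
        cells.append(c)

    a_tot = counts_to_molar(sum(c.antigen_total for c in effs) / max(n_eff, 1),
                            n_eff / vol) if n_eff else 0.0
    b_tot = counts_to_molar(sum(c.antigen_total for c in tgts) / max(n_tgt, 1),
                            n_tgt / vol) if n_tgt else 0.0
    y_tot = ng_per_ml_to_molar(cfg.bite_ng_per_ml, cfg.params.bite_mw_kda)
    eq = solve_equilibrium(params.binding, a_tot, b_tot, y_tot)
    pop.allocate_binary_complexes(cells, eq, rng=rng_pop,
                                  binomial=cfg.params.population.binomial_allocation)

    state = SimState(cells=cells, scaled_volume_ml=vol, rng=rng_contacts)
    for c in cells:
        (state.free_effectors if c.role == pop.ROLE_EFFECTOR
         else state.free_targets).add(c.id)
    return state


def _attempt_adhesion(state: SimState, eff: pop.CellAgent, tgt: pop.CellAgent,
                      params: EngineParams) -> tuple[bool, float]:
    """Simulate one contact event and test adhesion; returns (ok, bonds)."""
    rng = state.rng
    dur = float(rng.uniform(*ct.CONTACT_DURATION_RANGE_S))
    r_e = params.encounter.cell_radius_E
    r_t = params.encounter.cell_radius_T
    bonds = ct.bond_count_fast(
        ct.surface_density(eff.free_antigen, r_e),
        ct.surface_density(eff.binary_complex, r_e),
        ct.surface_density(tgt.free_antigen, r_t),
        ct.surface_density(tgt.binary_complex, r_t),
        params.contact_area_um2, dur, params.k2d)
    p_a = ct.adhesion_probability(bonds, params.alpha)
    return bool(rng.random() < p_a), bonds


def step_round(state: SimState, params: EngineParams) -> SimState:
    """Execute one 60-s round (see module docstring for the ordering)."""
    rng = state.rng
    vol = state.scaled_volume_ml
    dt = params.encounter.round_duration

    # (1) probabilities from densities at the start of the round
    tgt_density = len(state.free_targets) / vol
    p_enc = ct.encounter_probability(tgt_density, params.encounter, "free_effector")
    # Entity recruitment fluxes: free effectors diffuse toward the entity as
    # well (relative diffusivity ~2D), free targets are immotile, so the two
    # classes contribute different swept volumes.
    enc2 = ct.EncounterParams(
        diffusion_coefficient=2.0 * params.encounter.diffusion_coefficient,
        cell_radius_E=params.encounter.cell_radius_E,
        cell_radius_T=params.encounter.cell_radius_T,
        round_duration=params.encounter.round_duration,
        spatial_coefficients=params.encounter.spatial_coefficients)
    v_e = enc2.swept_volume_ml(dt)      # entity vs diffusing free effector
    v_t = params.encounter.swept_volume_ml(dt)  # entity vs immotile target

    # (2) free-effector encounters: each free effector has one chance;
    # successful adhesions remove the pair, failures leave both free.
    n_free_e = len(state.free_effectors)
    if n_free_e and p_enc > 0:
        n_hits = int(rng.binomial(n_free_e, p_enc))
        for eff_id in state.free_effectors.sample(rng, n_hits):
            if eff_id not in state.free_effectors or not len(state.free_targets):
                continue
            tgt_id = state.free_targets.pick(rng)
            ok, bonds = _attempt_adhesion(
                state, state.cells[eff_id], state.cells[tgt_id], params)
            if ok:
                ent = state.new_entity(eff_id, tgt_id)
                state.events.append({"t_s": state.clock_s, "event": "form",
                                     "entity": ent.id, "bonds": bonds})

    # (3) recruitment: existing entities (snapshot; entities formed this
    # round wait until the next one) may each add one free cell
    for ent in [e for e in state.entities.values()
                if e.size < MAX_ENTITY_SIZE and e.formed_at < state.clock_s]:
        n_e, n_t = len(state.free_effectors), len(state.free_targets)
        flux_e = n_e / vol * v_e
        flux_t = n_t / vol * v_t
        if flux_e + flux_t <= 0:
            continue
        s_coef = params.encounter.spatial_coefficients.get(ent.label)
        if s_coef is None:
            raise KeyError(f"no spatial coefficient for entity class {ent.label!r}")
        p_rec = -math.expm1(-s_coef * (flux_e + flux_t))
        if rng.random() >= p_rec:
            continue
        recruit_effector = rng.random() < flux_e / (flux_e + flux_t)
        # adhesion tested between the recruit and one exposed member of the
        # opposite role (its current surface pools)
        if recruit_effector:
            new_id = state.free_effectors.pick(rng)
            partner_ids = [cid for cid in ent.member_ids
                           if state.cells[cid].role == pop.ROLE_TARGET]
        else:
            new_id = state.free_targets.pick(rng)
            partner_ids = [cid for cid in ent.member_ids
                           if state.cells[cid].role == pop.ROLE_EFFECTOR]
        partner = state.cells[partner_ids[int(rng.integers(len(partner_ids)))]]
        new_cell = state.cells[new_id]
        eff, tgt = (new_cell, partner) if recruit_effector else (partner, new_cell)
        ok, bonds = _attempt_adhesion(state, eff, tgt, params)
        if ok:
            ent.member_ids.append(new_id)
            if recruit_effector:
                ent.e_count += 1
                state.free_effectors.remove(new_id)
            else:
                ent.t_count += 1
                state.free_targets.remove(new_id)
            new_cell.entity_id = ent.id
            new_cell.state = pop.STATE_ENGAGED
            state.events.append({"t_s": state.clock_s, "event": "recruit",
                                 "entity": ent.id, "label": ent.label,
                                 "bonds": bonds})

    # (4) receptor updates, every 60 s
    if params.downreg_on:
        for c in state.cells:
            if c.role == pop.ROLE_EFFECTOR and c.state != pop.STATE_LYSED:
                pop.update_cd3_downregulation(c, dt, params.downreg)
    if params.internalization_on and params.cd19_internalization_per_min > 0:
        for c in state.cells:
            if c.role == pop.ROLE_TARGET and c.state != pop.STATE_LYSED:
                pop.update_cd19_internalization(
                    c, dt / 60.0, params.cd19_internalization_per_min)

    state.clock_s += dt
    if params.invariant_checks:
        _check_invariants(state)
    return state


def _check_invariants(state: SimState) -> None:
    engaged = [c.id for c in state.cells
               if c.entity_id is not None and c.state != pop.STATE_LYSED]
    member_count = sum(len(e.member_ids) for e in state.entities.values())
    lysed_members = sum(1 for c in state.cells
                        if c.state == pop.STATE_LYSED and c.entity_id is not None)
    if len(engaged) + lysed_members != member_count:
        raise InvariantError("entity membership inconsistent with cell states")
    for e in state.entities.values():
        if not (2 <= e.size <= MAX_ENTITY_SIZE):
            raise InvariantError(f"entity {e.id} has {e.size} members")


@dataclass
class VariantSummary:
    n_entities: int
    variant_fraction: float
    composition: dict[str, float]
    median_et_total: float
    median_et_variants: float


def summarize_variants(state: SimState) -> VariantSummary:
    """Variant share of synapses, composition shares, and E:T medians."""
    ents = list(state.entities.values())
    if not ents:
        return VariantSummary(0, float("nan"), {}, float("nan"), float("nan"))
    labels = [e.label for e in ents]
    variants = [e for e in ents if e.label != "ET"]
    shares: dict[str, float] = {}
    if variants:
        for lab in VARIANT_LABELS:
            n = sum(1 for e in variants if e.label == lab)
            if n:
                shares[lab] = n / len(variants)
    et_all = [e.e_count / e.t_count for e in ents]
    et_var = [e.e_count / e.t_count for e in variants]
    return VariantSummary(
        n_entities=len(ents),
        variant_fraction=len(variants) / len(ents),
        composition=shares,
        median_et_total=float(np.median(et_all)),
        median_et_variants=float(np.median(et_var)) if et_var else float("nan"),
    )


@dataclass
class BaseResult:
    """Replicated base-model output bundle."""

    timeseries: pd.DataFrame       # replicate, time_min, % engaged (E and T)
    entities: pd.DataFrame         # one row per synapse entity at end
    summary: pd.DataFrame          # per-timepoint mean +/- SE over replicates
    variant_summaries: list[VariantSummary]
    final_states: list[SimState]

    @property
    def final_engagement_pct(self) -> float:
        """Mean % of effector cells engaged at the final timepoint."""
        last = self.summary.iloc[-1]
        return float(last["pct_effectors_engaged_mean"])


def run_base(cfg: RunConfig, keep_states: bool = False) -> BaseResult:
    """Replicated base-model runs (<= 60 min)."""
    if cfg.duration_min > 60.0 + 1e-9:
        raise ValueError("base model is limited to 60 min; use the in vitro model")
    params = engine_params_from_config(cfg)
    n_rounds = int(round(cfg.duration_min * 60 / params.encounter.round_duration))

    ts_rows, ent_rows, var_summaries, states = [], [], [], []
    for rep in range(cfg.replicates):
        rngs = spawn_rngs(cfg.seed * 100003 + rep)
        state = initialize_state(cfg, rngs["population"], rngs["contacts"], params)
        ts_rows.append({"replicate": rep, "time_min": 0.0,
                        "pct_effectors_engaged": 0.0, "pct_targets_engaged": 0.0})
        for _ in range(n_rounds):
            step_round(state, params)
            ts_rows.append({
                "replicate": rep, "time_min": state.clock_s / 60.0,
                "pct_effectors_engaged": 100 * state.engaged_fraction(pop.ROLE_EFFECTOR),
                "pct_targets_engaged": 100 * state.engaged_fraction(pop.ROLE_TARGET),
            })
        for e in state.entities.values():
            ent_rows.append({"replicate": rep, "entity": e.id, "label": e.label,
                             "e_count": e.e_count, "t_count": e.t_count,
                             "formed_at_min": e.formed_at / 60.0})
        var_summaries.append(summarize_variants(state))
        if keep_states:
            states.append(state)

    ts = pd.DataFrame(ts_rows)
    summary = (ts.groupby("time_min")
                 .agg(pct_effectors_engaged_mean=("pct_effectors_engaged", "mean"),
                      pct_effectors_engaged_se=("pct_effectors_engaged", "sem"),
                      pct_targets_engaged_mean=("pct_targets_engaged", "mean"),
                      pct_targets_engaged_se=("pct_targets_engaged", "sem"))
                 .reset_index())
    entities = pd.DataFrame(ent_rows, columns=["replicate", "entity", "label",
                                               "e_count", "t_count", "formed_at_min"])
    return BaseResult(timeseries=ts, entities=entities, summary=summary,
                      variant_summaries=var_summaries, final_states=states)


def pooled_variant_stats(result: BaseResult) -> VariantSummary:
    """Variant statistics pooled over all replicates of a run."""
    ents = result.entities
    if ents.empty:
        return VariantSummary(0, float("nan"), {}, float("nan"), float("nan"))
    labels = ents["label"]
    variants = ents[labels != "ET"]
    shares = {}
    if len(variants):
        counts = variants["label"].value_counts()
        shares = {lab: float(counts.get(lab, 0)) / len(variants)
                  for lab in VARIANT_LABELS if counts.get(lab, 0)}
    et_all = ents["e_count"] / ents["t_count"]
    et_var = variants["e_count"] / variants["t_count"]
    return VariantSummary(
        n_entities=len(ents),
        variant_fraction=len(variants) / len(ents),
        composition=shares,
        median_et_total=float(et_all.median()),
        median_et_variants=float(et_var.median()) if len(et_var) else float("nan"),
    )
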