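"""In vivo model: organ compartments, trafficking, dosing, regimen ranking.

The body is a set of named compartments (blood, bone marrow, lymph nodes,
spleen, lung, gut, remainder).  A fixed "partition repertoire" describes
what fraction of each lymphocyte population resides in each compartment;
synapse formation and killing run independently inside every organ except
blood, which is a pure trafficking route.  Every hour 4.17% of the free B
cells in each organ are released to the blood and immediately reassigned to
a new organ multinomially by the repertoire; B cells also turn over
(daughters inherit the parent's CD19 expression, so therapeutic selection —
not mutation — drives antigen escape), and the BiTE concentration follows
the dosing regimen through a steady-state infusion-rate/clearance
conversion with per-organ exposure scaling.

T cells are exogenous: their organ densities follow the repertoire and an
optional patient-specific time multiplier; T-cell death and trafficking are
not modelled.

The whole system is simulated at a single density-preserving scale factor
so each organ's agent count is proportional to its real cell count, which
lets trafficking move agents directly while conserving totals exactly.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from . import population as pop
from .config import RunConfig, spawn_rngs
from .engine import SimState, engine_params_from_config, step_round
from .population import ExpressionSpec
from .serial import KillRecord, _detach_due_entities, reequilibrate

STATE_DEPARTED = "departed"

#: States of cells that are present and alive in an organ.
_ALIVE = (pop.STATE_FREE, pop.STATE_ENGAGED)

HOURS_PER_WEEK = 168


class OrganConfigError(ValueError):
    pass


@dataclass(frozen=True)
class Organ:
    name: str
    volume_ml: float
    b_fraction: float        # partition-repertoire fraction of B cells
    t_fraction: float        # same for T cells
    bite_exposure: float = 1.0   # organ concentration / plasma concentration
    forms_synapses: bool = True

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise OrganConfigError(f"{self.name}: volume must be > 0")
        if not (0 <= self.b_fraction <= 1 and 0 <= self.t_fraction <= 1):
            raise OrganConfigError(f"{self.name}: partition fractions in [0,1]")


# Default partition repertoire and volumes.  Blood holds 2% of lymphocytes;
# the remaining fractions and volumes are literature-plausible values for a
# human reference body (see docs/methods.md) and are fully overridable.
DEFAULT_ORGANS = (
    Organ("blood", 5000.0, 0.02, 0.02, forms_synapses=False),
    Organ("bone_marrow", 1750.0, 0.30, 0.05),
    Organ("lymph_nodes", 250.0, 0.25, 0.45),
    Organ("spleen", 200.0, 0.15, 0.20),
    Organ("lung", 1000.0, 0.03, 0.08),
    Organ("gut", 1200.0, 0.10, 0.10),
    Organ("remainder", 30000.0, 0.15, 0.10),
)


class OrganSystem:
    """Validated set of compartments with partition fractions summing to 1."""

    def __init__(self, organs=DEFAULT_ORGANS):
        self.organs: dict[str, Organ] = {o.name: o for o in organs}
        if "blood" not in self.organs:
            raise OrganConfigError("an OrganSystem requires a blood compartment")
        if self.organs["blood"].forms_synapses:
            raise OrganConfigError(
                "the blood compartment is a trafficking route only and must "
                "not form synapses")
        for attr in ("b_fraction", "t_fraction"):
            total = sum(getattr(o, attr) for o in self.organs.values())
            if abs(total - 1.0) > 1e-9:
                raise OrganConfigError(f"{attr}s sum to {total}, expected 1")

    def __iter__(self):
        return iter(self.organs.values())

    def __getitem__(self, name: str) -> Organ:
        return self.organs[name]

    @property
    def names(self) -> list[str]:
        return list(self.organs)


def partition_cells(total_count: float, organs: OrganSystem,
                    kind: str = "b") -> dict[str, float]:
    """Distribute a systemic cell count over compartments by the repertoire.

    Returns per-organ counts; the sum over organs equals the input exactly.
    """
    attr = {"b": "b_fraction", "t": "t_fraction"}[kind]
    counts = {o.name: total_count * getattr(o, attr) for o in organs}
    return counts


def organ_densities(total_count: float, organs: OrganSystem,
                    kind: str = "b") -> dict[str, float]:
    counts = partition_cells(total_count, organs, kind)
    return {name: counts[name] / organs[name].volume_ml for name in counts}


@dataclass(frozen=True)
class DoseRegimen:
    """Piecewise-constant continuous-infusion schedule.

    ``weekly_ug_per_day[i]`` is the infusion rate during week i; weeks past
    the end of the list are drug-free.
    """

    name: str
    scheme: int
    dose_level: str
    weekly_ug_per_day: tuple[float, ...]

    def __post_init__(self) -> None:
        if any(w < 0 for w in self.weekly_ug_per_day):
            raise ValueError("dose levels must be non-negative")

    def infusion_rate_ug_per_day(self, time_h: float) -> float:
        week = int(time_h // HOURS_PER_WEEK)
        if week < 0 or week >= len(self.weekly_ug_per_day):
            return 0.0
        return self.weekly_ug_per_day[week]

    def plasma_ng_per_ml(self, time_h: float, clearance_l_per_h: float) -> float:
        """Steady-state concentration = infusion rate / clearance."""
        rate = self.infusion_rate_ug_per_day(time_h)
        return rate / (24.0 * clearance_l_per_h)  # ug/day / (L/h*24h) = ug/L = ng/mL

    @property
    def total_dose_ug(self) -> float:
        return 7.0 * sum(self.weekly_ug_per_day)


def load_regimen(name: str) -> DoseRegimen:
    """Load a dosing-regimen preset shipped with the package."""
    ref = importlib.resources.files("synapse_sim") / "presets" / "regimens.yaml"
    data = yaml.safe_load(ref.read_text())
    try:
        entry = data[name]
    except KeyError:
        raise KeyError(f"unknown regimen preset {name!r}; "
                       f"available: {sorted(data)}") from None
    return DoseRegimen(name=name, scheme=int(entry["scheme"]),
                       dose_level=str(entry["dose_level"]),
                       weekly_ug_per_day=tuple(float(x) for x in entry["weekly_ug_per_day"]))


@dataclass(frozen=True)
class PatientProfile:
    baseline_blood_b_per_ul: float
    b_growth_per_day: float = 0.0071
    t_to_b_ratio: float = 1.0
    cd19_mean: float = 3.0e4
    cd3_mean: float = 1.0e5
    #: optional (time_h, multiplier) control points for T-cell expansion,
    #: linearly interpolated; None = constant T density
    t_multiplier_points: tuple[tuple[float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.baseline_blood_b_per_ul <= 0:
            raise ValueError("baseline B density must be > 0")
        if self.b_growth_per_day < 0:
            raise ValueError("growth rate must be >= 0")

    def t_multiplier(self, time_h: float) -> float:
        if not self.t_multiplier_points:
            return 1.0
        ts = [p[0] for p in self.t_multiplier_points]
        ms = [p[1] for p in self.t_multiplier_points]
        return float(np.interp(time_h, ts, ms))

    @property
    def total_b_count(self) -> float:
        """Systemic B count implied by the blood density and 2% repertoire."""
        # density/uL -> /mL; blood holds b_fraction of the system
        return self.baseline_blood_b_per_ul * 1e3 * 5000.0 / 0.02


@dataclass
class InVivoState:
    """Per-organ agent populations at a common density-preserving scale."""

    organs: OrganSystem
    scale: float                       # simulated fraction of the real body
    states: dict[str, SimState]        # per-organ agents + synapses
    rng_traffic: np.random.Generator
    clock_h: float = 0.0
    kill_records: dict[str, list[KillRecord]] = field(default_factory=dict)

    def alive_b_count(self, organ: str) -> int:
        return sum(1 for c in self.states[organ].cells
                   if c.role == pop.ROLE_TARGET and c.state in _ALIVE)

    def total_alive_b(self) -> int:
        return sum(self.alive_b_count(name) for name in self.organs.names)

    def free_b_ids(self, organ: str) -> list[int]:
        st = self.states[organ]
        return [c.id for c in st.cells
                if c.role == pop.ROLE_TARGET and c.state == pop.STATE_FREE]


def _make_organ_state(organ: Organ, n_b: int, n_t: int, subvolume_ml: float,
                      profile: PatientProfile, dispersion: float,
                      rng_pop: np.random.Generator,
                      rng_contacts: np.random.Generator) -> SimState:
    b_spec = ExpressionSpec(mean=profile.cd19_mean, dispersion=dispersion, label="B")
    t_spec = ExpressionSpec(mean=profile.cd3_mean, dispersion=dispersion, label="T")
    tgts = pop.generate_population(n_b, pop.ROLE_TARGET, b_spec, rng_pop)
    effs = pop.generate_population(n_t, pop.ROLE_EFFECTOR, t_spec, rng_pop) \
        if organ.forms_synapses else []
    cells: list[pop.CellAgent] = []
    for c in effs + tgts:
        c.id = len(cells)
        c.organ = organ.name
        cells.append(c)
    st = SimState(cells=cells, scaled_volume_ml=subvolume_ml, rng=rng_contacts)
    for c in cells:
        (state_pool := st.free_effectors if c.role == pop.ROLE_EFFECTOR
         else st.free_targets).add(c.id)
    return st


def _add_b_cell(st: SimState, organ_name: str, cd19: float) -> pop.CellAgent:
    cell = pop.CellAgent(id=len(st.cells), role=pop.ROLE_TARGET,
                         antigen_total=cd19, organ=organ_name)
    st.cells.append(cell)
    st.free_targets.add(cell.id)
    return cell


def traffic_b_cells(state: InVivoState, dt_h: float = 1.0,
                    rate_per_h: float = 0.0417) -> InVivoState:
    """One trafficking event: each organ releases ``rate_per_h*dt`` of its
    free B cells to the blood, and the pooled cells are reassigned to new
    organs multinomially by the partition repertoire.  Trafficking alone
    conserves the total B count exactly."""
    if dt_h != int(dt_h):
        raise ValueError("trafficking runs on an hourly event loop")
    rng = state.rng_traffic
    p_leave = min(rate_per_h * dt_h, 1.0)
    pool_cd19: list[float] = []
    for name in state.organs.names:
        st = state.states[name]
        free_ids = state.free_b_ids(name)
        if not free_ids:
            continue
        n_leave = int(rng.binomial(len(free_ids), p_leave))
        if n_leave == 0:
            continue
        leavers = rng.choice(len(free_ids), size=n_leave, replace=False)
        for idx in leavers:
            cid = free_ids[int(idx)]
            cell = st.cells[cid]
            st.free_targets.remove(cid)
            cell.state = STATE_DEPARTED
            pool_cd19.append(cell.antigen_total)
    if not pool_cd19:
        return state
    fractions = np.array([state.organs[n].b_fraction for n in state.organs.names])
    destinations = rng.choice(len(fractions), size=len(pool_cd19), p=fractions)
    for cd19, dest in zip(pool_cd19, destinations):
        name = state.organs.names[dest]
        _add_b_cell(state.states[name], name, cd19)
    return state


def update_t_cells(state: InVivoState, profile: PatientProfile,
                   baseline_t: dict[str, int], time_h: float) -> InVivoState:
    """Apply the exogenous patient T-cell time multiplier per organ.

    Expansion clones random existing effectors (fresh agents at the organ's
    expression distribution); contraction retires free effectors.  T cells
    are an input, not a modelled population — no death or trafficking.
    """
    mult = profile.t_multiplier(time_h)
    rng = state.rng_traffic
    for name, n_base in baseline_t.items():
        st = state.states[name]
        effs = [c for c in st.cells
                if c.role == pop.ROLE_EFFECTOR and c.state in _ALIVE]
        desired = int(round(n_base * mult))
        if desired > len(effs) and effs:
            for _ in range(desired - len(effs)):
                template = effs[int(rng.integers(len(effs)))]
                cell = pop.CellAgent(id=len(st.cells), role=pop.ROLE_EFFECTOR,
                                     antigen_total=template.antigen_initial,
                                     organ=name)
                st.cells.append(cell)
                st.free_effectors.add(cell.id)
        elif desired < len(effs):
            free = [c for c in effs if c.state == pop.STATE_FREE]
            n_drop = min(len(effs) - desired, len(free))
            for idx in rng.choice(len(free), size=n_drop, replace=False):
                cell = free[int(idx)]
                st.free_effectors.remove(cell.id)
                cell.state = STATE_DEPARTED
    return state


def b_cell_turnover(state: InVivoState, profile: PatientProfile,
                    dt_h: float = 1.0) -> InVivoState:
    """Per-organ exponential B-cell growth; daughters inherit CD19."""
    if profile.b_growth_per_day == 0.0:
        return state
    p_divide = -math.expm1(-profile.b_growth_per_day * dt_h / 24.0)
    rng = state.rng_traffic
    for name in state.organs.names:
        st = state.states[name]
        alive = [c for c in st.cells
                 if c.role == pop.ROLE_TARGET and c.state in _ALIVE]
        if not alive:
            continue
        n_div = int(rng.binomial(len(alive), p_divide))
        if n_div == 0:
            continue
        chosen = rng.choice(len(alive), size=n_div, replace=False)
        for idx in chosen:
            _add_b_cell(st, name, alive[int(idx)].antigen_total)
    return state


@dataclass
class InVivoResult:
    blood_b: pd.DataFrame          # replicate, time_h, blood B density /uL
    organ_lysis: pd.DataFrame      # per organ: kills, baseline, shares
    evolution: pd.DataFrame        # survivor CD19 means over time
    regimen: DoseRegimen
    scenario_key: str

    @property
    def final_blood_b_per_ul(self) -> float:
        last_t = self.blood_b["time_h"].max()
        return float(self.blood_b.loc[self.blood_b["time_h"] == last_t,
                                      "blood_b_per_ul"].mean())

    @property
    def final_survivor_mean_cd19(self) -> float:
        last_t = self.evolution["time_h"].max()
        return float(self.evolution.loc[self.evolution["time_h"] == last_t,
                                        "survivor_mean_cd19"].mean())

    def lysis_shares(self) -> pd.Series:
        """Each organ's share (%) of all cells lysed, averaged over replicates."""
        g = self.organ_lysis.groupby("organ")[["kills"]].mean()
        total = g["kills"].sum()
        return 100.0 * g["kills"] / total if total > 0 else g["kills"] * 0.0

    def fractional_lysis(self) -> pd.Series:
        """Kills / baseline count per organ (%), averaged over replicates."""
        g = self.organ_lysis.groupby("organ")[["kills", "baseline"]].mean()
        return 100.0 * g["kills"] / g["baseline"].replace(0, np.nan)


def run_invivo(cfg: RunConfig, organs: OrganSystem | None = None,
               regimen: DoseRegimen | None = None,
               profile: PatientProfile | None = None) -> InVivoResult:
    """Hourly in vivo loop wrapping 60-s synapse rounds in every organ."""
    iv = cfg.invivo
    if iv is None:
        raise ValueError("run_invivo needs the invivo settings block")
    organs = organs or OrganSystem()
    regimen = regimen or load_regimen(iv.regimen)
    profile = profile or PatientProfile(
        baseline_blood_b_per_ul=iv.baseline_blood_b_per_ul,
        b_growth_per_day=iv.b_growth_per_day, t_to_b_ratio=iv.t_to_b_ratio,
        cd19_mean=iv.cd19_mean, cd3_mean=iv.cd3_mean)

    params = engine_params_from_config(cfg)
    params = replace(params, internalization_on=False, invariant_checks=False)
    params_frozen = replace(params, downreg_on=False)
    rounds_per_h = int(round(3600 / params.encounter.round_duration))
    n_hours = int(round(iv.duration_days * 24))
    dispersion = cfg.params.population.dispersion

    blood = organs["blood"]
    total_b = profile.baseline_blood_b_per_ul * 1e3 * blood.volume_ml / blood.b_fraction
    total_t = total_b * profile.t_to_b_ratio
    scale = iv.agent_cap / total_b

    blood_rows, organ_rows, evo_rows = [], [], []
    for rep in range(cfg.replicates):
        rngs = spawn_rngs(cfg.seed * 100003 + rep)
        states: dict[str, SimState] = {}
        baseline_counts: dict[str, int] = {}
        baseline_t: dict[str, int] = {}
        for organ in organs:
            n_b = int(round(total_b * organ.b_fraction * scale))
            n_t = int(round(total_t * organ.t_fraction * scale))
            st = _make_organ_state(organ, n_b, n_t, organ.volume_ml * scale,
                                   profile, dispersion,
                                   rngs["population"], rngs["contacts"])
            states[organ.name] = st
            baseline_counts[organ.name] = n_b
            if organ.forms_synapses:
                baseline_t[organ.name] = n_t
        ivs = InVivoState(organs=organs, scale=scale, states=states,
                          rng_traffic=rngs["trafficking"],
                          kill_records={n: [] for n in organs.names})

        def record(t_h: float) -> None:
            residual = ivs.total_alive_b() / scale
            blood_density_per_ml = residual * organs["blood"].b_fraction \
                / organs["blood"].volume_ml
            blood_rows.append({"replicate": rep, "time_h": t_h,
                               "blood_b_per_ul": blood_density_per_ml / 1e3})
            cd19 = [c.antigen_total for st in ivs.states.values()
                    for c in st.cells
                    if c.role == pop.ROLE_TARGET and c.state in _ALIVE]
            evo_rows.append({"replicate": rep, "time_h": t_h,
                             "survivor_mean_cd19":
                                 float(np.mean(cd19)) if cd19 else float("nan")})

        record(0.0)
        for hour in range(n_hours):
            plasma = regimen.plasma_ng_per_ml(hour, iv.clearance_l_per_h)
            p_hour = params if hour < 1 else params_frozen
            for organ in organs:
                if not organ.forms_synapses:
                    continue
                st = states[organ.name]
                conc = plasma * organ.bite_exposure
                reequilibrate(st, p_hour, conc, cfg.params.bite_mw_kda)
                recs = ivs.kill_records[organ.name]
                for _ in range(rounds_per_h):
                    _detach_due_entities(st, recs)
                    step_round(st, p_hour)
            if iv.trafficking_per_h > 0:
                traffic_b_cells(ivs, 1.0, iv.trafficking_per_h)
            b_cell_turnover(ivs, profile, 1.0)
            if profile.t_multiplier_points:
                update_t_cells(ivs, profile, baseline_t, float(hour + 1))
            ivs.clock_h = float(hour + 1)
            if (hour + 1) % 24 == 0 or hour == n_hours - 1:
                record(ivs.clock_h)

        for name in organs.names:
            organ_rows.append({"replicate": rep, "organ": name,
                               "kills": len(ivs.kill_records[name]),
                               "baseline": baseline_counts[name],
                               "residual": ivs.alive_b_count(name)})

    scenario_key = (f"B{profile.baseline_blood_b_per_ul}"
                    f"_g{profile.b_growth_per_day}"
                    f"_tb{profile.t_to_b_ratio}_cd19{profile.cd19_mean}"
                    f"_d{iv.duration_days}")
    return InVivoResult(blood_b=pd.DataFrame(blood_rows),
                        organ_lysis=pd.DataFrame(organ_rows),
                        evolution=pd.DataFrame(evo_rows),
                        regimen=regimen, scenario_key=scenario_key)


class RegimenComparisonError(ValueError):
    pass


def rank_regimens(results: list[InVivoResult], efficacy_rel_tol: float = 0.10,
                  evolution_rel_tol: float = 0.05) -> pd.DataFrame:
    """Rank regimens lexicographically: killing efficacy, then CD19
    evolution, then total dose.

    Efficacy = residual blood B density (lower wins beyond the relative
    tolerance); evolution = survivor-mean CD19 (higher wins — less antigen
    escape); ties at both tiers go to the lower total dose.
    """
    if len(results) < 2:
        raise RegimenComparisonError("need >=2 result bundles to rank")
    keys = {r.scenario_key for r in results}
    if len(keys) != 1:
        raise RegimenComparisonError(
            f"result bundles come from different scenarios: {sorted(keys)}")

    rows = [{"regimen": r.regimen.name,
             "final_blood_b_per_ul": r.final_blood_b_per_ul,
             "survivor_mean_cd19": r.final_survivor_mean_cd19,
             "total_dose_ug": r.regimen.total_dose_ug} for r in results]

    import functools

    def cmp(a, b):
        ea, eb = a["final_blood_b_per_ul"], b["final_blood_b_per_ul"]
        ref = max(ea, eb, 1e-300)
        if abs(ea - eb) / ref > efficacy_rel_tol:
            return -1 if ea < eb else 1
        ca, cb = a["survivor_mean_cd19"], b["survivor_mean_cd19"]
        refc = max(abs(ca), abs(cb), 1e-300)
        if not (math.isnan(ca) or math.isnan(cb)) \
                and abs(ca - cb) / refc > evolution_rel_tol:
            return -1 if ca > cb else 1
        if a["total_dose_ug"] != b["total_dose_ug"]:
            return -1 if a["total_dose_ug"] < b["total_dose_ug"] else 1
        return 0

    ranked = sorted(rows, key=functools.cmp_to_key(cmp))
    out = pd.DataFrame(ranked)
    out.insert(0, "rank", range(1, len(ranked) + 1))
    return out
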