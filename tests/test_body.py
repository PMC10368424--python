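"""In vivo model: compartments, trafficking, turnover, dosing, ranking."""

import math

import numpy as np
import pandas as pd
import pytest

from synapse_sim import (DoseRegimen, Organ, OrganSystem, PatientProfile,
                         RunConfig, b_cell_turnover, load_regimen,
                         partition_cells, rank_regimens, run_invivo,
                         traffic_b_cells)
from synapse_sim.body import (InVivoResult, InVivoState, OrganConfigError,
                              RegimenComparisonError, _make_organ_state)
from synapse_sim.config import InVivoSettings
import synapse_sim.population as pop


def _two_organ_system(split=0.5):
    return OrganSystem((
        Organ("blood", 5000.0, split, split, forms_synapses=False),
        Organ("lymph_nodes", 250.0, 1.0 - split, 1.0 - split),
    ))


def _state_with_b_cells(organs, per_organ_b, seed=0):
    rngs = np.random.default_rng(seed)
    profile = PatientProfile(baseline_blood_b_per_ul=200.0)
    states = {}
    for organ in organs:
        states[organ.name] = _make_organ_state(
            organ, per_organ_b.get(organ.name, 0), 0, 1e-4, profile, 0.4,
            np.random.default_rng(seed), np.random.default_rng(seed + 1))
    return InVivoState(organs=organs, scale=1e-7, states=states,
                       rng_traffic=rngs,
                       kill_records={o.name: [] for o in organs})


class TestOrganSystem:
    def test_default_repertoire_is_valid_and_blood_holds_two_percent(self):
        organs = OrganSystem()
        assert organs["blood"].b_fraction == 0.02
        counts = partition_cells(5e10, organs, "b")
        assert counts["blood"] == pytest.approx(1e9)
        assert sum(counts.values()) == pytest.approx(5e10, abs=1e-3)

    def test_single_organ_repertoire(self):
        organs = _two_organ_system(split=0.0)
        counts = partition_cells(1e6, organs, "b")
        assert counts["lymph_nodes"] == 1e6 and counts["blood"] == 0.0

    def test_fractions_must_sum_to_one(self):
        with pytest.raises(OrganConfigError, match="sum"):
            OrganSystem((
                Organ("blood", 5000.0, 0.5, 0.5, forms_synapses=False),
                Organ("spleen", 200.0, 0.4, 0.5),
            ))

    def test_blood_cannot_form_synapses(self):
        with pytest.raises(OrganConfigError, match="trafficking route"):
            OrganSystem((
                Organ("blood", 5000.0, 0.5, 0.5, forms_synapses=True),
                Organ("spleen", 200.0, 0.5, 0.5),
            ))


class TestTrafficking:
    def test_expected_release_fraction(self):
        """At 4.17%/h, an organ with n free B cells releases ~0.0417*n."""
        organs = _two_organ_system(split=0.5)
        n0 = 4000
        state = _state_with_b_cells(organs, {"lymph_nodes": n0}, seed=1)
        traffic_b_cells(state, 1.0, rate_per_h=0.0417)
        from synapse_sim.body import STATE_DEPARTED
        released = sum(1 for c in state.states["lymph_nodes"].cells
                       if c.state == STATE_DEPARTED)
        se = math.sqrt(n0 * 0.0417 * (1 - 0.0417))
        assert abs(released - 0.0417 * n0) < 3 * se

    def test_total_count_conserved_exactly_over_many_steps(self):
        organs = _two_organ_system(split=0.5)
        state = _state_with_b_cells(organs, {"lymph_nodes": 500, "blood": 500},
                                    seed=2)
        total0 = state.total_alive_b()
        for _ in range(100):
            traffic_b_cells(state, 1.0)
            assert state.total_alive_b() == total0

    def test_symmetric_start_is_stationary_in_expectation(self):
        organs = _two_organ_system(split=0.5)
        drifts = []
        for seed in range(8):
            state = _state_with_b_cells(organs,
                                        {"lymph_nodes": 500, "blood": 500},
                                        seed=seed)
            for _ in range(20):
                traffic_b_cells(state, 1.0)
            drifts.append(state.alive_b_count("blood") - 500)
        assert abs(np.mean(drifts)) < 3 * np.std(drifts) / math.sqrt(len(drifts)) + 5


class TestTurnover:
    def test_zero_growth_is_identity(self):
        organs = _two_organ_system()
        state = _state_with_b_cells(organs, {"lymph_nodes": 300})
        profile = PatientProfile(200.0, b_growth_per_day=0.0)
        b_cell_turnover(state, profile, 1.0)
        assert state.alive_b_count("lymph_nodes") == 300

    def test_high_growth_rate_compounds_to_closed_form(self):
        """0.071/day over 10 days with no killing: count x e^0.71."""
        organs = _two_organ_system()
        state = _state_with_b_cells(organs, {"lymph_nodes": 3000}, seed=4)
        profile = PatientProfile(200.0, b_growth_per_day=0.071)
        for _ in range(240):
            b_cell_turnover(state, profile, 1.0)
        expected = 3000 * math.exp(0.71)
        assert state.alive_b_count("lymph_nodes") == pytest.approx(expected,
                                                                   rel=0.05)

    def test_growth_preserves_mean_cd19(self):
        organs = _two_organ_system()
        state = _state_with_b_cells(organs, {"lymph_nodes": 3000}, seed=5)
        cells = state.states["lymph_nodes"].cells
        mean0 = np.mean([c.antigen_total for c in cells])
        profile = PatientProfile(200.0, b_growth_per_day=0.2)
        for _ in range(48):
            b_cell_turnover(state, profile, 1.0)
        mean1 = np.mean([c.antigen_total for c in cells
                         if c.state != pop.STATE_LYSED])
        assert mean1 == pytest.approx(mean0, rel=0.02)


class TestTCellUpdate:
    def test_expansion_multiplier_scales_effector_pool(self):
        from synapse_sim import update_t_cells
        organs = _two_organ_system()
        state = _state_with_b_cells(organs, {}, seed=6)
        st = state.states["lymph_nodes"]
        profile = PatientProfile(200.0,
                                 t_multiplier_points=((0.0, 1.0), (48.0, 3.0)))
        for _ in range(200):
            cell = pop.CellAgent(id=len(st.cells), role=pop.ROLE_EFFECTOR,
                                 antigen_total=1e5, organ="lymph_nodes")
            st.cells.append(cell)
            st.free_effectors.add(cell.id)
        update_t_cells(state, profile, {"lymph_nodes": 200}, time_h=48.0)
        alive = sum(1 for c in st.cells
                    if c.role == pop.ROLE_EFFECTOR and c.state == pop.STATE_FREE)
        assert alive == 600
        update_t_cells(state, profile, {"lymph_nodes": 200}, time_h=0.0)
        alive = sum(1 for c in st.cells
                    if c.role == pop.ROLE_EFFECTOR and c.state == pop.STATE_FREE)
        assert alive == 200


class TestDoseRegimen:
    def test_presets_load_and_plasma_conversion(self):
        reg = load_regimen("scheme1_high")
        assert reg.scheme == 1 and reg.dose_level == "high"
        assert reg.infusion_rate_ug_per_day(0.0) == 9.0
        assert reg.infusion_rate_ug_per_day(10 * 24.0) == 28.0
        # 28 ug/day / (24 h * 2 L/h) = 0.5833 ng/mL steady state
        assert reg.plasma_ng_per_ml(10 * 24.0, 2.0) == pytest.approx(28 / 48)

    def test_scheme2_delivers_less_total_dose(self):
        assert load_regimen("scheme2_high").total_dose_ug < \
            load_regimen("scheme1_high").total_dose_ug

    def test_unknown_preset_named_in_error(self):
        with pytest.raises(KeyError, match="nonexistent"):
            load_regimen("nonexistent")

    def test_negative_dose_rejected(self):
        with pytest.raises(ValueError):
            DoseRegimen("bad", 1, "high", (-1.0,))


class TestRunInvivo:
    def test_zero_dose_grows_at_profile_rate_with_no_lysis(self):
        cfg = RunConfig(model="invivo", replicates=1, seed=3,
                        invivo=InVivoSettings(duration_days=2.0,
                                              b_growth_per_day=0.071,
                                              agent_cap=1000))
        regimen = DoseRegimen("none", 1, "zero", (0.0,))
        res = run_invivo(cfg, regimen=regimen)
        assert res.organ_lysis["kills"].sum() == 0
        expected = 200.0 * math.exp(0.071 * 2)
        assert res.final_blood_b_per_ul == pytest.approx(expected, rel=0.05)

    def test_treatment_depletes_blood_b(self, invivo_result_small):
        res = invivo_result_small
        assert res.final_blood_b_per_ul < 200.0
        assert res.organ_lysis["kills"].sum() > 0

    def test_bone_marrow_is_a_sanctuary_site(self, invivo_result_small):
        """Fractional lysis in the bone marrow is below the lymph nodes in
        every seeded replicate — the antigen-escape reservoir."""
        df = invivo_result_small.organ_lysis.set_index(["replicate", "organ"])
        for rep in df.index.get_level_values(0).unique():
            bm = df.loc[(rep, "bone_marrow")]
            ln = df.loc[(rep, "lymph_nodes")]
            assert bm["kills"] / bm["baseline"] < ln["kills"] / ln["baseline"]

    def test_systemic_survivor_cd19_declines_under_treatment(self, invivo_result_small):
        evo = invivo_result_small.evolution.groupby("time_h")[
            "survivor_mean_cd19"].mean()
        assert evo.iloc[-1] < evo.iloc[0]


def _fake_result(name, final_b, cd19, total_dose, scenario="s"):
    blood = pd.DataFrame({"replicate": [0, 0], "time_h": [0.0, 24.0],
                          "blood_b_per_ul": [200.0, final_b]})
    evo = pd.DataFrame({"replicate": [0, 0], "time_h": [0.0, 24.0],
                        "survivor_mean_cd19": [3e4, cd19]})
    organ = pd.DataFrame({"replicate": [0], "organ": ["lymph_nodes"],
                          "kills": [1], "baseline": [10], "residual": [9]})
    reg = DoseRegimen(name, 1, "x", (total_dose / 7.0,))
    return InVivoResult(blood_b=blood, organ_lysis=organ, evolution=evo,
                        regimen=reg, scenario_key=scenario)


class TestRankRegimens:
    def test_tie_broken_by_lower_total_dose(self):
        a = _fake_result("small_dose", 10.0, 2e4, 70.0)
        b = _fake_result("large_dose", 10.0, 2e4, 140.0)
        table = rank_regimens([b, a])
        assert table.iloc[0]["regimen"] == "small_dose"

    def test_stronger_killing_wins_regardless_of_dose(self):
        a = _fake_result("kills_more", 1.0, 1.5e4, 500.0)
        b = _fake_result("kills_less", 50.0, 2.9e4, 10.0)
        table = rank_regimens([b, a])
        assert table.iloc[0]["regimen"] == "kills_more"

    def test_equal_efficacy_less_antigen_escape_wins(self):
        a = _fake_result("less_escape", 10.0, 2.8e4, 300.0)
        b = _fake_result("more_escape", 10.0, 1.2e4, 100.0)
        table = rank_regimens([a, b])
        assert table.iloc[0]["regimen"] == "less_escape"

    def test_mismatched_scenarios_rejected(self):
        a = _fake_result("a", 10.0, 2e4, 70.0, scenario="s1")
        b = _fake_result("b", 10.0, 2e4, 70.0, scenario="s2")
        with pytest.raises(RegimenComparisonError):
            rank_regimens([a, b])
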