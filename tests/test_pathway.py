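"""Pathway modules, grafting, interventions, scenario comparison."""

import pytest
from hypothesis import given, settings, strategies as st

from fseof.core import Metabolite, MetabolicModel, ModelError, Reaction
from fseof.lp import FixedConstraint, maximize_flux
from fseof.pathway import (
    SPINOSYN_A_DEMAND,
    InterventionSpec,
    MappingError,
    NCM_CURRENCY_FORMULAS,
    PathwayModule,
    apply_intervention,
    build_ncm_module,
    build_spinosad_module,
    compare_scenarios,
    graft_module,
    module_element_balance,
    module_species_present,
)
from fseof.toys import ToySpec, make_branched_toy, make_host_toy

TOL = 1e-6


@pytest.fixture
def grafted(host):
    return graft_module(host, build_spinosad_module())


class TestModuleBuilders:
    def test_branch_granularity_has_four_rhamnose_steps(self):
        mod = build_spinosad_module("branch")
        rham = [r.id for r in mod.reactions if r.id.startswith("SPN_RHAM_")]
        assert len(rham) == 4

    def test_lumped_granularity_has_single_rhamnose_step(self):
        mod = build_spinosad_module("lumped")
        rham = [r.id for r in mod.reactions if r.id.startswith("SPN_RHAM")]
        assert rham == ["SPN_RHAM_LUMP"]

    def test_unknown_granularity_raises(self):
        with pytest.raises(ModelError):
            build_spinosad_module("atomic")

    def test_module_reactions_carry_gene_tags(self):
        mod = build_spinosad_module()
        tagged = [r for r in mod.reactions if r.gene_rule.strip()]
        assert len(tagged) >= 6  # rhamnose branch + forosamine + PKS steps

    def test_spinosad_blend_demand_closed_by_default(self):
        mod = build_spinosad_module()
        blend = next(r for r in mod.reactions if r.id == "SPN_DM_spinosad")
        assert blend.upper_bound == 0.0

    def test_currency_species_disjoint_from_new_metabolites(self):
        for mod in (build_spinosad_module(), build_ncm_module()):
            assert not set(mod.currency_metabolites()) & set(mod.new_metabolite_ids)


class TestNCMStructure:
    """The NADPH-conserving malonyl-CoA route must fix carbon (no CO2
    release), spend no ATP, and conserve carbon in every step."""

    def test_carbon_conserved_in_every_reaction(self):
        balance = module_element_balance(
            build_ncm_module(), NCM_CURRENCY_FORMULAS, element="C"
        )
        assert balance and all(abs(v) <= TOL for v in balance.values())

    def test_no_co2_or_bicarbonate_species(self):
        assert not module_species_present(
            build_ncm_module(), ["co2", "hco3", "co3", "co2_c", "hco3_c"]
        )

    def test_no_atp_involvement(self):
        assert not module_species_present(
            build_ncm_module(), ["atp", "adp", "amp", "atp_c", "adp_c"]
        )

    def test_route_starts_from_pyruvate(self):
        assert module_species_present(build_ncm_module(), ["pyr"])

    def test_missing_formula_is_loud(self):
        incomplete = {k: v for k, v in NCM_CURRENCY_FORMULAS.items() if k != "coa"}
        with pytest.raises(ModelError, match="coa"):
            module_element_balance(build_ncm_module(), incomplete)


class TestGraft:
    def test_host_reactions_untouched(self, host, grafted):
        for r in host.reactions:
            g = grafted.reaction(r.id)
            assert g.stoichiometry == r.stoichiometry
            assert (g.lower_bound, g.upper_bound) == (r.lower_bound, r.upper_bound)

    def test_growth_preserved_exactly(self, host, grafted):
        mu_host = maximize_flux(host, host.biomass_reaction_id).objective_value
        mu_graft = maximize_flux(grafted, grafted.biomass_reaction_id).objective_value
        assert mu_graft == pytest.approx(mu_host, abs=TOL)

    def test_spinosyn_a_producible_on_host(self, grafted):
        sol = maximize_flux(grafted, SPINOSYN_A_DEMAND)
        assert sol.ok and sol.objective_value > 0.01

    def test_all_three_branches_required(self, grafted):
        """Rhamnose, forosamine and the PKS aglycone are each essential."""
        for rid in ("SPN_RHAM_gtt", "SPN_FORO_SYN", "SPN_AGL_SYN_A"):
            ko = apply_intervention(grafted, InterventionSpec("knockout", (rid,)))
            assert maximize_flux(ko, SPINOSYN_A_DEMAND).objective_value == pytest.approx(
                0.0, abs=TOL
            )

    def test_unresolved_currency_raises_listing_orphans(self, t1):
        with pytest.raises(MappingError, match="accoa"):
            graft_module(t1, build_spinosad_module())

    def test_explicit_mapping_renames_currency(self):
        currency = ["pyruvate_c", "coa_c", "malcoa_c", "nadp_c", "nadph_c"]
        mets = [Metabolite(m) for m in currency]
        rxns = [Reaction(f"EX_{m}", {m: 1.0}, -10, 10) for m in currency]
        mini = MetabolicModel(mets, rxns, biomass_reaction_id="EX_pyruvate_c")
        mapping = {"pyr": "pyruvate_c", "coa": "coa_c", "malcoa": "malcoa_c",
                   "nadp": "nadp_c", "nadph": "nadph_c"}
        # without mapping: orphans; with mapping: grafts cleanly
        with pytest.raises(MappingError):
            graft_module(mini, build_ncm_module())
        g = graft_module(mini, build_ncm_module(), mapping)
        assert "pyruvate_c" in g.reaction("NCM_BauA").stoichiometry

    def test_reaction_collision_rejected(self, host, grafted):
        with pytest.raises(ModelError, match="collides"):
            graft_module(grafted, build_spinosad_module())

    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_graft_never_reduces_any_host_maximum(self, seed):
        """Adding reactions only enlarges the feasible region, so every
        host flux maximum is weakly monotone under grafting."""
        model, _ = make_branched_toy(ToySpec(seed=seed))
        mod = PathwayModule(
            "probe",
            [Reaction("PROBE_r", {"accoa": -1.0, "PROBE_x": 1.0}, 0, 5)],
            [Metabolite("PROBE_x")],
        )
        if not model.has_metabolite("accoa"):
            return
        g = graft_module(model, mod)
        for rid in ("R_bio", "EX_p"):
            before = maximize_flux(model, rid).objective_value
            after = maximize_flux(g, rid).objective_value
            assert after >= before - 1e-6


class TestInterventions:
    def test_amplify_scales_both_bounds(self, host):
        out = apply_intervention(
            host, InterventionSpec("amplify", ("EX_glc",), factor=2.0)
        )
        r = out.reaction("EX_glc")
        assert (r.lower_bound, r.upper_bound) == (0.0, 20.0)

    def test_knockout_zeroes_bounds(self, host):
        out = apply_intervention(host, InterventionSpec("knockout", ("PDH",)))
        r = out.reaction("PDH")
        assert r.lower_bound == r.upper_bound == 0.0

    def test_enable_degradation_opens_closed_reaction(self, host):
        assert host.reaction("TAG_DEG").upper_bound == 0.0
        out = apply_intervention(host, InterventionSpec("enable_degradation", ("TAG_DEG",)))
        assert out.reaction("TAG_DEG").upper_bound >= 1000

    def test_original_model_never_mutated(self, host):
        apply_intervention(host, InterventionSpec("knockout", ("PDH",)))
        assert host.reaction("PDH").upper_bound > 0

    def test_unknown_kind_and_bad_factor_rejected(self):
        with pytest.raises(ModelError):
            InterventionSpec("overexpress", ("r",))
        with pytest.raises(ModelError):
            InterventionSpec("amplify", ("r",), factor=0.0)

    def test_unknown_target_is_key_error(self, host):
        with pytest.raises(KeyError):
            apply_intervention(host, InterventionSpec("knockout", ("nope",)))

    @settings(deadline=None, max_examples=8, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_knockout_never_increases_product(self, seed):
        """Zeroing bounds shrinks the feasible region, so the product
        maximum can only fall — checked for every reaction of a toy."""
        model, _ = make_branched_toy(ToySpec(seed=seed))
        base = maximize_flux(model, "EX_p").objective_value
        for r in model.reactions:
            if r.id in ("EX_p",):
                continue
            ko = apply_intervention(model, InterventionSpec("knockout", (r.id,)))
            assert maximize_flux(ko, "EX_p").objective_value <= base + 1e-6


class TestScenarios:
    def test_base_prepended_and_delta_zero(self, grafted):
        res = compare_scenarios(
            grafted,
            [("ncm", [InterventionSpec("add_module", module=build_ncm_module())])],
            SPINOSYN_A_DEMAND,
            "EX_glc",
        )
        assert [r.scenario for r in res] == ["base", "ncm"]
        assert res[0].delta_vs_base == pytest.approx(0.0)

    def test_ncm_module_raises_spinosyn_flux(self, grafted):
        res = compare_scenarios(
            grafted,
            [("ncm", [InterventionSpec("add_module", module=build_ncm_module())])],
            SPINOSYN_A_DEMAND,
            "EX_glc",
        )
        assert res[1].delta_vs_base > 0.05
        assert res[1].yield_per_substrate > res[0].yield_per_substrate

    def test_knockout_of_required_branch_zeroes_product(self, grafted):
        res = compare_scenarios(
            grafted,
            [("no_foro", [InterventionSpec("knockout", ("SPN_FORO_SYN",))])],
            SPINOSYN_A_DEMAND,
            "EX_glc",
        )
        assert res[1].max_target_flux == pytest.approx(0.0, abs=TOL)
        assert res[1].delta_vs_base < 0

    def test_broken_scenario_flagged_not_dropped(self, grafted):
        res = compare_scenarios(
            grafted,
            [("bad", [InterventionSpec("knockout", ("missing_rxn",))])],
            SPINOSYN_A_DEMAND,
            "EX_glc",
        )
        assert len(res) == 2 and res[1].status.startswith("error")

    def test_growth_floor_enforced(self, grafted):
        mu = maximize_flux(grafted, grafted.biomass_reaction_id).objective_value
        res = compare_scenarios(grafted, [], SPINOSYN_A_DEMAND, "EX_glc",
                                growth_floor_fraction=0.5)
        # product attainable at the floor is below the unconstrained maximum
        free = maximize_flux(grafted, SPINOSYN_A_DEMAND).objective_value
        assert res[0].max_target_flux <= free + TOL
        floored = grafted.copy()
        floored.reaction(grafted.biomass_reaction_id).lower_bound = 0.5 * mu
        direct = maximize_flux(floored, SPINOSYN_A_DEMAND).objective_value
        assert res[0].max_target_flux == pytest.approx(direct, abs=TOL)

    def test_synergy_witness(self):
        """Two edits that are individually useless but jointly productive:
        amplifying the conversion step alone leaves supply limiting, and a
        second supply route alone leaves conversion limiting."""
        mets = [Metabolite(x) for x in ("s", "m", "p")]
        rxns = [
            Reaction("EX_s", {"s": 1.0}, 0, 10),
            Reaction("R_supply", {"s": -1.0, "m": 1.0}, 0, 5),
            Reaction("R_mod", {"m": -1.0, "p": 1.0}, 0, 5),
            Reaction("EX_p", {"p": -1.0}, 0, 1000),
            Reaction("R_bio", {"s": -1.0}, 0, 1000),
        ]
        model = MetabolicModel(mets, rxns, biomass_reaction_id="R_bio")
        second_route = PathwayModule(
            "supply2", [Reaction("NCM2", {"s": -1.0, "m": 1.0}, 0, 5)], []
        )
        amp = InterventionSpec("amplify", ("R_mod",), factor=2.0)
        add = InterventionSpec("add_module", module=second_route)
        res = {
            r.scenario: r
            for r in compare_scenarios(
                model,
                [("amp", [amp]), ("add", [add]), ("both", [amp, add])],
                "EX_p",
                "EX_s",
                growth_floor_fraction=0.0,
            )
        }
        assert res["amp"].delta_vs_base == pytest.approx(0.0, abs=TOL)
        assert res["add"].delta_vs_base == pytest.approx(0.0, abs=TOL)
        assert res["both"].delta_vs_base == pytest.approx(5.0, abs=TOL)


class TestScanOnGraftedHost:
    def test_fseof_flags_precursor_supply_up_and_competition_down(self, grafted):
        from fseof.scan import ScanConfig, classify_targets, run_scan, score_reactions

        cfg = ScanConfig(grafted.biomass_reaction_id, SPINOSYN_A_DEMAND)
        table = classify_targets(
            score_reactions(run_scan(grafted, cfg)), grafted, cfg
        )
        up, down = set(table.up_ids()), set(table.down_ids())
        # the silent biosynthetic module itself must surface as ACTIVATED up
        assert {"SPN_AGL_SYN_A", "SPN_FORO_SYN", "SPN_RHAM_gtt"} <= up
        # malonyl-CoA supply amplified, a flux-diverting branch attenuated
        assert "ACC" in up
        assert len(down) > 0 and down.isdisjoint(up)
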