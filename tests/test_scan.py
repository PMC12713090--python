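"""FSEOF scan, scoring, classification, gene folding, export."""

import numpy as np
import pytest

from fseof.core import Metabolite, MetabolicModel, Reaction
from fseof.scan import (
    ReactionScore,
    ScanConfig,
    ScanError,
    classify_targets,
    export_target_table,
    run_control,
    run_scan,
    score_genes,
    score_reactions,
)

TOL = 1e-6


class TestConfig:
    def test_default_fraction_grid(self):
        cfg = ScanConfig("R_bio", "EX_p")
        assert cfg.fractions == (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)

    @pytest.mark.parametrize(
        "fractions", [(0.5, 0.2), (0.0, 0.5), (0.5, 1.0), ()]
    )
    def test_bad_fraction_grids_rejected(self, fractions):
        with pytest.raises(ScanError):
            ScanConfig("R_bio", "EX_p", fractions=fractions)


class TestControl:
    def test_t1_control_is_pure_growth(self, t1, t1_config):
        ctrl = run_control(t1, t1_config)
        assert ctrl.objective_value == pytest.approx(10.0, abs=TOL)
        assert ctrl.fluxes["EX_p"] == pytest.approx(0.0, abs=TOL)

    def test_product_only_model_grows_nothing(self):
        m = MetabolicModel(
            [Metabolite("A"), Metabolite("P")],
            [
                Reaction("up", {"A": 1.0}, 0, 10),
                Reaction("mk", {"A": -1.0, "P": 1.0}, 0, 1000),
                Reaction("EX_p", {"P": -1.0}, 0, 1000),
                Reaction("bio", {"A": -1.0}, 0, 0),  # growth impossible
            ],
            biomass_reaction_id="bio",
        )
        ctrl = run_control(m, ScanConfig("bio", "EX_p"))
        assert ctrl.objective_value == pytest.approx(0.0, abs=TOL)
        assert all(abs(v) <= TOL for v in ctrl.fluxes.values())

    def test_infeasible_model_propagates_status(self, t1, t1_config):
        m = t1.copy()
        # uptake forced above the combined sink capacity -> no feasible flux
        m.reaction("EX_glc").lower_bound = 20.0
        m.reaction("EX_glc").upper_bound = 30.0
        m.reaction("R_bio").upper_bound = 5.0
        m.reaction("R_p").upper_bound = 0.0
        assert not run_control(m, t1_config).ok


class TestRunScan:
    def test_t1_level_structure(self, t1, t1_config):
        scan = run_scan(t1, t1_config)
        assert scan.max_biomass == pytest.approx(10.0, abs=TOL)
        for f in t1_config.fractions:
            assert scan.target_max_per_level[f] == pytest.approx(10 * (1 - f), abs=TOL)
            lvl = scan.levels[f]
            assert lvl.fluxes["EX_glc"] == pytest.approx(10.0, abs=TOL)
            assert lvl.fluxes["R_bio"] == pytest.approx(10 * f, abs=TOL)

    def test_single_fraction_scan(self, t1):
        cfg = ScanConfig("R_bio", "EX_p", fractions=(0.5,))
        scan = run_scan(t1, cfg)
        assert set(scan.levels) == {0.5}
        assert scan.levels[0.5].fluxes["R_bio"] == pytest.approx(5.0, abs=TOL)

    def test_unreachable_target_warns(self, t1):
        m = t1.copy()
        m.reaction("R_p").upper_bound = 0.0
        scan = run_scan(m, ScanConfig("R_bio", "EX_p"))
        assert any("unreachable" in w for w in scan.warnings)


class TestScores:
    def test_t1_closed_forms(self, t1, t1_config):
        scores = {s.reaction_id: s for s in score_reactions(run_scan(t1, t1_config))}
        assert scores["EX_glc"].score == pytest.approx(1.0, abs=TOL)
        assert scores["R_bio"].score == pytest.approx(0.5, abs=TOL)  # mean(fractions)
        assert scores["R_p"].activated
        assert scores["R_p"].production_flux_mean == pytest.approx(5.0, abs=TOL)

    def test_biomass_score_is_mean_fraction_for_any_model(self, t2_factory):
        """The biomass level flux is f×max by construction, so its raw score
        equals mean(fractions) — a closed form independent of the model."""
        for seed in (0, 5):
            model, _ = t2_factory(seed=seed)
            cfg = ScanConfig("R_bio", "EX_p")
            scores = {s.reaction_id: s for s in score_reactions(run_scan(model, cfg))}
            assert scores["R_bio"].score == pytest.approx(
                np.mean(cfg.fractions), abs=TOL
            )

    def test_constant_flux_reaction_scores_exactly_one(self, t2_factory):
        model, _ = t2_factory(seed=2)
        cfg = ScanConfig("R_bio", "EX_p")
        scores = score_reactions(run_scan(model, cfg))
        for s in scores:
            if s.score is None:
                continue
            lvls = list(s.level_fluxes.values())
            if abs(s.control_flux) > TOL and all(
                abs(v - s.control_flux) <= 1e-9 for v in lvls
            ):
                assert s.score == pytest.approx(1.0, abs=1e-9)

    def test_scale_invariance_of_scores(self, t2_factory):
        """Uniformly rescaling all bounds rescales fluxes but not scores."""
        model, _ = t2_factory(seed=4)
        scaled = model.copy()
        for r in scaled.reactions:
            r.lower_bound *= 3.0
            r.upper_bound *= 3.0
        cfg = ScanConfig("R_bio", "EX_p")
        a = {s.reaction_id: s for s in score_reactions(run_scan(model, cfg))}
        b = {s.reaction_id: s for s in score_reactions(run_scan(scaled, cfg))}
        for rid in a:
            assert a[rid].activated == b[rid].activated
            if a[rid].score is not None and b[rid].score is not None:
                assert a[rid].score == pytest.approx(b[rid].score, abs=1e-6)

    def test_empty_scan_is_contract_error(self, t1, t1_config):
        scan = run_scan(t1, t1_config)
        scan.levels = {f: type(scan.control)({}, float("nan"), "infeasible")
                       for f in t1_config.fractions}
        with pytest.raises(ScanError):
            score_reactions(scan)


def _score(rid, value=None, activated=False, mean=1.0, ctrl=1.0, consistent=True,
           reason=""):
    return ReactionScore(
        reaction_id=rid, score=value, activated=activated,
        production_flux_mean=mean, control_flux=ctrl,
        direction_consistent=consistent, reason=reason,
    )


@pytest.fixture
def four_reaction_model():
    mets = [Metabolite(x) for x in "ABCDE"]
    rxns = [
        Reaction("r1", {"A": -1, "B": 1}, 0, 10, gene_rule="g1"),
        Reaction("r2", {"B": -1, "C": 1}, 0, 10, gene_rule="g1 and g2"),
        Reaction("r3", {"C": -1, "D": 1}, 0, 10, gene_rule="g3"),
        Reaction("r4", {"D": -1, "E": 1}, 0, 10, gene_rule=""),
        Reaction("bio", {"E": -1}, 0, 10),
        Reaction("tgt", {"A": 1}, 0, 10),
    ]
    return MetabolicModel(mets, rxns, biomass_reaction_id="bio")


class TestClassify:
    def test_partition_with_zero_dead_band(self, four_reaction_model):
        cfg = ScanConfig("bio", "tgt", dead_band=0.0)
        scores = [
            _score("r1", 1.5), _score("r2", 1.0), _score("r3", 0.4),
            _score("r4", None, activated=True, ctrl=0.0),
        ]
        table = classify_targets(scores, four_reaction_model, cfg)
        assert table.up_ids() == ["r4", "r1"]  # ACTIVATED ranks first
        assert table.down_ids() == ["r3"]
        assert ("r2", "neutral score") in table.excluded

    def test_dead_band_suppresses_near_neutral(self, four_reaction_model):
        cfg = ScanConfig("bio", "tgt", dead_band=0.05)
        scores = [_score("r1", 1.04), _score("r2", 0.96)]
        table = classify_targets(scores, four_reaction_model, cfg)
        assert table.up_ids() == [] and table.down_ids() == []

    def test_biomass_target_and_exchanges_never_listed(self, t1, t1_config):
        scan = run_scan(t1, t1_config)
        table = classify_targets(score_reactions(scan), t1, t1_config)
        listed = set(table.up_ids()) | set(table.down_ids())
        assert "R_bio" not in listed and "EX_p" not in listed
        assert "EX_glc" not in listed

    def test_all_inactive_yields_empty_table(self, four_reaction_model):
        cfg = ScanConfig("bio", "tgt")
        scores = [_score(r, 0.0, mean=0.0, ctrl=0.0, reason="inactive")
                  for r in ("r1", "r2", "r3")]
        table = classify_targets(scores, four_reaction_model, cfg)
        assert table.up_ids() == [] and table.down_ids() == []

    def test_gene_only_filter_drops_gene_less(self, four_reaction_model):
        cfg = ScanConfig("bio", "tgt", gene_only=True)
        scores = [_score("r3", 1.5), _score("r4", 1.5)]
        table = classify_targets(scores, four_reaction_model, cfg)
        assert table.up_ids() == ["r3"]
        assert ("r4", "no gene association") in table.excluded

    def test_classification_invariant_to_score_ordering(self, four_reaction_model):
        cfg = ScanConfig("bio", "tgt")
        scores = [_score("r1", 1.5), _score("r2", 2.5), _score("r3", 0.2)]
        fwd = classify_targets(scores, four_reaction_model, cfg)
        rev = classify_targets(list(reversed(scores)), four_reaction_model, cfg)
        assert fwd.up_ids() == rev.up_ids() and fwd.down_ids() == rev.down_ids()

    def test_planted_targets_recovered_on_branched_toy(self, t2_factory):
        model, truth = t2_factory(seed=1)
        cfg = ScanConfig("R_bio", "EX_p")
        table = classify_targets(score_reactions(run_scan(model, cfg)), model, cfg)
        assert truth.expected_up <= set(table.up_ids())
        assert truth.expected_down <= set(table.down_ids())


class TestGeneScores:
    def test_up_takes_max_and_lists_support(self, four_reaction_model):
        scores = [_score("r1", 1.5), _score("r2", 0.9)]
        out = {g.gene_id: g for g in score_genes(four_reaction_model, scores, "up")}
        assert out["g1"].score == pytest.approx(1.5)
        assert set(out["g1"].supporting_reactions) == {"r1", "r2"}

    def test_and_rule_scores_both_genes(self, four_reaction_model):
        scores = [_score("r2", 2.0)]
        out = {g.gene_id: g for g in score_genes(four_reaction_model, scores, "up")}
        assert out["g1"].score == out["g2"].score == pytest.approx(2.0)

    def test_activated_dominates_numeric(self, four_reaction_model):
        scores = [_score("r1", 5.0), _score("r2", None, activated=True, ctrl=0.0)]
        out = {g.gene_id: g for g in score_genes(four_reaction_model, scores, "up")}
        assert out["g1"].activated

    def test_down_takes_min(self, four_reaction_model):
        scores = [_score("r1", 0.4), _score("r2", 0.8)]
        out = {g.gene_id: g for g in score_genes(four_reaction_model, scores, "down")}
        assert out["g1"].score == pytest.approx(0.4)

    def test_gene_in_no_rule_omitted(self, four_reaction_model):
        out = score_genes(four_reaction_model, [_score("r4", 2.0)], "up")
        assert out == []


class TestExport:
    def test_t1_table_rows(self, t1, t1_config, tmp_path):
        scan = run_scan(t1, t1_config)
        table = classify_targets(score_reactions(scan), t1, t1_config)
        out = tmp_path / "targets.tsv"
        export_target_table(table, out, fractions=t1_config.fractions)
        lines = out.read_text().splitlines()
        # R_p is the only listable reaction: ACTIVATED up; biomass, target
        # and exchanges are excluded by rule
        assert len(lines) == 2
        assert lines[1].split("\t")[1] == "R_p"
        assert "ACTIVATED" in lines[1]

    def test_empty_table_header_only(self, tmp_path):
        from fseof.scan import TargetTable

        out = tmp_path / "t.tsv"
        export_target_table(TargetTable([], [], []), out)
        assert len(out.read_text().splitlines()) == 1

    def test_re_export_byte_identical(self, t1, t1_config, tmp_path):
        scan = run_scan(t1, t1_config)
        table = classify_targets(score_reactions(scan), t1, t1_config)
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        export_target_table(table, a, fractions=t1_config.fractions)
        export_target_table(table, b, fractions=t1_config.fractions)
        assert a.read_bytes() == b.read_bytes()
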