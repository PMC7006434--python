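import json

import numpy as np
import pytest

from astroflux import synth
from astroflux.constraints import apply_medium
from astroflux.errors import ScenarioError, UndefinedIC50Error
from astroflux.fba import canonical_fluxes, knockout
from astroflux.scenarios import (
    FoldChangeRecord,
    PipelineConfig,
    RobustnessCurve,
    ScenarioSpec,
    build_scenario,
    classify_knockouts,
    fold_changes,
    ic50,
    inflammatory_spec,
    mean_ic50,
    robustness_curve,
    run_pipeline,
    subsystem_activity,
    treatment_spec,
)

CONTROL = synth.PALMITATE_EXCHANGE
OBJECTIVE = "EX_gln_L(e)"
LEX = [synth.BIOMASS_ID, OBJECTIVE]


@pytest.fixture(scope="module")
def ic50_mean(healthy_model):
    mean, _, _, _ = mean_ic50(healthy_model, CONTROL, synth.TOY_OBJECTIVES, n=201)
    return mean


@pytest.fixture(scope="module")
def inflamed_model(healthy_model, ic50_mean):
    return build_scenario(healthy_model, inflammatory_spec(CONTROL, ic50_mean))


@pytest.fixture(scope="module")
def treated_model(healthy_model, ic50_mean):
    return build_scenario(healthy_model, treatment_spec(CONTROL, ic50_mean, 0.5))


class TestBuildScenario:
    def test_healthy_keeps_free_palmitate_uptake(self, healthy_model, toy_params):
        lb, ub = healthy_model.reaction(CONTROL).bounds
        assert lb == -toy_params.palmitate_cap and ub > 0

    def test_inflammatory_pins_palmitate(self, inflamed_model, ic50_mean):
        assert inflamed_model.reaction(CONTROL).bounds == (-ic50_mean, -ic50_mean)

    def test_treatment_reaction_count(self, inflamed_model, treated_model):
        # ten tibolone reactions plus the five-reaction estradiol stub
        assert treated_model.n_reactions == inflamed_model.n_reactions + 10 + 5

    def test_missing_control_is_error(self, healthy_model):
        spec = ScenarioSpec(name="bad", forced_bounds={"EX_ghost(e)": (0.0, 0.0)})
        with pytest.raises(ScenarioError):
            build_scenario(healthy_model, spec)


class TestRobustnessCurve:
    def test_linear_decline_matches_analytic(self, healthy_model, toy_params):
        u0 = toy_params.inhibition_u0
        curve = robustness_curve(healthy_model, CONTROL, "EX_lac_L(e)", n=101)
        z0 = curve.values[0]
        for u, z, ok in zip(curve.grid, curve.values, curve.feasible):
            if ok:
                assert z == pytest.approx(z0 * (1 - u / u0), abs=1e-6)

    def test_control_with_no_effect_gives_constant_curve(self, chain_model):
        curve = robustness_curve(chain_model, "E_in", "E_out", n=20, u_lo=0.0, u_hi=2.0)
        # E_in is itself the feed: forcing uptake u caps the chain at u
        assert curve.values == pytest.approx(curve.grid, abs=1e-8)

    def test_constant_curve_on_disjoint_control(self):
        from .conftest import make_chain_model
        from astroflux.model import Metabolite, Reaction

        model = make_chain_model()
        model.add_metabolite(Metabolite(id="inert[c]"))
        model.add_reaction(Reaction(id="E_inert", stoichiometry={"inert[c]": -1.0},
                                    lower_bound=-1000.0))
        model.add_reaction(Reaction(id="SINK_inert", stoichiometry={"inert[c]": -1.0},
                                    lower_bound=0.0))
        curve = robustness_curve(model, "E_inert", "E_out", n=15)
        assert np.allclose(curve.values, curve.values[0])

    def test_points_beyond_capacity_flagged_infeasible(self, healthy_model, toy_params):
        curve = robustness_curve(healthy_model, CONTROL, "EX_lac_L(e)", n=101)
        beyond = curve.grid > toy_params.inhibition_u0 + 1e-9
        assert beyond.any()
        assert not curve.feasible[beyond].any()
        assert (curve.values[beyond] == 0.0).all()

    def test_grid_length_matches_n(self, healthy_model):
        curve = robustness_curve(healthy_model, CONTROL, "EX_lac_L(e)", n=50)
        assert len(curve.grid) == 50 and len(curve.values) == 50

    def test_alias_control_id(self, healthy_model):
        curve = robustness_curve(healthy_model, "EXhdca(e)", "EX_lac_L(e)", n=11)
        assert curve.control_id == CONTROL

    def test_missing_objective_is_error(self, healthy_model):
        with pytest.raises(Exception):
            robustness_curve(healthy_model, CONTROL, "nope", n=5)

    def test_concavity_on_feasible_region(self, healthy_model):
        for objective in synth.TOY_OBJECTIVES:
            curve = robustness_curve(healthy_model, CONTROL, objective, n=101)
            feasible = curve.values[curve.feasible]
            assert np.all(np.diff(feasible, 2) <= 1e-6)


def _line_curve(u0, n=101):
    grid = np.linspace(0.0, 1.0, n)
    values = np.maximum(1.0 - grid / u0, 0.0)
    return RobustnessCurve("ctrl", "obj", grid, values, np.ones(n, dtype=bool))


class TestIC50:
    def test_unit_line_crosses_at_half(self):
        assert ic50(_line_curve(1.0)) == pytest.approx(0.5, abs=1e-9)

    def test_constant_curve_is_undefined(self):
        n = 21
        curve = RobustnessCurve("c", "o", np.linspace(0, 1, n), np.full(n, 3.0),
                                np.ones(n, dtype=bool))
        with pytest.raises(UndefinedIC50Error):
            ic50(curve)

    def test_toy_equals_engineered_closed_form(self, healthy_model, toy_params):
        grid_spacing = 1.0 / 200
        for objective in synth.TOY_OBJECTIVES:
            curve = robustness_curve(healthy_model, CONTROL, objective, n=201)
            assert ic50(curve) == pytest.approx(
                toy_params.inhibition_u0 / 2, abs=2 * grid_spacing
            )

    def test_refinement_stability(self, healthy_model):
        coarse = ic50(robustness_curve(healthy_model, CONTROL, "EX_lac_L(e)", n=1000))
        fine = ic50(robustness_curve(healthy_model, CONTROL, "EX_lac_L(e)", n=4000))
        assert abs(coarse - fine) <= 2.0 / 999

    def test_two_feasible_points_required(self):
        curve = RobustnessCurve("c", "o", np.array([0.0, 0.5, 1.0]),
                                np.array([1.0, 0.0, 0.0]),
                                np.array([True, False, False]))
        with pytest.raises(UndefinedIC50Error):
            ic50(curve)


class TestMeanIC50:
    def test_identical_curves_zero_sd(self, healthy_model):
        mean, sd, per, undefined = mean_ic50(
            healthy_model, CONTROL, synth.TOY_OBJECTIVES, n=201
        )
        assert sd == pytest.approx(0.0, abs=1e-9)
        assert undefined == []
        assert len(per) == 5

    def test_mean_of_two_values(self):
        values = [ic50(_line_curve(0.8)), ic50(_line_curve(1.2))]
        assert values == pytest.approx([0.4, 0.6], abs=1e-9)
        assert np.mean(values) == pytest.approx(0.5, abs=1e-9)

    def test_toy_mean_is_half_u0(self, ic50_mean, toy_params):
        assert ic50_mean == pytest.approx(toy_params.inhibition_u0 / 2, abs=0.01)


class TestFoldChanges:
    def test_printed_worked_example(self):
        records = fold_changes({"FTCD": 0.39}, {"FTCD": 1.28}, threshold=2.0)
        assert len(records) == 1
        assert records[0].fold_change == pytest.approx(2.28, abs=0.005)

    def test_identical_fluxes_filtered_out(self):
        assert fold_changes({"r": 1.5}, {"r": 1.5}, threshold=0.1) == []

    def test_zero_reference_branch(self):
        records = fold_changes({"r": 0.0}, {"r": 3.5}, threshold=2.0)
        assert records[0].fold_change == pytest.approx(3.5)

    def test_self_comparison_empty_at_any_positive_threshold(self, healthy_model):
        sol = canonical_fluxes(healthy_model, LEX)
        assert fold_changes(sol, sol, threshold=0.5) == []
        assert fold_changes(sol, sol, threshold=2.0) == []

    def test_sorted_by_magnitude_descending(self):
        records = fold_changes({"a": 1.0, "b": 1.0}, {"a": 4.0, "b": 9.0})
        assert [r.reaction_id for r in records] == ["b", "a"]

    def test_include_all_returns_every_shared_reaction(self):
        records = fold_changes({"a": 1.0, "b": 2.0, "only_ref": 1.0},
                               {"a": 1.0, "b": 2.0}, include_all=True)
        assert [r.reaction_id for r in records] == ["a", "b"]

    def test_treatment_effect_visible_and_abolished_by_T1(
        self, inflamed_model, treated_model
    ):
        ref = canonical_fluxes(inflamed_model, LEX)
        alt = canonical_fluxes(treated_model, LEX)
        assert len(fold_changes(ref, alt, threshold=2.0)) >= 1
        alt_ko = canonical_fluxes(knockout(treated_model, "T1"), LEX)
        assert fold_changes(ref, alt_ko, threshold=2.0) == []


@pytest.fixture(scope="module")
def classifications(healthy_model, inflamed_model, treated_model):
    return classify_knockouts(healthy_model, inflamed_model, treated_model, OBJECTIVE)


class TestClassifyKnockouts:
    def _by_label(self, classifications, label):
        return sorted(c.reaction_id for c in classifications if c.label == label)

    def test_shared_resource_knockout_is_pro_inflammatory(self, classifications):
        pro = self._by_label(classifications, "pro_inflammatory")
        assert "ALAt" in pro and "BIOMASS" in pro

    def test_oxygen_route_is_anti_inflammatory(self, classifications):
        anti = self._by_label(classifications, "anti_inflammatory")
        assert "EX_o2(e)" in anti

    def test_tibolone_entry_is_treatment_essential(self, classifications):
        essential = self._by_label(classifications, "treatment_essential")
        assert "T1" in essential and "ES1" in essential

    def test_redundant_tibolone_route_is_neutral(self, classifications):
        by_id = {c.reaction_id: c.label for c in classifications}
        assert by_id["T6"] == "neutral"  # T7 provides the alternative route
        assert by_id["T10"] == "neutral"

    def test_labels_mutually_exclusive(self, classifications):
        seen = {}
        for c in classifications:
            assert c.reaction_id not in seen
            seen[c.reaction_id] = c.label

    def test_order_invariance(self, healthy_model, inflamed_model, treated_model,
                              classifications):
        treatment_ids = [r.id for r in treated_model.reactions
                         if not inflamed_model.has_reaction(r.id)]
        again = classify_knockouts(
            healthy_model, inflamed_model, treated_model, OBJECTIVE,
            treatment_ids=list(reversed(treatment_ids)),
        )
        assert [(c.reaction_id, c.label) for c in again] == [
            (c.reaction_id, c.label) for c in classifications
        ]


class TestSubsystemActivity:
    def test_identical_fluxes_all_zero(self):
        fluxes = {"a": 1.0, "b": 0.0}
        result = subsystem_activity(fluxes, fluxes, {"a": "s1", "b": "s1"})
        assert result["s1"]["activated_pct"] == 0.0
        assert result["s1"]["inactivated_pct"] == 0.0

    def test_one_of_four_newly_active(self):
        ref = {"a": 0.0, "b": 1.0, "c": 1.0, "d": 1.0}
        alt = {"a": 2.0, "b": 1.0, "c": 1.0, "d": 1.0}
        result = subsystem_activity(ref, alt, {k: "s" for k in ref})
        assert result["s"]["activated_pct"] == pytest.approx(25.0)

    def test_untagged_grouped_as_unassigned(self):
        result = subsystem_activity({"a": 0.0}, {"a": 1.0}, {})
        assert result["unassigned"]["activated_pct"] == pytest.approx(100.0)

    def test_toy_scenarios_match_manual_tally(self, healthy_model, inflamed_model):
        ref = canonical_fluxes(healthy_model, LEX).fluxes
        alt = canonical_fluxes(inflamed_model, LEX).fluxes
        submap = {r.id: r.subsystem for r in healthy_model.reactions}
        result = subsystem_activity(ref, alt, submap, tol=1e-6)
        # independent tally
        for name, stats in result.items():
            members = [r for r, s in submap.items() if (s or "unassigned") == name]
            act = sum(1 for r in members
                      if abs(ref[r]) <= 1e-6 and abs(alt[r]) > 1e-6)
            inact = sum(1 for r in members
                        if abs(ref[r]) > 1e-6 and abs(alt[r]) <= 1e-6)
            assert stats["activated_pct"] == pytest.approx(100.0 * act / len(members))
            assert stats["inactivated_pct"] == pytest.approx(100.0 * inact / len(members))


class TestPipeline:
    def test_smoke_produces_all_reports(self, tmp_path):
        config = PipelineConfig(outdir=str(tmp_path / "run"), grid_n=60, seed=11)
        summary = run_pipeline(config)
        expected = [
            "expression.tsv", "fluxes_healthy.tsv", "fluxes_inflammatory.tsv",
            "fluxes_treatment.tsv", "foldchange_healthy_vs_inflammatory.tsv",
            "foldchange_inflammatory_vs_treatment.tsv", "knockouts.tsv",
            "subsystem_activity.tsv", "summary.json", "run.log",
        ]
        for name in expected:
            assert (tmp_path / "run" / name).exists(), name
        assert summary["ic50"]["mean"] == pytest.approx(0.25, abs=0.02)

    def test_grid_n_controls_curve_length(self, tmp_path):
        config = PipelineConfig(outdir=str(tmp_path / "run"), grid_n=50, seed=11)
        run_pipeline(config)
        curve = (tmp_path / "run" / "robustness_DM_atp.tsv").read_text().splitlines()
        assert len(curve) == 51  # header + 50 grid points

    def test_fixed_seed_byte_identical(self, tmp_path):
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        run_pipeline(PipelineConfig(outdir=str(out1), grid_n=40, seed=5))
        run_pipeline(PipelineConfig(outdir=str(out2), grid_n=40, seed=5))
        files1 = sorted(p.name for p in out1.iterdir())
        assert files1 == sorted(p.name for p in out2.iterdir())
        for name in files1:
            assert (out1 / name).read_bytes() == (out2 / name).read_bytes(), name

    def test_config_yaml_round_trip(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("grid_n: 77\nseed: 9\nobjective_id: EX_lac_L(e)\n")
        config = PipelineConfig.from_yaml(path)
        assert config.grid_n == 77 and config.seed == 9
        assert config.objective_id == "EX_lac_L(e)"

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "config.yaml"
        path.write_text("grid_m: 7\n")
        with pytest.raises(ScenarioError, match="grid_m"):
            PipelineConfig.from_yaml(path)

    def test_summary_json_knockout_labels(self, tmp_path):
        config = PipelineConfig(outdir=str(tmp_path / "run"), grid_n=60, seed=11)
        run_pipeline(config)
        summary = json.loads((tmp_path / "run" / "summary.json").read_text())
        assert "T1" in summary["knockout_labels"]["treatment_essential"]
        assert "ALAt" in summary["knockout_labels"]["pro_inflammatory"]
        assert summary["knockout_labels"]["anti_inflammatory"]
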