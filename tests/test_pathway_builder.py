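"""Scenario construction: topology contracts, repression motifs, sampling."""

import numpy as np
import pytest

import follisim as fs
from follisim.pathway_builder import (
    MIRNA_IDS,
    ScenarioSpec,
    add_mirna_repression,
    build_receptor_module,
    build_scenario,
    default_ledger,
    sample_parameters,
)
from follisim.reaction_network import conserved_moieties, validate_model
from follisim.simulator import SimulationSettings, simulate


class TestScenarioSpec:
    def test_sf_rejects_fold_changes(self):
        with pytest.raises(ValueError):
            ScenarioSpec(scenario="SF", expression_multipliers={"TEK": 2.0})

    def test_df_mirna_requires_all_four(self):
        with pytest.raises(ValueError):
            ScenarioSpec(scenario="DF_miRNA",
                         mirna_levels={"hsa_miR_30d_3p": 1.0})

    def test_unknown_axis_rejected(self):
        with pytest.raises(ValueError, match="axis"):
            ScenarioSpec(scenario="DF", expression_multipliers={"BRAF": 2.0})


class TestTopologyContracts:
    def test_sf_df_identical_reactions(self, scenario_models):
        sf, df = scenario_models["SF"], scenario_models["DF"]
        assert [r.id for r in sf.reactions] == [r.id for r in df.reactions]
        assert sf.species_ids() == df.species_ids()

    def test_df_mirna_strict_superset(self, scenario_models):
        df, dfm = scenario_models["DF"], scenario_models["DF_miRNA"]
        assert len(dfm.species) > len(df.species)
        assert len(dfm.reactions) > len(df.reactions)
        assert set(df.species_ids()) < set(dfm.species_ids())

    def test_df_with_unit_multipliers_is_sf(self, scenario_models):
        neutral = build_scenario(ScenarioSpec(
            scenario="DF", expression_multipliers={k: 1.0 for k in
                                                   ("ANGPT1", "ANGPT2", "TEK")}))
        sf = scenario_models["SF"]
        assert neutral.species_ids() == sf.species_ids()
        np.testing.assert_array_equal(neutral.initial_state(), sf.initial_state())

    def test_assembled_models_validate_cleanly(self, scenario_models):
        for model in scenario_models.values():
            report = validate_model(model)
            assert report.ok, report.errors

    def test_expected_conserved_totals_present(self, scenario_models):
        cons = conserved_moieties(scenario_models["SF"])
        member_sets = [set(c) for c in cons]
        for expected in [
            {"Ras_GDP", "Ras_GTP"}, {"MEK", "pMEK", "ppMEK"},
            {"ERK", "pERK", "ppERK"}, {"Akt", "pAkt"},
            {"PIP2", "PIP3"}, {"EIF4EBP1", "pEIF4EBP1"},
        ]:
            assert any(expected <= s for s in member_sets), expected


class TestReceptorModule:
    def test_no_ligand_no_signal(self):
        led = default_ledger()
        model = build_receptor_module(led)
        model.get_species("ANGPT1").initial_amount = 0.0
        model.get_species("ANGPT2").initial_amount = 0.0
        tc = simulate(model, SimulationSettings(t_end=200, n_output_points=200))
        assert np.abs(tc.series("pRec")).max() <= 1e-12

    def test_angpt2_arm_is_silent(self):
        """ANGPT2 binds TEK but its complex emits no phospho-receptor."""
        model = build_receptor_module()
        model.get_species("ANGPT1").initial_amount = 0.0
        tc = simulate(model, SimulationSettings(t_end=200, n_output_points=200))
        assert tc.series("A2_TEK").max() > 0.01
        assert np.abs(tc.series("pRec")).max() <= 1e-12

    def test_angpt2_competition_lowers_phospho_peak(self):
        peaks = []
        for a2 in (0.0, 1.0, 3.0):
            model = build_receptor_module()
            model.get_species("ANGPT2").initial_amount = a2
            tc = simulate(model, SimulationSettings(t_end=300, n_output_points=300))
            peaks.append(tc.series("pRec").max())
        assert peaks[0] > peaks[1] > peaks[2]


class TestMirnaRepression:
    def test_zero_strength_is_identity(self, scenario_models):
        df = scenario_models["DF"]
        blocked = add_mirna_repression(df, "hsa_miR_30d_3p", "MYC",
                                       "translation_block", 0.0)
        t1 = simulate(df, SimulationSettings(t_end=500, n_output_points=100))
        t2 = simulate(blocked, SimulationSettings(t_end=500, n_output_points=100))
        for sid in df.species_ids():
            np.testing.assert_allclose(t1.series(sid), t2.series(sid),
                                       rtol=1e-7, atol=1e-10)

    def test_double_application_multiplies_divisors(self, scenario_models):
        """Blocking twice with s1, s2 equals the combined (1+s1 m)(1+s2 m)."""
        df = scenario_models["DF"]
        m, s1, s2 = 1.0, 0.8, 1.7
        twice = add_mirna_repression(df, "mirX", "MYC", "translation_block", s1, m)
        twice = add_mirna_repression(twice, "mirY", "MYC", "translation_block", s2, m)
        combined = (1 + s1 * m) * (1 + s2 * m)
        once = add_mirna_repression(df, "mirX", "MYC", "translation_block",
                                    combined - 1.0, m)
        ta = simulate(twice, SimulationSettings(t_end=800, n_output_points=100))
        tb = simulate(once, SimulationSettings(t_end=800, n_output_points=100))
        for sid in ("MYC", "pMYC", "ppMYC"):
            np.testing.assert_allclose(ta.series(sid), tb.series(sid),
                                       rtol=1e-6, atol=1e-9)

    def test_myc_block_lowers_steady_total(self, scenario_runs):
        df, dfm = scenario_runs["DF"], scenario_runs["DF_miRNA"]
        total = lambda tc: (tc.series("MYC") + tc.series("pMYC")
                            + tc.series("ppMYC"))[-1]
        assert total(dfm) < total(df)

    def test_unknown_target_raises(self, scenario_models):
        with pytest.raises(KeyError):
            add_mirna_repression(scenario_models["DF"], "mirX", "nosuch",
                                 "translation_block", 1.0)

    def test_negative_strength_raises(self, scenario_models):
        with pytest.raises(ValueError):
            add_mirna_repression(scenario_models["DF"], "mirX", "MYC",
                                 "translation_block", -0.5)

    def test_mirnas_are_constant_species(self, scenario_models):
        dfm = scenario_models["DF_miRNA"]
        for mid in MIRNA_IDS:
            assert dfm.get_species(mid).constant


class TestParameterSampling:
    def test_zero_cv_is_identity(self):
        led = default_ledger()
        out = sample_parameters(led, seed=3, coefficient_of_variation=0.0)
        assert {k: v.value for k, v in out.rates.items()} == \
               {k: v.value for k, v in led.rates.items()}

    def test_seed_determinism(self):
        led = default_ledger()
        a = sample_parameters(led, seed=7, coefficient_of_variation=0.2)
        b = sample_parameters(led, seed=7, coefficient_of_variation=0.2)
        c = sample_parameters(led, seed=8, coefficient_of_variation=0.2)
        assert {k: v.value for k, v in a.rates.items()} == \
               {k: v.value for k, v in b.rates.items()}
        assert {k: v.value for k, v in a.rates.items()} != \
               {k: v.value for k, v in c.rates.items()}

    def test_original_ledger_untouched(self):
        led = default_ledger()
        before = {k: v.value for k, v in led.rates.items()}
        sample_parameters(led, seed=1, coefficient_of_variation=0.5)
        assert {k: v.value for k, v in led.rates.items()} == before
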