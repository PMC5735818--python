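"""Core representation: rate laws, stoichiometry, ODE assembly, moieties."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import follisim as fs
from follisim.reaction_network import (
    ModelConsistencyError,
    build_ode_rhs,
    conserved_moieties,
    mass_action_rate,
    stoichiometric_matrix,
    validate_model,
)

from conftest import binding_model, chain_model


def _binding_reaction():
    return fs.ReactionDef(id="bind", reactants=[("A", 1), ("B", 1)],
                          products=[("AB", 1)], kf=1.0, kr=0.5)


class TestMassActionRate:
    @pytest.mark.parametrize(
        "state,expected",
        [
            ({"A": 0.0, "B": 5.0, "AB": 0.0}, 0.0),
            ({"A": 2.0, "B": 3.0, "AB": 4.0}, 1.0 * 2 * 3 - 0.5 * 4),
            # equilibrium: [AB]/([A][B]) = kf/kr = 2 gives zero net flux
            ({"A": 1.5, "B": 2.0, "AB": 6.0}, 0.0),
        ],
    )
    def test_printed_rate_law(self, state, expected):
        assert mass_action_rate(_binding_reaction(), state) == pytest.approx(expected)

    def test_unknown_species_raises(self):
        with pytest.raises(ModelConsistencyError, match="AB"):
            mass_action_rate(_binding_reaction(), {"A": 1.0, "B": 1.0})

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError, match="negative"):
            mass_action_rate(_binding_reaction(), {"A": -1.0, "B": 1.0, "AB": 0.0})

    @given(
        a=st.floats(0.01, 10), b=st.floats(0.01, 10),
        kf=st.floats(0.01, 10), kr=st.floats(0.01, 10),
    )
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_detailed_balance_at_equilibrium(self, a, b, kf, kr):
        """Any state on the kf/kr equilibrium manifold has zero net flux."""
        rxn = fs.ReactionDef(id="bind", reactants=[("A", 1), ("B", 1)],
                             products=[("AB", 1)], kf=kf, kr=kr)
        ab = kf / kr * a * b
        flux = mass_action_rate(rxn, {"A": a, "B": b, "AB": ab})
        assert abs(flux) <= 1e-12 * max(1.0, kf * a * b)


class TestStoichiometry:
    def test_single_binding_column(self):
        smat = stoichiometric_matrix(binding_model())
        assert smat.row_ids == ["A", "B", "AB"]
        np.testing.assert_array_equal(smat.matrix[:, 0], [-1, -1, 1])

    def test_reversible_reaction_is_one_column(self):
        smat = stoichiometric_matrix(binding_model())
        assert smat.matrix.shape == (3, 1)

    def test_chain(self):
        smat = stoichiometric_matrix(chain_model())
        np.testing.assert_array_equal(smat.matrix, [[-1, 0], [1, -1], [0, 1]])


@st.composite
def small_models(draw):
    n_species = draw(st.integers(2, 8))
    ids = [f"S{i}" for i in range(n_species)]
    species = [
        fs.SpeciesDef(id=sid, initial_amount=draw(st.floats(0.0, 5.0)))
        for sid in ids
    ]
    n_rxn = draw(st.integers(1, 6))
    reactions = []
    for j in range(n_rxn):
        nr = draw(st.integers(0, 2))
        np_ = draw(st.integers(0 if nr else 1, 2))
        reactants = [(draw(st.sampled_from(ids)), 1) for _ in range(nr)]
        products = [(draw(st.sampled_from(ids)), 1) for _ in range(np_)]
        reactions.append(fs.ReactionDef(
            id=f"r{j}", reactants=reactants, products=products,
            kf=draw(st.floats(0.0, 3.0)),
            kr=draw(st.floats(0.0, 3.0)) if nr and np_ else 0.0,
        ))
    return fs.NetworkModel(species=species, reactions=reactions)


class TestOdeRhs:
    def test_irreversible_conversion(self):
        model = fs.NetworkModel(
            species=[fs.SpeciesDef(id="A", initial_amount=1.0), fs.SpeciesDef(id="B")],
            reactions=[fs.ReactionDef(id="r", reactants=[("A", 1)],
                                      products=[("B", 1)], kf=0.1)],
        )
        dy = build_ode_rhs(model)(0.0, model.initial_state())
        np.testing.assert_allclose(dy, [-0.1, 0.1])

    def test_constant_species_has_zero_rate(self):
        model = fs.NetworkModel(
            species=[fs.SpeciesDef(id="M", initial_amount=1.0, constant=True),
                     fs.SpeciesDef(id="X", initial_amount=1.0)],
            reactions=[fs.ReactionDef(id="r", reactants=[("X", 1), ("M", 1)],
                                      products=[("M", 1)], kf=0.3)],
        )
        dy = build_ode_rhs(model)(0.0, model.initial_state())
        assert dy[0] == 0.0
        assert dy[1] == pytest.approx(-0.3)

    def test_unknown_rule_symbol_raises(self):
        model = binding_model()
        model.global_parameters["obs"] = 0.0
        model.rules.append(fs.AssignmentRule(target="obs", formula="A + nosuch"))
        with pytest.raises(ModelConsistencyError, match="nosuch"):
            build_ode_rhs(model)

    @given(model=small_models(), data=st.data())
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_matches_brute_force_n_dot_v(self, model, data):
        """dy/dt equals an explicit per-species sum over reactions."""
        state = np.array(
            [data.draw(st.floats(0.01, 5.0)) for _ in model.species]
        )
        dy = build_ode_rhs(model)(0.0, state)
        named = dict(zip(model.species_ids(), state))
        expected = np.zeros(len(model.species))
        for rxn in model.reactions:
            flux = mass_action_rate(rxn, named)
            for i, sid in enumerate(model.species_ids()):
                net = sum(c for s, c in rxn.products if s == sid) - sum(
                    c for s, c in rxn.reactants if s == sid
                )
                expected[i] += net * flux
        np.testing.assert_allclose(dy, expected, rtol=1e-12, atol=1e-12)


class TestConservedMoieties:
    def test_reversible_binding_totals(self):
        cons = conserved_moieties(binding_model())
        found = {frozenset(c.items()) for c in cons}
        assert frozenset({"A": 1, "AB": 1}.items()) in found
        assert frozenset({"B": 1, "AB": 1}.items()) in found

    def test_chain_total(self):
        cons = conserved_moieties(chain_model())
        assert len(cons) == 1
        assert cons[0] == {"A": 1, "B": 1, "C": 1}

    def test_sink_destroys_conservation(self):
        """A degradation sink removes the naive total from the basis, and
        everything still reported annihilates N exactly."""
        model = chain_model()
        model.reactions.append(
            fs.ReactionDef(id="sink", reactants=[("C", 1)], products=[], kf=0.1)
        )
        cons = conserved_moieties(model)
        smat = stoichiometric_matrix(model).matrix
        ids = model.species_ids()
        for c in cons:
            vec = np.array([c.get(sid, 0) for sid in ids])
            assert np.abs(vec @ smat).max() == 0
        assert {"A": 1, "B": 1, "C": 1} not in cons

    def test_all_builder_moieties_annihilate_n(self, scenario_models):
        model = scenario_models["SF"]
        smat = stoichiometric_matrix(model).matrix
        ids = model.species_ids()
        cons = conserved_moieties(model)
        assert cons, "builder model should have conserved cycles"
        for c in cons:
            vec = np.array([c.get(sid, 0) for sid in ids])
            assert np.abs(vec @ smat).max() == 0


class TestValidation:
    def test_empty_model(self):
        report = validate_model(fs.NetworkModel())
        assert (report.n_species, report.n_reactions,
                report.n_parameters, report.n_rules) == (0, 0, 0, 0)
        assert report.ok

    def test_dangling_reference_is_named(self):
        model = fs.NetworkModel(
            species=[fs.SpeciesDef(id="A", initial_amount=1.0)],
            reactions=[fs.ReactionDef(id="r", reactants=[("A", 1)],
                                      products=[("ghost", 1)], kf=1.0)],
        )
        report = validate_model(model)
        assert not report.ok
        assert any("ghost" in e for e in report.errors)

    def test_duplicate_ids_flagged(self):
        model = binding_model()
        model.species.append(fs.SpeciesDef(id="A"))
        assert any("duplicate" in e for e in validate_model(model).errors)

    def test_order_cap_enforced(self):
        with pytest.raises(ValueError, match="order"):
            fs.ReactionDef(id="r", reactants=[("A", 2), ("B", 1)],
                           products=[("C", 1)], kf=1.0)
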