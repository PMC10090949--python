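"""Domain types, boundary-reaction editing and unit conversion."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from natrigem.gpr import GeneRule, GprSyntaxError
from natrigem.model import (MetabolicModel, Metabolite, ModelValidationError,
                            Reaction, add_boundary_reaction, mass_rate_to_molar,
                            molecular_weight, parse_formula, set_bounds)
from natrigem import solve_fba


class TestFormulae:
    def test_parse_glucose(self):
        assert parse_formula("C6H12O6") == {"C": 6, "H": 12, "O": 6}

    def test_molecular_weights(self):
        assert molecular_weight("C6H12O6") == pytest.approx(180.156, abs=1e-3)
        assert molecular_weight("C2H3O2") == pytest.approx(59.044, abs=1e-3)

    @pytest.mark.parametrize("bad", ["", "6CH", "C6H12O6!"])
    def test_bad_formula_rejected(self, bad):
        with pytest.raises(ValueError):
            parse_formula(bad)

    def test_unknown_element_rejected_in_weight(self):
        with pytest.raises(ValueError, match="Xx"):
            molecular_weight("Xx2")

    def test_mass_rate_to_molar_examples(self):
        # 3.9 g/gDW/h glucose and 1.4 g/gDW/h acetate, the reported rates
        assert mass_rate_to_molar(3.9, "C6H12O6") == pytest.approx(21.65, abs=0.01)
        assert mass_rate_to_molar(1.4, "C2H3O2") == pytest.approx(23.71, abs=0.01)
        assert mass_rate_to_molar(0.0, "C6H12O6") == 0.0

    @given(st.floats(min_value=0, max_value=100), st.floats(min_value=0, max_value=100))
    @settings(max_examples=50, deadline=None)
    def test_mass_rate_is_linear(self, a, b):
        f = "C6H12O6"
        total = mass_rate_to_molar(a + b, f)
        assert total == pytest.approx(
            mass_rate_to_molar(a, f) + mass_rate_to_molar(b, f), rel=1e-12, abs=1e-12)


class TestModelInvariants:
    def test_stoichiometric_matrix_shape_and_columns(self, toy6):
        S = toy6.stoichiometric_matrix()
        assert S.shape == (len(toy6.metabolites), len(toy6.reactions))
        # every reaction column touches at least one metabolite
        assert (abs(S).sum(axis=0) > 0).all()

    def test_unknown_metabolite_rejected(self):
        with pytest.raises(ModelValidationError, match="RX"):
            MetabolicModel(
                metabolites=[Metabolite(id="a_c")],
                reactions=[Reaction(id="RX", stoichiometry={"ghost": 1.0})],
                genes=[], objective_reaction_id="RX")

    def test_missing_objective_rejected(self, toy6):
        with pytest.raises(ModelValidationError, match="objective"):
            MetabolicModel(metabolites=toy6.metabolites,
                           reactions=toy6.reactions, genes=toy6.genes,
                           objective_reaction_id="NOPE")

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ModelValidationError):
            Reaction(id="R", stoichiometry={"x": 1.0}, lower_bound=1, upper_bound=-1)

    def test_boundary_classification_is_partition(self, toy6):
        m = add_boundary_reaction(toy6, "A_c", "sink")
        kinds = {r: m.boundary_kind(r) for r in m.reaction_ids}
        assert kinds["EX_A"] == "exchange"
        assert kinds["SK_A_c"] == "sink"
        # the biomass drain is, structurally, a demand reaction
        assert kinds["BIOMASS"] == "demand"
        assert kinds["R1"] == kinds["T_A"] == "internal"
        # every reaction falls in exactly one class
        assert set(kinds.values()) <= {"exchange", "sink", "demand", "internal"}


class TestBoundaryReactions:
    def test_existing_exchange_is_idempotent(self, toy6):
        assert add_boundary_reaction(toy6, "A_e", "exchange") is toy6

    def test_demand_definition(self, toy6):
        m = add_boundary_reaction(toy6, "C_c", "demand")
        r = m.reaction("DM_C_c")
        assert r.stoichiometry == {"C_c": -1.0}
        assert (r.lower_bound, r.upper_bound) == (0.0, 1000.0)

    def test_exchange_requires_extracellular(self, toy6):
        with pytest.raises(ModelValidationError):
            add_boundary_reaction(toy6, "C_c", "exchange")

    def test_unknown_metabolite_errors(self, toy6):
        with pytest.raises(KeyError):
            add_boundary_reaction(toy6, "nope_c", "sink")

    def test_sink_feeds_downstream_pathway(self, toy6):
        # carbon through a B_c sink alone supports mu = 10 via R2
        m = set_bounds(toy6, "EX_A", lower=0.0)
        m = add_boundary_reaction(m, "B_c", "sink")
        m = set_bounds(m, "SK_B_c", lower=-10.0, upper=0.0)
        assert solve_fba(m).objective_value == pytest.approx(10.0, abs=1e-6)


class TestGeneRuleRoundTrip:
    @pytest.mark.parametrize("text", [
        "g1", "g1 and g2", "g1 or g2", "(g1 and g2) or (g1 and g3)",
        "g1 and (g2 or g3) and g4", "((g1))",
    ])
    def test_parse_serialize_reparse_is_stable(self, text):
        rule = GeneRule.from_string(text)
        again = GeneRule.from_string(rule.to_string())
        assert again.to_string() == rule.to_string()
        # semantics preserved: same truth table over the mentioned genes
        genes = sorted(rule.genes())
        for mask in range(2 ** len(genes)):
            deleted = {g for i, g in enumerate(genes) if mask >> i & 1}
            assert rule.evaluate(deleted) == again.evaluate(deleted)

    def test_empty_rule_always_active(self):
        assert GeneRule.empty().evaluate({"g1"}) is True

    @pytest.mark.parametrize("bad", ["g1 and", "(g1", "and g2", "g1 ) g2"])
    def test_syntax_errors(self, bad):
        with pytest.raises(GprSyntaxError):
            GeneRule.from_string(bad)

    def test_precedence_and_binds_tighter(self):
        rule = GeneRule.from_string("g1 or g2 and g3")
        # g1 deleted, g2 present, g3 deleted: (g2 and g3) false, g1 false
        assert rule.evaluate({"g1", "g3"}) is False
        assert rule.evaluate({"g1"}) is True
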