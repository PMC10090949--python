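"""GPR evaluation, knockout screens, viability assays and scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from natrigem.essentiality import (ConfusionMatrix, SubstratePanel,
                                   essentiality_confusion, essentiality_screen,
                                   evaluate_gene_rule, run_substrate_panel,
                                   score_panel, substrate_viability)
from natrigem.gpr import GeneRule
from natrigem.synthetic import make_random_network
from oracle import eval_rule_string, random_rule

GENES = ["g1", "g2", "g3", "g4", "g5"]


class TestGeneRuleEvaluation:
    @pytest.mark.parametrize("rule,deleted,expect", [
        ("g2 or g3", {"g2"}, True),
        ("g4 and g5", {"g5"}, False),
        ("(g1 and g2) or (g1 and g3)", {"g2", "g3"}, False),
        ("(g1 and g2) or (g1 and g3)", {"g2"}, True),
        ("", {"g1", "g2"}, True),
    ])
    def test_examples(self, rule, deleted, expect):
        assert evaluate_gene_rule(GeneRule.from_string(rule), deleted) is expect

    def test_thousand_random_rules_match_truth_tables(self):
        rng = np.random.default_rng(20260923)
        for _ in range(1000):
            text = random_rule(rng, GENES)
            rule = GeneRule.from_string(text)
            for mask in range(2 ** len(GENES)):
                present = {g for i, g in enumerate(GENES) if mask >> i & 1}
                deleted = set(GENES) - present
                assert rule.evaluate(deleted) == eval_rule_string(text, present), \
                    f"rule {text!r} disagrees at present={present}"

    @given(st.integers(min_value=0, max_value=2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_property_random_tree_agrees_with_interpreter(self, seed):
        rng = np.random.default_rng(seed)
        text = random_rule(rng, GENES)
        rule = GeneRule.from_string(text)
        for mask in range(2 ** len(GENES)):
            present = {g for i, g in enumerate(GENES) if mask >> i & 1}
            assert rule.evaluate(set(GENES) - present) == \
                eval_rule_string(text, present)


class TestEssentialityScreen:
    def test_toy6_essential_set(self, toy6):
        res = essentiality_screen(toy6, tau_ess=0.9)
        assert res.essential_genes == {"g1", "g4", "g5"}
        # knocking the bypass gene changes nothing: R3 is off at optimum
        assert res.mu_ko["g6"] == pytest.approx(10.0, abs=1e-6)
        # losing the complex forces the half-yield bypass
        assert res.mu_ko["g4"] == pytest.approx(5.0, abs=1e-6)

    def test_monotone_in_threshold(self, toy6):
        loose = essentiality_screen(toy6, tau_ess=0.5).essential_genes
        strict = essentiality_screen(toy6, tau_ess=0.9).essential_genes
        assert loose <= strict

    def test_monotone_on_random_networks(self):
        for seed in range(3):
            m = make_random_network(4, n_bypass=2, seed=seed)
            loose = essentiality_screen(m, tau_ess=0.3).essential_genes
            strict = essentiality_screen(m, tau_ess=0.95).essential_genes
            assert loose <= strict

    def test_unused_gene_is_never_essential(self, toy6):
        m = toy6.copy()
        m.genes.append("ghost")
        res = essentiality_screen(m, tau_ess=0.9)
        assert "ghost" not in res.essential_genes
        assert res.mu_ko["ghost"] == pytest.approx(res.mu_wt)

    def test_zero_wildtype_growth_rejected(self, toy6):
        from natrigem.model import set_bounds
        with pytest.raises(ValueError):
            essentiality_screen(set_bounds(toy6, "EX_A", lower=0.0))


class TestSubstrateViability:
    def test_extracellular_supply_uses_transporter(self, toy6):
        assert substrate_viability(toy6, "A_e", "extracellular") is True

    def test_mode_split_localizes_missing_transport(self, toy6):
        m = toy6.copy()
        m.reactions = [r for r in m.reactions if r.id != "T_A"]
        m.validate()
        assert substrate_viability(m, "A_e", "extracellular") is False
        assert substrate_viability(m, "A_c", "cytoplasmic") is True

    def test_absent_substrate_marked_not_in_model(self, toy6):
        assert substrate_viability(toy6, "xyz_c", "cytoplasmic") is None

    def test_viability_uptake_invariant_above_noise(self, toy6):
        assert substrate_viability(toy6, "A_e", "extracellular", uptake=0.01) \
            == substrate_viability(toy6, "A_e", "extracellular", uptake=100.0)


class TestPanelScoring:
    def test_perfect_predictions(self):
        panel = SubstratePanel(labels={"a": True, "b": False})
        cm = score_panel({"a": True, "b": False}, panel)
        assert (cm.tp, cm.fp, cm.tn, cm.fn) == (1, 0, 1, 0)
        assert cm.accuracy == 1.0

    def test_counts_and_accuracy_arithmetic(self):
        panel = SubstratePanel(labels={"a": True, "b": False, "c": False,
                                       "d": True})
        cm = score_panel({"a": True, "b": False, "c": False, "d": False}, panel)
        assert (cm.tp, cm.tn, cm.fn, cm.fp) == (1, 2, 1, 0)
        assert cm.accuracy == pytest.approx(0.75)
        assert cm.total == 4

    def test_not_in_model_excluded(self):
        panel = SubstratePanel(labels={"a": True, "b": False, "zz": True})
        cm = score_panel({"a": True, "b": False, "zz": None}, panel)
        assert cm.total == 2

    def test_panel_run_on_toy(self, toy6):
        panel = SubstratePanel(labels={"A_e": True, "missing_e": False})
        preds = run_substrate_panel(toy6, panel)
        cm = score_panel(preds, panel)
        assert (cm.tp, cm.total) == (1, 1)


class TestEssentialityConfusion:
    def test_identity(self):
        cm = essentiality_confusion({"a", "b"}, {"a", "b"}, {"a", "b", "c"})
        assert (cm.fp, cm.fn) == (0, 0)

    def test_set_arithmetic(self):
        universe = set("abcdefghij")
        cm = essentiality_confusion({"a", "b", "c"}, {"b", "c", "d"}, universe)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (2, 1, 1, 6)

    def test_subset_violation_rejected(self):
        with pytest.raises(ValueError):
            essentiality_confusion({"z"}, {"a"}, {"a", "b"})
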