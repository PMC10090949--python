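"""Spectral-count normalization, coverage, ANOVA, weight fractions."""

import numpy as np
import pandas as pd
import pytest

from natrigem.proteomics import (ProteomeTable, category_weight_fraction,
                                 differential_expression, normalize_counts,
                                 one_way_anova, reaction_expression_coverage)
from natrigem.gpr import GeneRule
from natrigem.synthetic import make_synthetic_proteome, make_toy6


def _table(data, **meta):
    counts = pd.DataFrame(data).T
    return ProteomeTable(counts=counts, **meta)


class TestNormalization:
    def test_totals_equalized_and_grand_total_conserved(self):
        t = _table({"s1": {"a": 40, "b": 60}, "s2": {"a": 100, "b": 200}})
        out = normalize_counts(t)
        totals = out.counts.sum(axis=1)
        assert totals["s1"] == pytest.approx(200.0)
        assert totals["s2"] == pytest.approx(200.0)
        assert out.counts.values.sum() == pytest.approx(t.counts.values.sum())
        # within-sample rank order preserved
        assert (out.counts.loc["s2", "b"] > out.counts.loc["s2", "a"])

    def test_equal_totals_are_fixed_point(self):
        t = _table({"s1": {"a": 50, "b": 50}, "s2": {"a": 30, "b": 70}})
        out = normalize_counts(t)
        pd.testing.assert_frame_equal(out.counts, t.counts, check_like=True,
                                      check_dtype=False)

    def test_single_sample_unchanged(self):
        t = _table({"s1": {"a": 7, "b": 3}})
        pd.testing.assert_frame_equal(normalize_counts(t).counts, t.counts,
                                      check_dtype=False)

    def test_zero_total_sample_named(self):
        t = _table({"s1": {"a": 1}, "sz": {"a": 0}})
        with pytest.raises(ValueError, match="sz"):
            normalize_counts(t)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            _table({"s1": {"a": -1}})


class TestCoverage:
    def test_complex_and_isoenzyme_semantics(self, toy6):
        # detected {g1, g3, g4}: T_A found via g1, R1 via g3 (isoenzyme),
        # R2 misses only g5 -> 2/3 fully detected, 3/3 all-but-one
        rep = reaction_expression_coverage(
            toy6, {"T_A", "R1", "R2", "BIOMASS"}, {"g1", "g3", "g4"})
        assert rep.n_gene_associated == 3
        assert rep.n_fully_detected == 2
        assert rep.n_all_but_one == 3
        assert rep.n_active_reactions == 4

    @pytest.mark.parametrize("rule,detected,full,abo", [
        ("g4 and g5", {"g4"}, False, True),
        ("g2 or g3", {"g3"}, True, True),
        ("g1 and g2 and g3", {"g1"}, False, False),
        ("(g1 and g2) or g3", set(), False, True),
    ])
    def test_rule_detection_cases(self, rule, detected, full, abo):
        from natrigem.proteomics import _rule_detection
        assert _rule_detection(GeneRule.from_string(rule), detected) == (full, abo)

    def test_nesting_inequality_on_random_fixtures(self):
        from oracle import random_rule
        from natrigem.model import MetabolicModel, Metabolite, Reaction
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(6)]
        for _ in range(20):
            reactions = [
                Reaction(id=f"R{j}", stoichiometry={"m_c": 1.0},
                         gene_rule=GeneRule.from_string(random_rule(rng, genes)))
                for j in range(8)]
            model = MetabolicModel(
                metabolites=[Metabolite(id="m_c")], reactions=reactions,
                genes=genes, objective_reaction_id="R0")
            detected = {g for g in genes if rng.random() < 0.5}
            rep = reaction_expression_coverage(
                model, set(model.reaction_ids), detected)
            assert rep.n_fully_detected <= rep.n_all_but_one
            assert rep.n_all_but_one <= rep.n_gene_associated
            assert rep.n_gene_associated <= rep.n_active_reactions


class TestAnova:
    def test_identical_groups(self):
        f, p = one_way_anova([[1.0, 2.0], [1.0, 2.0]])
        assert f == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_computed_f(self):
        # SSB = 4, SSW = 1, df (1, 2) -> F = 8
        f, p = one_way_anova([[1, 2], [3, 4]])
        assert f == pytest.approx(8.0)
        assert 0 < p < 1

    def test_within_group_permutation_invariance(self):
        f1, p1 = one_way_anova([[1, 2, 5], [3, 4, 9]])
        f2, p2 = one_way_anova([[5, 1, 2], [9, 4, 3]])
        assert f1 == pytest.approx(f2) and p1 == pytest.approx(p2)

    def test_zero_within_variance_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1, 1], [2, 2]])

    def test_agrees_with_permutation_null(self):
        """p value consistent with a permutation F distribution."""
        rng = np.random.default_rng(17)
        a = rng.normal(0.0, 1.0, 6)
        b = rng.normal(1.0, 1.0, 6)
        f_obs, p = one_way_anova([a, b])
        pooled = np.concatenate([a, b])
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            f_perm, _ = one_way_anova([perm[:6], perm[6:]])
            count += f_perm >= f_obs
        p_perm = count / n_perm
        assert abs(p - p_perm) < 3 * np.sqrt(p_perm * (1 - p_perm) / n_perm) + 0.01

    def test_power_on_synthetic_fold_change(self):
        """A 4-fold protein shift at ~1000 counts is detected (p < 0.01)."""
        hits = 0
        for seed in range(100):
            table = make_synthetic_proteome(
                shares={"focal": 0.1, "other": 0.9},
                masses={"focal": 30.0, "other": 30.0},
                lengths={"focal": 270.0, "other": 270.0},
                categories={}, total_counts=10_000, n_samples=6,
                group_effects={"focal": 4.0}, seed=seed)
            res = differential_expression(table, "salinity_mM", 0, 300)
            hits += res.loc["focal", "p"] < 0.01
        assert hits >= 95


class TestWeightFractions:
    @pytest.fixture
    def table(self):
        counts = pd.DataFrame({"rpA": [10.0], "rpB": [10.0], "met": [20.0]},
                              index=["s1"])
        meta = pd.DataFrame({
            "length_aa": [100, 100, 100],
            "mass_g_per_mmol": [2.0, 2.0, 2.0],
            "category": ["ribosome", "ribosome", "metabolism"],
        }, index=["rpA", "rpB", "met"])
        return ProteomeTable(counts=counts, protein_meta=meta)

    def test_category_partition_sums_to_100(self, table):
        f1 = category_weight_fraction(table, "s1", "ribosome")
        f2 = category_weight_fraction(table, "s1", "metabolism")
        assert f1 + f2 == pytest.approx(100.0)
        assert f1 == pytest.approx(50.0)

    def test_all_in_one_category_is_100(self):
        counts = pd.DataFrame({"a": [5.0]}, index=["s1"])
        meta = pd.DataFrame({"length_aa": [10], "mass_g_per_mmol": [1.0],
                             "category": ["x"]}, index=["a"])
        t = ProteomeTable(counts=counts, protein_meta=meta)
        assert category_weight_fraction(t, "s1", "x") == pytest.approx(100.0)

    def test_unknown_sample_or_category_rejected(self, table):
        with pytest.raises(KeyError):
            category_weight_fraction(table, "zz", "ribosome")
        with pytest.raises(ValueError):
            category_weight_fraction(table, "s1", "nope")

    def test_mass_share_recovery_within_sampling_error(self):
        """Measured category fraction matches the generating share."""
        shares = {"a": 0.3, "b": 0.7}
        masses = {"a": 20.0, "b": 40.0}
        lengths = {"a": 180.0, "b": 360.0}
        cats = {"a": "x", "b": "y"}

        def measure(seed):
            t = make_synthetic_proteome(shares, masses, lengths, cats,
                                        total_counts=10_000, n_samples=2,
                                        seed=seed)
            return category_weight_fraction(t, "sample0", "x")

        estimate = measure(seed=0)
        replicas = [measure(seed=s) for s in range(1, 21)]
        se = np.std(replicas, ddof=1)
        assert abs(estimate - 30.0) <= 3 * se + 1e-9
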