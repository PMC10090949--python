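"""RBA-lite: bisection solve, calibration, allocation, coverage."""

import numpy as np
import pytest

from natrigem.lp import FluxSample
from natrigem.rba import (DEFAULT_KAPP, EnzymeSpec, ProteinSpec, _RbaLp,
                          allocation_summary, calibrate_kapp,
                          enzyme_concentration, expressed_gene_coverage,
                          protein_concentrations, solve_rba)
from natrigem.synthetic import (make_rba_instance, make_self_replicator,
                                make_synthetic_proteome)


class TestSelfReplicator:
    def test_closed_form_growth_rate(self):
        # translation capacity at saturation: mu* = k / L
        problem = make_self_replicator(k_translation=36_000,
                                       ribosome_length=36_000)
        sol = solve_rba(problem, 1e-3, 5.0, tol=1e-4)
        assert sol.mu == pytest.approx(1.0, abs=2e-4)

    def test_closed_form_scales_with_elongation_rate(self):
        problem = make_self_replicator(k_translation=72_000,
                                       ribosome_length=36_000)
        sol = solve_rba(problem, 1e-3, 5.0, tol=1e-4)
        assert sol.mu == pytest.approx(2.0, abs=2e-4)

    def test_all_protein_is_translational_machinery(self):
        problem = make_self_replicator()
        sol = solve_rba(problem)
        alloc = allocation_summary(sol, problem.proteins,
                                   {"ribosome": "translational machinery"})
        assert alloc["translational machinery"] == pytest.approx(1.0)


class TestSolveRba:
    def test_density_constraint_tight_at_optimum(self):
        problem = make_rba_instance()
        sol = solve_rba(problem)
        mass = sum(sol.protein_conc[p] * problem.proteins[p].mass_g_per_mmol
                   for p in sol.protein_conc)
        assert mass == pytest.approx(problem.p_total, abs=1e-6)

    def test_feasibility_monotone_in_mu(self):
        problem = make_rba_instance()
        sol = solve_rba(problem, tol=1e-4)
        lp = _RbaLp(problem)
        assert lp.solve(0.5 * sol.mu).status == 0
        assert lp.solve(sol.mu).status == 0
        assert lp.solve(sol.mu + 1e-3).status != 0

    def test_doubling_kapp_never_decreases_growth(self):
        base = make_rba_instance()
        fast = make_rba_instance(kapp_transport=4_000, kapp_synthesis=1_600)
        assert solve_rba(fast).mu >= solve_rba(base).mu - 1e-6

    def test_infeasible_bracket_rejected(self):
        problem = make_rba_instance()
        with pytest.raises(ValueError):
            solve_rba(problem, mu_lo=100.0, mu_hi=200.0)

    def test_exhausted_bracket_flagged(self):
        problem = make_rba_instance()
        sol = solve_rba(problem, mu_lo=1e-3, mu_hi=0.01)
        assert sol.bracket_exhausted
        assert sol.mu == pytest.approx(0.01)


class TestProteinConcentrations:
    def test_single_protein_example(self):
        conc = protein_concentrations({"p": 123.0}, {"p": 50.0}, p_total=0.47)
        assert conc["p"] == pytest.approx(0.47 / 50.0)

    def test_equal_counts_equal_masses_split_evenly(self):
        conc = protein_concentrations({"a": 10, "b": 10}, {"a": 2.0, "b": 2.0},
                                      p_total=0.4)
        assert conc["a"] == pytest.approx(conc["b"])
        assert conc["a"] + conc["b"] == pytest.approx(0.4 / 2.0)

    def test_count_scale_invariance(self):
        masses = {"a": 3.0, "b": 7.0}
        c1 = protein_concentrations({"a": 5, "b": 15}, masses)
        c2 = protein_concentrations({"a": 10, "b": 30}, masses)
        for p in masses:
            assert c1[p] == pytest.approx(c2[p])

    def test_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            protein_concentrations({"a": 0.0}, {"a": 1.0})


class TestKappCalibration:
    def test_division_example(self):
        enz = EnzymeSpec(reaction_id="R", composition={"p": 1.0})
        sample = FluxSample(n=2, seed=0, reaction_ids=["R"],
                            matrix=np.array([[1.0], [1.0]]))
        out = calibrate_kapp(sample, {"p": 0.001}, [enz])
        assert out[0].kapp_forward == pytest.approx(1000.0)

    def test_undetected_enzyme_gets_default(self):
        enz = EnzymeSpec(reaction_id="R", composition={"p": 1.0})
        sample = FluxSample(n=1, seed=0, reaction_ids=["R"],
                            matrix=np.array([[1.0]]))
        out = calibrate_kapp(sample, {}, [enz])
        assert out[0].kapp_forward == DEFAULT_KAPP == pytest.approx(172 * 3600)

    def test_limiting_subunit_rule(self):
        enz = EnzymeSpec(reaction_id="R", composition={"a": 2.0, "b": 1.0})
        assert enzyme_concentration(enz, {"a": 1.0, "b": 10.0}) == \
            pytest.approx(0.5)

    def test_parameter_recovery_from_simulated_proteome(self):
        """Known kapps come back from the instance's own optimum."""
        problem = make_rba_instance(kapp_transport=2_000, kapp_synthesis=800)
        sol = solve_rba(problem, tol=1e-5)
        # proteome shares at the optimum -> multinomial counts -> back
        mass = {p: spec.mass_g_per_mmol for p, spec in problem.proteins.items()}
        total = sum(sol.protein_conc[p] * mass[p] for p in sol.protein_conc)
        shares = {p: sol.protein_conc[p] * mass[p] / total
                  for p in sol.protein_conc}
        lengths = {p: spec.length_aa for p, spec in problem.proteins.items()}
        table = make_synthetic_proteome(
            shares, mass, lengths, {}, total_counts=200_000, n_samples=2,
            seed=11)
        counts = table.counts.mean(axis=0).to_dict()
        conc = protein_concentrations(counts, mass, p_total=problem.p_total)
        flux_rows = np.array([[sol.fluxes[r] for r in problem.model.reaction_ids]])
        sample = FluxSample(n=1, seed=0,
                            reaction_ids=problem.model.reaction_ids,
                            matrix=flux_rows)
        calibrated = calibrate_kapp(sample, conc, problem.enzymes)
        expected = {"T_S": 2_000.0, "R_AA": 800.0}
        for enz in calibrated:
            assert enz.kapp_forward == pytest.approx(
                expected[enz.reaction_id], rel=0.05)


class TestAllocationAndCoverage:
    def test_two_equal_categories_split_half(self):
        sol_conc = {"a": 1.0, "b": 1.0}
        proteins = {"a": ProteinSpec(100, 10), "b": ProteinSpec(100, 10)}
        from natrigem.rba import RbaSolution
        sol = RbaSolution(mu=1.0, fluxes={}, enzyme_conc={}, machinery_conc={},
                          protein_conc=sol_conc)
        alloc = allocation_summary(sol, proteins, {"a": "x", "b": "y"})
        assert alloc == {"x": pytest.approx(0.5), "y": pytest.approx(0.5)}

    def test_coverage_examples(self):
        from natrigem.rba import RbaSolution
        sol = RbaSolution(mu=1.0, fluxes={}, enzyme_conc={}, machinery_conc={},
                          protein_conc={"a": 1e-3, "b": 1e-3, "c": 1e-3,
                                        "d": 1e-3, "e": 1e-9})
        assert expressed_gene_coverage(sol, {"a", "b", "c"}) == \
            pytest.approx(0.75)
        assert expressed_gene_coverage(sol, {"a", "b", "c", "d", "x"}) == 1.0
        with pytest.raises(ValueError):
            expressed_gene_coverage(sol, {"a"}, threshold=1.0)
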