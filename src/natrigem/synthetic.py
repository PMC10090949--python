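"""Synthetic fixtures with hand-solvable ground truth.

Every generator here is deterministic under a fixed seed and its documented
ground truth is exact in rational arithmetic, so the fixtures double as
oracles for the LP, essentiality, RBA and proteomics machinery without any
external model download.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gpr import GeneRule
from .model import MetabolicModel, Metabolite, Reaction
from .proteomics import ProteomeTable
from .rba import EnzymeSpec, MachinerySpec, ProteinSpec, RbaProblem


def make_toy6() -> MetabolicModel:
    """The six-reaction toy network TOY6.

    A_e is taken up (EX_A, lb -10), transported (T_A, gene g1), converted
    A_c -> B_c (R1, g2 or g3) -> C_c (R2, g4 and g5) and drained as biomass.
    R3 (gene g6) is a half-yield bypass A_c -> 0.5 C_c. Ground truth:
    optimum mu = 10; FVA of R3 at 98% of optimum = [0, 0.4]; essential
    genes at the 90% threshold = {g1, g4, g5}.
    """
    mets = [
        Metabolite(id="A_e", formula="C6H12O6", compartment="e"),
        Metabolite(id="A_c", formula="C6H12O6", compartment="c"),
        Metabolite(id="B_c", formula="C6H12O6", compartment="c"),
        Metabolite(id="C_c", formula="C6H12O6", compartment="c"),
    ]

    def rxn(rid, stoich, lb, ub, rule=""):
        return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                        upper_bound=ub, gene_rule=GeneRule.from_string(rule))

    reactions = [
        rxn("EX_A", {"A_e": -1}, -10, 1000),
        rxn("T_A", {"A_e": -1, "A_c": 1}, 0, 1000, "g1"),
        rxn("R1", {"A_c": -1, "B_c": 1}, 0, 1000, "g2 or g3"),
        rxn("R2", {"B_c": -1, "C_c": 1}, 0, 1000, "g4 and g5"),
        rxn("R3", {"A_c": -1, "C_c": 0.5}, 0, 1000, "g6"),
        rxn("BIOMASS", {"C_c": -1}, 0, 1000),
    ]
    return MetabolicModel(metabolites=mets, reactions=reactions,
                          genes=["g1", "g2", "g3", "g4", "g5", "g6"],
                          objective_reaction_id="BIOMASS", name="TOY6")


def make_random_network(n_linear: int, n_bypass: int = 0, seed: int = 0,
                        uptake: float = 10.0) -> MetabolicModel:
    """A random linear chain with lower-yield bypasses; optimum = uptake.

    The chain substrate -> M1 -> ... -> biomass has unit yields, so the
    optimum equals the uptake bound and every chain gene is essential at
    tau = 0.9 unless a bypass of yield >= 0.9 shortcuts its step. Bypass
    yields are drawn uniformly from (0, 1).
    """
    if n_linear < 2:
        raise ValueError("n_linear must be >= 2")
    rng = np.random.default_rng(seed)
    mets = [Metabolite(id="S_e", formula="C6H12O6", compartment="e")]
    mets += [Metabolite(id=f"M{i}_c", formula="C6H12O6", compartment="c")
             for i in range(n_linear)]

    def rxn(rid, stoich, lb, ub, rule=""):
        return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                        upper_bound=ub, gene_rule=GeneRule.from_string(rule))

    reactions = [rxn("EX_S", {"S_e": -1}, -uptake, 1000),
                 rxn("T_S", {"S_e": -1, "M0_c": 1}, 0, 1000, "gT")]
    genes = ["gT"]
    for i in range(n_linear - 1):
        gene = f"g{i}"
        genes.append(gene)
        reactions.append(rxn(f"STEP{i}", {f"M{i}_c": -1, f"M{i+1}_c": 1},
                             0, 1000, gene))
    bypass_yields = {}
    for b in range(n_bypass):
        step = int(rng.integers(0, n_linear - 1))
        y = float(rng.uniform(0.05, 0.99))
        gene = f"gb{b}"
        genes.append(gene)
        bypass_yields[f"BYP{b}"] = (step, y)
        reactions.append(rxn(f"BYP{b}", {f"M{step}_c": -1, f"M{step+1}_c": y},
                             0, 1000, gene))
    reactions.append(rxn("BIOMASS", {f"M{n_linear-1}_c": -1}, 0, 1000))
    model = MetabolicModel(metabolites=mets, reactions=reactions, genes=genes,
                           objective_reaction_id="BIOMASS",
                           name=f"chain{n_linear}_{seed}")
    model.bypass_yields = bypass_yields  # ground truth for tests
    return model


def make_synthetic_proteome(shares: dict[str, float],
                            masses: dict[str, float],
                            lengths: dict[str, float],
                            categories: dict[str, str],
                            total_counts: int = 10_000,
                            n_samples: int = 6,
                            group_effects: dict[str, float] | None = None,
                            seed: int = 0) -> ProteomeTable:
    """Multinomial spectral-count matrix from known protein mass fractions.

    Count expectations are proportional to share/mass (a heavy protein
    yields fewer spectra per gram); ``group_effects`` multiplies the
    expected counts of chosen proteins in the second half of the samples,
    emulating a salinity response. Group metadata labels the halves 0 and
    300 mM NaCl.
    """
    if abs(sum(shares.values()) - 1.0) > 1e-9:
        raise ValueError("mass shares must sum to 1")
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    rng = np.random.default_rng(seed)
    prots = sorted(shares)
    base_w = np.array([shares[p] / masses[p] for p in prots])
    group_effects = group_effects or {}
    rows = {}
    salinities = []
    for s in range(n_samples):
        w = base_w.copy()
        second_half = s >= n_samples // 2
        if second_half:
            for p, fold in group_effects.items():
                w[prots.index(p)] *= fold
        probs = w / w.sum()
        rows[f"sample{s}"] = rng.multinomial(total_counts, probs)
        salinities.append(300 if second_half else 0)
    counts = pd.DataFrame.from_dict(rows, orient="index", columns=prots)
    sample_meta = pd.DataFrame({"salinity_mM": salinities,
                                "growth_phase": "exponential",
                                "replicate": list(range(n_samples))},
                               index=counts.index)
    protein_meta = pd.DataFrame({
        "length_aa": [lengths[p] for p in prots],
        "mass_g_per_mmol": [masses[p] for p in prots],
        "category": [categories.get(p, "other") for p in prots],
    }, index=prots)
    return ProteomeTable(counts=counts, sample_meta=sample_meta,
                         protein_meta=protein_meta)


def make_self_replicator(k_translation: float = 36_000.0,
                         ribosome_length: float = 36_000.0,
                         p_total: float = 0.47) -> RbaProblem:
    """Ribosome-only self-replicating cell; closed form mu* = k / L.

    All protein is ribosome; the translation-capacity constraint at
    saturation gives mu * L * c_R = k * c_R regardless of the density
    bound, so the bisected optimum must equal k_translation /
    ribosome_length.
    """
    mets = [Metabolite(id="aa_c", formula="C5H9NO2", compartment="c")]
    reactions = [Reaction(id="SRC_aa", stoichiometry={"aa_c": 1.0},
                          lower_bound=0.0, upper_bound=1e7)]
    model = MetabolicModel(metabolites=mets, reactions=reactions, genes=[],
                           objective_reaction_id="SRC_aa",
                           name="self_replicator")
    proteins = {"ribosome": ProteinSpec(length_aa=ribosome_length,
                                        mass_g_per_mmol=ribosome_length * 0.109)}
    machinery = [MachinerySpec(process="translation",
                               composition={"ribosome": 1.0},
                               capacity_rate=k_translation)]
    return RbaProblem(model=model, proteins=proteins, enzymes=[],
                      machinery=machinery, p_total=p_total,
                      aa_species="aa_c")


def make_rba_instance(kapp_transport: float = 2_000.0,
                      kapp_synthesis: float = 800.0,
                      k_translation: float = 72_000.0,
                      p_total: float = 0.47) -> RbaProblem:
    """A small RBA instance with known apparent catalytic rates.

    A substrate is imported (enzyme pT, 1 copy) and converted to amino
    acids (enzyme pA, homodimer), which translation (ribosome R) turns
    into protein; a non-catalytic storage protein absorbs spare proteome
    mass. Used for the kapp-recovery property: simulate the proteome at
    the optimum, re-calibrate, and the known rates come back.
    """
    mets = [Metabolite(id="S_e", formula="C6H12O6", compartment="e"),
            Metabolite(id="S_c", formula="C6H12O6", compartment="c"),
            Metabolite(id="aa_c", formula="C5H9NO2", compartment="c")]
    reactions = [
        Reaction(id="EX_S", stoichiometry={"S_e": -1}, lower_bound=-10.0,
                 upper_bound=1000.0),
        Reaction(id="T_S", stoichiometry={"S_e": -1, "S_c": 1},
                 lower_bound=0.0, upper_bound=1000.0),
        Reaction(id="R_AA", stoichiometry={"S_c": -1, "aa_c": 1.5},
                 lower_bound=0.0, upper_bound=1000.0),
    ]
    model = MetabolicModel(metabolites=mets, reactions=reactions, genes=[],
                           objective_reaction_id="R_AA", name="rba_toy")
    proteins = {
        "pT": ProteinSpec(length_aa=300.0, mass_g_per_mmol=300 * 0.109),
        "pA": ProteinSpec(length_aa=450.0, mass_g_per_mmol=450 * 0.109),
        "R": ProteinSpec(length_aa=7_500.0, mass_g_per_mmol=7_500 * 0.109),
        "storage": ProteinSpec(length_aa=250.0, mass_g_per_mmol=250 * 0.109),
    }
    enzymes = [
        EnzymeSpec(reaction_id="T_S", composition={"pT": 1.0},
                   kapp_forward=kapp_transport, kapp_backward=kapp_transport),
        EnzymeSpec(reaction_id="R_AA", composition={"pA": 2.0},
                   kapp_forward=kapp_synthesis, kapp_backward=kapp_synthesis),
    ]
    machinery = [MachinerySpec(process="translation", composition={"R": 1.0},
                               capacity_rate=k_translation)]
    return RbaProblem(model=model, proteins=proteins, enzymes=enzymes,
                      machinery=machinery, p_total=p_total,
                      aa_species="aa_c", free_proteins=["storage"])
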