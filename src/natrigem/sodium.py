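"""Sodium-motive-force bioenergetics of a halophilic respiratory chain.

Vibrio-type bacteria pump sodium out of the cell with a Na+-translocating
NADH:quinone oxidoreductase (Na+-NQR) and interconvert the resulting sodium
motive force (SMF) with the proton motive force (PMF) through Na+/H+
antiporters. A sodium-translocating oxaloacetate decarboxylase (Na+-OAD),
run in reverse, can exploit the SMF to carboxylate pyruvate to oxaloacetate
— an anaplerotic route alternative to PEP carboxylase (PPC).

The arithmetic at a 2:1 H+/Na+ antiporter stoichiometry and a 4 H+/ATP
synthase: carboxylating one pyruvate through the Na+-OAD spends two
extracellular sodium ions == four extracellular protons == one ATP, while
the PPC route forgoes the one ATP of pyruvate kinase — the two routes cost
the same. The real pump, however, counter-transports one proton per
catalytic event (the proton its decarboxylation chemistry consumes is taken
from outside), which rebates one extracellular proton and makes the
SMF-driven route strictly cheaper; an optimizing model therefore prefers it.

This module builds a small, element- and charge-balanced core network that
exhibits these effects exactly, and provides the enforced-sodium-influx
sweep used to study high-salinity conditions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lp import InfeasibleProblemError, run_fva, solve_fba
from .model import (MetabolicModel, Metabolite, Reaction, knock_out_reaction,
                    parse_formula, set_bounds)
from .gpr import GeneRule

#: default glucose uptake bound of the core model (mmol gDW^-1 h^-1)
GLC_UPTAKE = 10.0
#: ATP demand of the core biomass reaction (mmol per unit growth); chosen
#: high enough that the optimum is energy- rather than carbon-limited, so
#: dissipating the SMF shows up directly in the growth rate.
BIOMASS_ATP = 30.0


def _mets() -> list[Metabolite]:
    def m(mid, formula, charge, comp):
        return Metabolite(id=mid, formula=formula, charge=charge, compartment=comp)

    return [
        m("glc_e", "C6H12O6", 0, "e"), m("glc_c", "C6H12O6", 0, "c"),
        m("pep_c", "C3H2O6P", -3, "c"), m("pyr_c", "C3H3O3", -1, "c"),
        m("oaa_c", "C4H2O5", -2, "c"),
        m("co2_c", "CO2", 0, "c"), m("co2_e", "CO2", 0, "e"),
        m("hco3_c", "CHO3", -1, "c"),
        m("h2o_c", "H2O", 0, "c"), m("h2o_e", "H2O", 0, "e"),
        m("o2_c", "O2", 0, "c"), m("o2_e", "O2", 0, "e"),
        m("pi_c", "HO4P", -2, "c"),
        m("adp_c", "C10H12N5O10P2", -3, "c"), m("atp_c", "C10H12N5O13P3", -4, "c"),
        m("nad_c", "C21H26N7O14P2", -1, "c"), m("nadh_c", "C21H27N7O14P2", -2, "c"),
        m("q8_c", "C49H74O4", 0, "c"), m("q8h2_c", "C49H76O4", 0, "c"),
        m("na_c", "Na", 1, "c"), m("na_e", "Na", 1, "e"),
        m("h_c", "H", 1, "c"), m("h_e", "H", 1, "e"),
    ]


#: reactions that move species across the membrane (element/charge checked)
MEMBRANE_REACTIONS = ("T_GLC", "T_O2", "T_CO2", "T_H2O", "NQR", "CYO", "ATPS",
                      "ANT", "OAD", "NA_LEAK")


def build_halophile_core(nNa_nqr: int = 2, counter_proton: bool = True,
                         ant_h_per_na: int = 2,
                         glucose_uptake: float = GLC_UPTAKE) -> MetabolicModel:
    """Construct the fixed membrane-energetics core model.

    Parameters
    ----------
    nNa_nqr:
        Na+ pumped per NADH by the Na+-NQR (>= 1). Only ratios relative to
        the antiporter and ATP synthase matter for the equal-cost result.
    counter_proton:
        When True (the biological case) the proton consumed by the OAD
        decarboxylation chemistry is taken from the outside — the
        counter-transport that tips the anaplerotic cost balance. When
        False it is taken from the cytoplasm (equal-cost control).
    ant_h_per_na:
        H+ translocated per Na+ by the antiporter (2 is the halophile
        default; 1 halves the ATP-equivalent value of a sodium ion).
    """
    if nNa_nqr < 1:
        raise ValueError("nNa_nqr must be >= 1")
    oad_proton = "h_e" if counter_proton else "h_c"

    def rxn(rid, stoich, lb, ub, rule=""):
        return Reaction(id=rid, stoichiometry=stoich, lower_bound=lb,
                        upper_bound=ub, gene_rule=GeneRule.from_string(rule))

    reactions = [
        rxn("EX_glc", {"glc_e": -1}, -glucose_uptake, 1000),
        rxn("EX_o2", {"o2_e": -1}, -1000, 1000),
        rxn("EX_co2", {"co2_e": -1}, -1000, 1000),
        rxn("EX_h2o", {"h2o_e": -1}, -1000, 1000),
        rxn("T_GLC", {"glc_e": -1, "glc_c": 1}, 0, 1000, "glcT"),
        rxn("T_O2", {"o2_e": -1, "o2_c": 1}, -1000, 1000),
        rxn("T_CO2", {"co2_c": -1, "co2_e": 1}, -1000, 1000),
        rxn("T_H2O", {"h2o_c": -1, "h2o_e": 1}, -1000, 1000),
        # glucose -> 2 PEP skeleton (substrate-level ATP arrives at PYK)
        rxn("GLYC", {"glc_c": -1, "nad_c": -2, "pi_c": -2,
                     "pep_c": 2, "nadh_c": 2, "h2o_c": 2, "h_c": 4},
            0, 1000, "gapA"),
        rxn("PYK", {"pep_c": -1, "adp_c": -1, "h_c": -1,
                    "pyr_c": 1, "atp_c": 1}, 0, 1000, "pyk"),
        rxn("PPC", {"pep_c": -1, "hco3_c": -1, "oaa_c": 1, "pi_c": 1},
            0, 1000, "ppc"),
        rxn("CA", {"co2_c": -1, "h2o_c": -1, "hco3_c": 1, "h_c": 1},
            -1000, 1000),
        # full oxidation lump of pyruvate: 5 NADH per pyruvate
        rxn("PYRDH", {"pyr_c": -1, "h2o_c": -3, "nad_c": -5,
                      "co2_c": 3, "nadh_c": 5, "h_c": 4}, 0, 1000, "aceE"),
        rxn("NQR", {"nadh_c": -1, "q8_c": -1, "h_c": -1, "na_c": -nNa_nqr,
                    "nad_c": 1, "q8h2_c": 1, "na_e": nNa_nqr},
            0, 1000, "nqrA and nqrB"),
        rxn("CYO", {"q8h2_c": -1, "o2_c": -0.5, "h_c": -4,
                    "q8_c": 1, "h2o_c": 1, "h_e": 4}, 0, 1000, "cyoA"),
        rxn("ATPS", {"adp_c": -1, "pi_c": -1, "h_e": -4,
                     "atp_c": 1, "h2o_c": 1, "h_c": 3}, -1000, 1000, "atpA"),
        rxn("ANT", {"na_c": -1, "h_e": -ant_h_per_na,
                    "na_e": 1, "h_c": ant_h_per_na}, -1000, 1000, "nhaB"),
        # decarboxylation direction forward; carboxylation = reverse
        rxn("OAD", {"oaa_c": -1, "na_c": -2, oad_proton: -1,
                    "pyr_c": 1, "co2_c": 1, "na_e": 2}, -1000, 1000,
            "oadA and oadB"),
        rxn("NA_LEAK", {"na_e": -1, "na_c": 1}, 0, 0),
        rxn("ATPM", {"atp_c": -1, "h2o_c": -1,
                     "adp_c": 1, "pi_c": 1, "h_c": 1}, 0, 1000),
        # biomass drain: 1 OAA + 1 PYR skeleton + ATP hydrolysis; the 3 H+
        # taken up with the anionic precursors keep the drain charge-neutral
        rxn("BIOMASS", {"oaa_c": -1, "pyr_c": -1, "atp_c": -BIOMASS_ATP,
                        "h2o_c": -BIOMASS_ATP, "adp_c": BIOMASS_ATP,
                        "pi_c": BIOMASS_ATP, "h_c": BIOMASS_ATP - 3}, 0, 1000),
    ]
    genes = sorted({g for r in reactions for g in r.gene_rule.genes()})
    return MetabolicModel(metabolites=_mets(), reactions=reactions,
                          genes=genes, objective_reaction_id="BIOMASS",
                          name="halophile_core")


def check_membrane_balance(model: MetabolicModel,
                           reaction_ids=MEMBRANE_REACTIONS) -> dict[str, dict]:
    """Element/charge imbalance per membrane reaction (all-zero = balanced)."""
    out: dict[str, dict] = {}
    for rid in reaction_ids:
        try:
            rxn = model.reaction(rid)
        except KeyError:
            continue
        elements: dict[str, float] = {}
        charge = 0.0
        for met_id, coeff in rxn.stoichiometry.items():
            met = model.metabolite(met_id)
            for el, cnt in parse_formula(met.formula).items():
                elements[el] = elements.get(el, 0.0) + coeff * cnt
            charge += coeff * met.charge
        imbalance = {el: v for el, v in elements.items() if abs(v) > 1e-9}
        if abs(charge) > 1e-9:
            imbalance["charge"] = charge
        out[rid] = imbalance
    return out


def atp_equivalent_cost(model: MetabolicModel, route: str,
                        glucose_uptake: float = GLC_UPTAKE) -> float:
    """ATP-synthase equivalents forgone per anaplerotic carboxylation.

    Measured by LP accounting: maximize ATP dissipation (ATPM flux) while
    draining one unit of oxaloacetate, once with a hypothetical uncoupled
    carboxylase (pyr + co2 -> oaa + h, the zero-cost reference) and once
    with only the requested route open; the difference is the route's cost.
    Meaningful on the ``counter_proton=False`` build for the pure
    accounting (the counter-proton otherwise rebates a quarter ATP).
    """
    if route not in ("OAD", "PPC"):
        raise ValueError(f"unknown anaplerotic route {route!r}")
    model.reaction(route)  # KeyError if the route reaction is absent

    def atpm_max(m: MetabolicModel) -> float:
        m = m.copy()
        m.objective_reaction_id = "ATPM"
        sol = solve_fba(m)
        if not sol.optimal:
            raise InfeasibleProblemError("ATP accounting LP not optimal")
        return sol.objective_value

    base = model.copy()
    base = set_bounds(base, "EX_glc", lower=-glucose_uptake)
    base = set_bounds(base, "BIOMASS", upper=0.0)
    # drain 1 OAA/h; co-consuming 2 H+ keeps the drain charge-neutral
    base.reactions.append(Reaction(id="DM_oaa",
                                   stoichiometry={"oaa_c": -1, "h_c": -2},
                                   lower_bound=1.0, upper_bound=1.0))

    ref = base.copy()
    ref = knock_out_reaction(ref, "OAD")
    ref = knock_out_reaction(ref, "PPC")
    ref.reactions.append(Reaction(
        id="CARB_FREE", stoichiometry={"pyr_c": -1, "co2_c": -1,
                                       "oaa_c": 1, "h_c": 1},
        lower_bound=0.0, upper_bound=1000.0))

    test = base.copy()
    other = "PPC" if route == "OAD" else "OAD"
    test = knock_out_reaction(test, other)

    return atpm_max(ref) - atpm_max(test)


@dataclass
class InfluxSweepResult:
    influxes: list[float]
    mu: list[float]
    f_oad: list[float | None]  # None past washout (no inward Na flux)

    def as_arrays(self):
        return (np.array(self.influxes), np.array(self.mu),
                np.array([np.nan if f is None else f for f in self.f_oad]))


def _sodium_row(model: MetabolicModel):
    S = model.stoichiometric_matrix()
    return S[model.metabolite_ids.index("na_c"), :]


def sodium_influx_sweep(model: MetabolicModel, influxes,
                        leak_reaction: str = "NA_LEAK",
                        oad_reaction: str = "OAD") -> InfluxSweepResult:
    """Growth and OAD SMF-share under enforced sodium influx.

    For each influx value phi the leak reaction (na_e -> na_c) is fixed to
    phi and the FBA optimum recorded. ``f_oad`` is the fraction of
    carrier-mediated cytoplasm-ward Na+ translocation carried by the OAD
    running as a carboxylase: the enforced leak is the perturbation being
    applied, not a competing SMF consumer, so it is excluded from the
    denominator — with it included the fraction would be diluted by the
    perturbation itself and could only fall.
    """
    influxes = list(influxes)
    if any(phi < 0 for phi in influxes):
        raise ValueError("influxes must be >= 0")
    model.reaction(leak_reaction)
    na_row = _sodium_row(model)
    leak_idx = model.reaction_ids.index(leak_reaction)
    oad_idx = model.reaction_ids.index(oad_reaction)

    mus: list[float] = []
    fs: list[float | None] = []
    for phi in influxes:
        m = set_bounds(model, leak_reaction, lower=phi, upper=phi)
        sol = solve_fba(m)
        if not sol.optimal:
            mus.append(0.0)
            fs.append(None)
            continue
        mus.append(sol.objective_value)
        v = sol.flux_vector(m)
        inward = na_row * v  # na_c production per reaction
        inward[leak_idx] = 0.0
        total = inward[inward > 1e-9].sum()
        oad_in = max(inward[oad_idx], 0.0)
        fs.append(None if total <= 1e-9 else float(oad_in / total))
    return InfluxSweepResult(influxes=influxes, mu=mus, f_oad=fs)


def reaction_knockout_effect(model: MetabolicModel, reaction_id: str) -> float:
    """Relative growth decrease (mu_wt - mu_ko) / mu_wt of a reaction KO."""
    wt = solve_fba(model)
    if not wt.optimal or wt.objective_value <= 0:
        raise ValueError("wild-type growth is zero; knockout effect undefined")
    ko = solve_fba(knock_out_reaction(model, reaction_id))
    mu_ko = ko.objective_value if ko.optimal else 0.0
    return (wt.objective_value - mu_ko) / wt.objective_value


def oad_carboxylation_fva_min(model: MetabolicModel, fraction: float = 1.0) -> float:
    """FVA minimum of OAD *carboxylation* flux (reverse sense, so -max).

    Positive at fraction 1.0 means every optimal solution carboxylates
    through the Na+-OAD — the preference theorem for the counter-proton
    pump.
    """
    res = run_fva(model, fraction=fraction, reaction_ids=["OAD"])
    lo, hi = res.ranges["OAD"]
    # carboxylation is the reverse direction: flux -hi .. -lo
    return -hi
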