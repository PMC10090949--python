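"""Cross-model comparison: reaction mapping, theoretical yields, and growth
under shared artificial biomass reactions.

Two reconstructions of different organisms rarely share reaction ids, so
correspondence is established in two phases: (1) shared cross-database
annotation keys (KEGG, MetaCyc, BiGG, ...), then (2) a canonical
stoichiometric signature (metabolites translated through their own
annotation keys, coefficients reduced to the smallest integer ratio,
direction ignored). Proton/water bookkeeping differences therefore land in
the unmapped lists rather than being silently merged.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from math import gcd

from .lp import solve_fba
from .model import (DEFAULT_BOUND, MetabolicModel, Metabolite, Reaction,
                    add_boundary_reaction, molecular_weight, set_bounds)


@dataclass
class ReactionMapping:
    pairs: list[tuple[str, str, str]]  # (id in A, id in B, evidence)
    unmapped_a: list[str] = field(default_factory=list)
    unmapped_b: list[str] = field(default_factory=list)


def _annotation_keys(rxn: Reaction) -> set[tuple[str, str]]:
    return {(db, ext) for db, ext in rxn.annotations.items()}


def _met_token(model: MetabolicModel, met_id: str) -> str:
    """Cross-model metabolite token: its smallest annotation key, else id."""
    met = model.metabolite(met_id)
    ann = getattr(met, "annotations", None)
    if ann:
        db, ext = min(ann.items())
        key = f"{db}:{ext}"
    else:
        key = met_id.rsplit("_", 1)[0] if "_" in met_id else met_id
    return f"{key}@{met.compartment}"


def _signature(model: MetabolicModel, rxn: Reaction) -> tuple:
    """Direction-agnostic canonical stoichiometric signature."""
    fracs = {
        _met_token(model, m): Fraction(c).limit_denominator(10**6)
        for m, c in rxn.stoichiometry.items()
    }
    denom = 1
    for f in fracs.values():
        denom = denom * f.denominator // gcd(denom, f.denominator)
    ints = {t: int(f * denom) for t, f in fracs.items()}
    g = 0
    for v in ints.values():
        g = gcd(g, abs(v))
    if g > 1:
        ints = {t: v // g for t, v in ints.items()}
    fwd = tuple(sorted(ints.items()))
    rev = tuple(sorted((t, -v) for t, v in ints.items()))
    return min(fwd, rev)


def map_reactions(model_a: MetabolicModel,
                  model_b: MetabolicModel) -> ReactionMapping:
    """Greedy two-phase 1:1 reaction mapping; annotation matches win."""
    pairs: list[tuple[str, str, str]] = []
    used_a: set[str] = set()
    used_b: set[str] = set()

    by_key_b: dict[tuple[str, str], list[str]] = {}
    for r in model_b.reactions:
        for key in _annotation_keys(r):
            by_key_b.setdefault(key, []).append(r.id)
    for r in model_a.reactions:
        match = None
        for key in sorted(_annotation_keys(r)):
            for cand in by_key_b.get(key, []):
                if cand not in used_b:
                    match = (cand, f"annotation:{key[0]}")
                    break
            if match:
                break
        if match:
            pairs.append((r.id, match[0], match[1]))
            used_a.add(r.id)
            used_b.add(match[0])

    by_sig_b: dict[tuple, list[str]] = {}
    for r in model_b.reactions:
        if r.id not in used_b:
            by_sig_b.setdefault(_signature(model_b, r), []).append(r.id)
    for r in model_a.reactions:
        if r.id in used_a:
            continue
        for cand in by_sig_b.get(_signature(model_a, r), []):
            if cand not in used_b:
                pairs.append((r.id, cand, "stoichiometry"))
                used_a.add(r.id)
                used_b.add(cand)
                break

    return ReactionMapping(
        pairs=pairs,
        unmapped_a=[r.id for r in model_a.reactions if r.id not in used_a],
        unmapped_b=[r.id for r in model_b.reactions if r.id not in used_b],
    )


def max_theoretical_yield(model: MetabolicModel, target_metabolite: str,
                          substrate_exchange: str,
                          substrate_uptake: float = 10.0) -> float:
    """Maximal production flux of a metabolite at fixed substrate uptake.

    Adds (or reuses) a demand reaction for the target, releases the biomass
    objective (bound >= 0) and maximizes the demand flux. Unproducible
    targets yield 0, not an error.
    """
    m = add_boundary_reaction(model, target_metabolite, "demand")
    dm_id = "DM_" + target_metabolite
    m = set_bounds(m, substrate_exchange, lower=-substrate_uptake)
    m.objective_reaction_id = dm_id
    sol = solve_fba(m)
    if not sol.optimal:
        return 0.0
    return max(0.0, sol.objective_value)


def _biomass_components(model: MetabolicModel) -> dict[str, float]:
    """Consumed species of the biomass reaction (positive coefficients)."""
    biomass = model.reaction(model.objective_reaction_id)
    return {m: -c for m, c in biomass.stoichiometry.items() if c < 0}


def shared_biomass_growth(model_a: MetabolicModel, model_b: MetabolicModel,
                          substrate_exchange_a: str, substrate_exchange_b: str,
                          substrate_uptake_g: float,
                          producible_tol: float = 1e-6) -> tuple[float, float]:
    """Growth of both models on an artificial shared biomass reaction.

    The artificial biomass keeps only precursors producible (maximal yield
    above ``producible_tol``) by *both* models, with each model's own
    coefficients renormalized so one unit of flux drains 1 g of precursor
    mass — preserving mu's h^-1 units. Components without formulas are
    dropped with a warning. The substrate uptake is mass-specific
    (g gDW^-1 h^-1) and converted per model.
    """
    comp_a = _biomass_components(model_a)
    comp_b = _biomass_components(model_b)

    def producible(model, ex, comps):
        out = set()
        for met in comps:
            y = max_theoretical_yield(model, met, ex, 10.0)
            if y > producible_tol:
                out.add(_met_token(model, met))
        return out

    tok_a = {met: _met_token(model_a, met) for met in comp_a}
    tok_b = {met: _met_token(model_b, met) for met in comp_b}
    common = (producible(model_a, substrate_exchange_a, comp_a)
              & producible(model_b, substrate_exchange_b, comp_b)
              & set(tok_a.values()) & set(tok_b.values()))
    if not common:
        raise ValueError("no common producible biomass component")

    def growth(model, ex, comps, toks):
        keep = {}
        for met, coeff in comps.items():
            if toks[met] not in common:
                continue
            f = model.metabolite(met).formula
            if f is None:
                warnings.warn(f"dropping biomass component {met!r}: no formula")
                continue
            keep[met] = (coeff, molecular_weight(f))
        total_g = sum(c * mw / 1000.0 for c, mw in keep.values())
        m = model.copy()
        m.reactions.append(Reaction(
            id="BIOMASS_shared",
            stoichiometry={met: -c / total_g for met, (c, mw) in keep.items()},
            lower_bound=0.0, upper_bound=DEFAULT_BOUND))
        m.objective_reaction_id = "BIOMASS_shared"
        sub_met = model.metabolite(
            next(iter(model.reaction(ex).stoichiometry)))
        from .model import mass_rate_to_molar
        m = set_bounds(m, ex, lower=-mass_rate_to_molar(substrate_uptake_g,
                                                        sub_met.formula))
        sol = solve_fba(m)
        return sol.objective_value if sol.optimal else 0.0

    return (growth(model_a, substrate_exchange_a, comp_a, tok_a),
            growth(model_b, substrate_exchange_b, comp_b, tok_b))
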