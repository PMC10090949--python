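"""Stoichiometric model domain types and editing operations.

A :class:`MetabolicModel` is the usual constraint-based representation of a
metabolic network: metabolites (rows of the stoichiometric matrix S),
reactions (columns, with flux bounds in mmol gDW^-1 h^-1 and a gene rule),
and one designated objective reaction (typically biomass, whose flux is the
specific growth rate mu in h^-1).

Sign conventions follow the SBML-FBC community standard: negative
stoichiometric coefficients consume, exchange fluxes are negative for uptake
and positive for secretion.
"""

from __future__ import annotations

import copy as _copy
import re
from dataclasses import dataclass, field, replace

import numpy as np

from .gpr import GeneRule

#: Default magnitude for unconstrained flux bounds (mmol gDW^-1 h^-1).
DEFAULT_BOUND = 1000.0

# IUPAC 2021 standard (average) atomic weights, abridged to elements that
# occur in metabolic reconstructions.
ATOMIC_WEIGHTS: dict[str, float] = {
    "H": 1.008, "He": 4.0026, "Li": 6.94, "B": 10.81, "C": 12.011,
    "N": 14.007, "O": 15.999, "F": 18.998, "Na": 22.990, "Mg": 24.305,
    "Al": 26.982, "Si": 28.085, "P": 30.974, "S": 32.06, "Cl": 35.45,
    "K": 39.098, "Ca": 40.078, "Cr": 51.996, "Mn": 54.938, "Fe": 55.845,
    "Co": 58.933, "Ni": 58.693, "Cu": 63.546, "Zn": 65.38, "As": 74.922,
    "Se": 78.971, "Br": 79.904, "Mo": 95.95, "I": 126.90, "W": 183.84,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*\.?\d*)")


class ModelValidationError(ValueError):
    """A model (or model file) violates a structural invariant."""


class FormulaError(ValueError):
    """An elemental formula string could not be interpreted."""


def parse_formula(formula: str) -> dict[str, float]:
    """Parse an elemental formula like ``C6H12O6`` into element -> count.

    Counts may be fractional (average biomass-component formulas sometimes
    are). Raises :class:`FormulaError` on anything unparseable.
    """
    if formula is None or formula == "":
        raise FormulaError("empty formula")
    pos = 0
    out: dict[str, float] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise FormulaError(f"unparseable formula {formula!r}")
        pos = m.end()
        elem, count = m.group(1), m.group(2)
        out[elem] = out.get(elem, 0.0) + (float(count) if count else 1.0)
    if pos != len(formula) or not out:
        raise FormulaError(f"unparseable formula {formula!r}")
    return out


def molecular_weight(formula: str) -> float:
    """Average molecular weight in g/mol from standard atomic weights."""
    comp = parse_formula(formula)
    try:
        return sum(ATOMIC_WEIGHTS[el] * n for el, n in comp.items())
    except KeyError as exc:
        raise FormulaError(f"unknown element {exc.args[0]!r} in {formula!r}") from exc


def mass_rate_to_molar(rate_g: float, formula: str) -> float:
    """Convert a mass-specific rate (g gDW^-1 h^-1) to mmol gDW^-1 h^-1.

    Flux bounds in the LP are molar, while measured uptake/secretion rates
    are usually reported per gram of substrate; this is the bridge:
    ``rate_g / MW(formula) * 1000``.
    """
    return rate_g / molecular_weight(formula) * 1000.0


@dataclass
class Metabolite:
    id: str
    name: str = ""
    formula: str | None = None
    charge: int = 0
    compartment: str = "c"
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.compartment:
            raise ModelValidationError(f"metabolite {self.id!r}: empty compartment")
        if self.formula is not None:
            parse_formula(self.formula)  # fail fast on junk


@dataclass
class Reaction:
    """A reaction column: signed stoichiometry, bounds, gene rule."""

    id: str
    stoichiometry: dict[str, float]
    lower_bound: float = -DEFAULT_BOUND
    upper_bound: float = DEFAULT_BOUND
    gene_rule: GeneRule = field(default_factory=GeneRule.empty)
    subsystem: str = ""
    name: str = ""
    annotations: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lower_bound > self.upper_bound:
            raise ModelValidationError(
                f"reaction {self.id!r}: lower bound {self.lower_bound} exceeds "
                f"upper bound {self.upper_bound}"
            )
        if not self.stoichiometry:
            raise ModelValidationError(f"reaction {self.id!r}: empty stoichiometry")

    @property
    def reversible(self) -> bool:
        return self.lower_bound < 0 < self.upper_bound

    def equation(self) -> str:
        lhs = [f"{-c:g} {m}" for m, c in sorted(self.stoichiometry.items()) if c < 0]
        rhs = [f"{c:g} {m}" for m, c in sorted(self.stoichiometry.items()) if c > 0]
        arrow = "<=>" if self.reversible else "-->"
        return f"{' + '.join(lhs)} {arrow} {' + '.join(rhs)}"


@dataclass
class MetabolicModel:
    metabolites: list[Metabolite]
    reactions: list[Reaction]
    genes: list[str]
    objective_reaction_id: str
    name: str = "model"

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups ----------------------------------------------------------
    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    def metabolite(self, met_id: str) -> Metabolite:
        for m in self.metabolites:
            if m.id == met_id:
                return m
        raise KeyError(met_id)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise KeyError(rxn_id)

    # -- structure --------------------------------------------------------
    def validate(self) -> None:
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            raise ModelValidationError(f"model {self.name!r}: duplicate metabolite ids")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            raise ModelValidationError(f"model {self.name!r}: duplicate reaction ids")
        known = set(met_ids)
        gene_set = set(self.genes)
        for r in self.reactions:
            missing = set(r.stoichiometry) - known
            if missing:
                raise ModelValidationError(
                    f"reaction {r.id!r} references unknown metabolites {sorted(missing)}"
                )
            undeclared = r.gene_rule.genes() - gene_set
            if undeclared:
                raise ModelValidationError(
                    f"reaction {r.id!r} gene rule uses undeclared genes {sorted(undeclared)}"
                )
        if self.objective_reaction_id not in set(rxn_ids):
            raise ModelValidationError(
                f"model {self.name!r}: objective reaction "
                f"{self.objective_reaction_id!r} not found"
            )

    def stoichiometric_matrix(self) -> np.ndarray:
        """Dense S with rows ordered as ``metabolites``, columns as ``reactions``."""
        row = {m.id: i for i, m in enumerate(self.metabolites)}
        S = np.zeros((len(self.metabolites), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for met, coeff in r.stoichiometry.items():
                S[row[met], j] = coeff
        return S

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        c[self.reaction_ids.index(self.objective_reaction_id)] = 1.0
        return c

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lb = np.array([r.lower_bound for r in self.reactions])
        ub = np.array([r.upper_bound for r in self.reactions])
        return lb, ub

    def copy(self) -> "MetabolicModel":
        return _copy.deepcopy(self)

    # -- boundary classification ------------------------------------------
    def boundary_kind(self, rxn_id: str) -> str:
        """Classify a reaction as exchange / sink / demand / internal.

        The classes partition the reaction set: single-metabolite reactions
        are exchange (extracellular species, reversible), demand
        (consumption-only) or sink (anything else, i.e. a supply); all other
        reactions are internal.
        """
        r = self.reaction(rxn_id)
        if len(r.stoichiometry) != 1:
            return "internal"
        (met_id, coeff), = r.stoichiometry.items()
        met = self.metabolite(met_id)
        if met.compartment == "e" and r.lower_bound < 0 <= r.upper_bound:
            return "exchange"
        if coeff < 0 and r.lower_bound >= 0:
            return "demand"
        return "sink"

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions if self.boundary_kind(r.id) == "exchange"]


_BOUNDARY_PREFIX = {"exchange": "EX_", "sink": "SK_", "demand": "DM_"}


def add_boundary_reaction(
    model: MetabolicModel, metabolite_id: str, kind: str
) -> MetabolicModel:
    """Return a model with a boundary reaction for ``metabolite_id`` added.

    ``exchange`` (reversible, extracellular species only), ``sink``
    (unconditional supply/removal of a cytosolic species) and ``demand``
    (consumption only). Idempotent: if the canonical id already exists the
    model is returned unchanged.
    """
    if kind not in _BOUNDARY_PREFIX:
        raise ValueError(f"unknown boundary kind {kind!r}")
    met = model.metabolite(metabolite_id)  # KeyError if absent
    if kind == "exchange" and met.compartment != "e":
        raise ModelValidationError(
            f"exchange requested for non-extracellular metabolite {metabolite_id!r}"
        )
    rxn_id = _BOUNDARY_PREFIX[kind] + metabolite_id
    for r in model.reactions:  # an equivalent reaction may exist under any id
        if r.id == model.objective_reaction_id:
            continue  # a biomass drain is structurally a demand; never reuse it
        if list(r.stoichiometry) == [metabolite_id] and \
                model.boundary_kind(r.id) == kind:
            return model
    if rxn_id in set(model.reaction_ids):
        return model
    lb, ub = (0.0, DEFAULT_BOUND) if kind == "demand" else (-DEFAULT_BOUND, DEFAULT_BOUND)
    new = model.copy()
    new.reactions.append(
        Reaction(id=rxn_id, stoichiometry={metabolite_id: -1.0}, lower_bound=lb,
                 upper_bound=ub)
    )
    new.validate()
    return new


def set_bounds(model: MetabolicModel, rxn_id: str, lower: float | None = None,
               upper: float | None = None) -> MetabolicModel:
    """Functional bound edit returning a new model (original untouched)."""
    new = model.copy()
    r = new.reaction(rxn_id)
    if lower is not None:
        r.lower_bound = lower
    if upper is not None:
        r.upper_bound = upper
    if r.lower_bound > r.upper_bound:
        raise ModelValidationError(
            f"reaction {rxn_id!r}: bounds [{r.lower_bound}, {r.upper_bound}] inverted"
        )
    return new


def knock_out_reaction(model: MetabolicModel, rxn_id: str) -> MetabolicModel:
    model.reaction(rxn_id)  # raise KeyError if absent
    return set_bounds(model, rxn_id, lower=0.0, upper=0.0)


def reaction_table(model: MetabolicModel) -> "pd.DataFrame":
    """Reaction summary table (id, equation, bounds, gene rule, subsystem)."""
    import pandas as pd

    rows = [
        {
            "reaction": r.id,
            "equation": r.equation(),
            "lower_bound": r.lower_bound,
            "upper_bound": r.upper_bound,
            "gene_rule": r.gene_rule.to_string(),
            "subsystem": r.subsystem,
        }
        for r in model.reactions
    ]
    return pd.DataFrame(rows)
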