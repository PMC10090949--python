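"""Minimal-medium growth simulation, biomass yield and flux normalization.

Experimental uptake/secretion rates are usually reported in g gDW^-1 h^-1;
the simulation converts them to molar bounds, fixes the substrate exchange
lower bound to -uptake, imposes secretion floors (minimum secretion rates)
as positive lower bounds on product exchanges, and maximizes biomass. The
yield is mu divided by the mass-specific uptake (gDW per g substrate),
so yield * uptake_g = mu holds exactly for every result.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .lp import FbaSolution, FvaResult, InfeasibleProblemError, solve_fba
from .model import MetabolicModel, mass_rate_to_molar, set_bounds


@dataclass
class GrowthConstraintSet:
    """Uptake and secretion constraints for one growth condition.

    ``uptake`` is interpreted in g gDW^-1 h^-1 when ``mass_units`` is True
    (the default, matching how chemostat data are reported) and converted
    via the substrate formula; otherwise it is already molar.
    ``secretion_floors`` map exchange ids to minimum secretion rates
    (same unit convention). ``oxygen_open`` closes aerobic respiration when
    False; ``co2_floor`` is a minimum CO2 secretion rate (molar), default 0
    so the constraint is present but non-binding.
    """

    substrate_exchange: str
    uptake: float
    mass_units: bool = True
    secretion_floors: dict[str, float] = field(default_factory=dict)
    oxygen_open: bool = True
    oxygen_exchange: str | None = None
    co2_floor: float = 0.0
    co2_exchange: str | None = None

    def __post_init__(self) -> None:
        if self.uptake < 0:
            raise ValueError("uptake rate must be >= 0")
        if any(v < 0 for v in self.secretion_floors.values()):
            raise ValueError("secretion floors must be >= 0")


@dataclass
class GrowthResult:
    mu: float
    yield_g_per_g: float | None  # None when uptake is zero
    uptake_molar: float
    solution: FbaSolution


def _exchange_metabolite(model: MetabolicModel, exchange_id: str):
    rxn = model.reaction(exchange_id)
    (met_id,), = (list(rxn.stoichiometry.keys()),)
    return model.metabolite(met_id)


def _to_molar(model: MetabolicModel, exchange_id: str, rate: float,
              mass_units: bool) -> float:
    if not mass_units:
        return rate
    met = _exchange_metabolite(model, exchange_id)
    if met.formula is None:
        raise ValueError(
            f"metabolite {met.id!r} has no formula; cannot convert mass rate")
    return mass_rate_to_molar(rate, met.formula)


def simulate_minimal_growth(model: MetabolicModel,
                            constraints: GrowthConstraintSet) -> GrowthResult:
    """FBA growth under a substrate uptake bound and secretion floors."""
    uptake_molar = _to_molar(model, constraints.substrate_exchange,
                             constraints.uptake, constraints.mass_units)
    m = set_bounds(model, constraints.substrate_exchange, lower=-uptake_molar)
    for ex_id, floor in constraints.secretion_floors.items():
        floor_molar = _to_molar(model, ex_id, floor, constraints.mass_units)
        m = set_bounds(m, ex_id, lower=floor_molar)
    if constraints.co2_exchange is not None:
        m = set_bounds(m, constraints.co2_exchange, lower=constraints.co2_floor)
    if not constraints.oxygen_open:
        if constraints.oxygen_exchange is None:
            raise ValueError("oxygen_open=False requires oxygen_exchange id")
        m = set_bounds(m, constraints.oxygen_exchange, lower=0.0)
    sol = solve_fba(m)
    if not sol.optimal:
        binding = sorted(constraints.secretion_floors)
        raise InfeasibleProblemError(
            f"growth LP {sol.status}: uptake {constraints.uptake} on "
            f"{constraints.substrate_exchange} with secretion floors {binding}")
    mu = sol.objective_value
    yield_gg = None
    if constraints.uptake > 0 and constraints.mass_units:
        yield_gg = mu / constraints.uptake
    return GrowthResult(mu=mu, yield_g_per_g=yield_gg,
                        uptake_molar=uptake_molar, solution=sol)


def normalize_to_substrate(fluxes: FbaSolution | FvaResult,
                           substrate_uptake: float):
    """Express fluxes (or FVA intervals) as percent of substrate uptake."""
    if substrate_uptake <= 0:
        raise ValueError("substrate uptake must be positive")
    scale = 100.0 / substrate_uptake
    if isinstance(fluxes, FvaResult):
        return {rid: (lo * scale, hi * scale)
                for rid, (lo, hi) in fluxes.ranges.items()}
    return {rid: v * scale for rid, v in fluxes.fluxes.items()}


def pearson_correlation(x, y) -> float:
    """Sample Pearson correlation; errors on constant input (undefined)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors with >= 3 entries")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant vectors")
    r, _ = stats.pearsonr(x, y)
    return float(r)
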