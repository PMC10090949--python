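"""Substrate viability assays, gene knockouts and confusion-matrix scoring.

Two in-silico assay modes mirror how a carbon source can be supplied to a
GSMM: an extracellular source (which forces the model to use its
transporters) or a direct cytoplasmic supply (which bypasses transport and
isolates the catabolic capability). Comparing the two localizes
false-negative growth predictions to missing transport reactions.

Gene essentiality follows the standard single-deletion protocol: delete a
gene, disable every reaction whose GPR rule is no longer satisfiable, and
re-solve; a gene is essential when the knockout optimum falls below
tau_ess (default 0.9) times the wild-type growth rate, or the LP becomes
infeasible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .gpr import GeneRule
from .lp import solve_fba
from .model import (MetabolicModel, add_boundary_reaction, parse_formula,
                    set_bounds)

#: growth-zero tolerance: mu above this counts as "viable" (LP noise floor)
GROWTH_TOL = 1e-6
#: formulas treated as inorganic carbon (kept open for secretion only)
_INORGANIC_CARBON = {"CO2", "CHO3", "HCO3", "CO3", "CH2O3"}


@dataclass
class SubstratePanel:
    """Experimental viability labels: substrate metabolite id -> bool."""

    labels: dict[str, bool]
    assay_ids: dict[str, str] = field(default_factory=dict)


@dataclass
class ConfusionMatrix:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


@dataclass
class EssentialityResult:
    tau_ess: float
    mu_wt: float
    mu_ko: dict[str, float | None]  # None = infeasible knockout

    @property
    def essential_genes(self) -> set[str]:
        out = set()
        for gene, mu in self.mu_ko.items():
            if mu is None or mu < self.tau_ess * self.mu_wt:
                out.add(gene)
        return out


def evaluate_gene_rule(rule: GeneRule, deleted: set[str]) -> bool:
    """True iff the reaction stays available with ``deleted`` genes removed."""
    return rule.evaluate(deleted)


def _carbon_bearing(model: MetabolicModel, met_id: str) -> bool:
    met = model.metabolite(met_id)
    if met.formula is None:
        return False
    return "C" in parse_formula(met.formula)


def close_carbon_exchanges(model: MetabolicModel,
                           keep_open: set[str] = frozenset()) -> MetabolicModel:
    """Close uptake of every carbon-bearing exchange except ``keep_open``.

    Inorganic carbon (CO2 / bicarbonate) exchanges stay open for secretion
    only (lower bound 0): that prevents spurious growth on carbon fixation
    while still letting the model vent CO2.
    """
    m = model
    for rxn in model.exchange_reactions():
        if rxn.id in keep_open:
            continue
        (met_id,), = (list(rxn.stoichiometry.keys()),)
        met = model.metabolite(met_id)
        if met.formula is not None and met.formula in _INORGANIC_CARBON:
            m = set_bounds(m, rxn.id, lower=0.0)
        elif _carbon_bearing(model, met_id):
            m = set_bounds(m, rxn.id, lower=0.0)
    return m


def substrate_viability(model: MetabolicModel, substrate_id: str, mode: str,
                        uptake: float = 10.0) -> bool | None:
    """Can the model grow on ``substrate_id`` as sole carbon source?

    ``mode='extracellular'`` supplies the ``_e`` species through an exchange
    (transport required); ``mode='cytoplasmic'`` supplies the ``_c`` species
    through a sink. Returns None ("not in model") when the species is
    absent, so panel runs never crash on unmapped substrates.
    """
    if mode not in ("extracellular", "cytoplasmic"):
        raise ValueError(f"unknown assay mode {mode!r}")
    try:
        met = model.metabolite(substrate_id)
    except KeyError:
        return None
    if mode == "extracellular" and met.compartment != "e":
        return None
    if mode == "cytoplasmic" and met.compartment == "e":
        return None

    if mode == "extracellular":
        m = add_boundary_reaction(model, substrate_id, "exchange")
        source = "EX_" + substrate_id if "EX_" + substrate_id in m.reaction_ids \
            else next(r.id for r in m.exchange_reactions()
                      if list(r.stoichiometry) == [substrate_id])
    else:
        m = add_boundary_reaction(model, substrate_id, "sink")
        source = "SK_" + substrate_id
    m = close_carbon_exchanges(m, keep_open={source})
    m = set_bounds(m, source, lower=-uptake, upper=0.0 if mode == "cytoplasmic"
                   else m.reaction(source).upper_bound)
    sol = solve_fba(m)
    return bool(sol.optimal and sol.objective_value > GROWTH_TOL)


def run_substrate_panel(model: MetabolicModel, panel: SubstratePanel,
                        mode: str = "extracellular",
                        uptake: float = 10.0) -> dict[str, bool | None]:
    return {sub: substrate_viability(model, sub, mode, uptake)
            for sub in panel.labels}


def score_panel(predictions: dict[str, bool | None],
                panel: SubstratePanel) -> ConfusionMatrix:
    """Confusion matrix with the experimental label as ground truth.

    Substrates absent from the model (prediction None) are excluded, as the
    published accuracy is computed only over carbon sources represented in
    the model.
    """
    if len(set(panel.labels)) != len(panel.labels):
        raise ValueError("duplicated substrate in panel")
    cm = ConfusionMatrix()
    for sub, truth in panel.labels.items():
        if sub not in predictions:
            raise ValueError(f"no prediction for panel substrate {sub!r}")
        pred = predictions[sub]
        if pred is None:
            continue
        if truth and pred:
            cm.tp += 1
        elif truth and not pred:
            cm.fn += 1
        elif not truth and pred:
            cm.fp += 1
        else:
            cm.tn += 1
    return cm


def apply_gene_knockout(model: MetabolicModel,
                        genes: set[str]) -> MetabolicModel:
    """Close (bounds -> 0) every reaction whose GPR becomes unsatisfied."""
    m = model
    for rxn in model.reactions:
        if rxn.gene_rule.is_empty:
            continue
        if not rxn.gene_rule.evaluate(genes):
            m = set_bounds(m, rxn.id, lower=0.0, upper=0.0)
    return m


def essentiality_screen(model: MetabolicModel,
                        tau_ess: float = 0.9) -> EssentialityResult:
    """Single-gene deletion screen against the wild-type optimum."""
    wt = solve_fba(model)
    if not wt.optimal or wt.objective_value <= GROWTH_TOL:
        raise ValueError("wild-type growth is zero; essentiality screen undefined")
    mu_wt = wt.objective_value
    mu_ko: dict[str, float | None] = {}
    for gene in model.genes:
        ko = apply_gene_knockout(model, {gene})
        if ko is model:  # gene appears in no rule; nothing changed
            mu_ko[gene] = mu_wt
            continue
        sol = solve_fba(ko)
        mu_ko[gene] = sol.objective_value if sol.optimal else None
    return EssentialityResult(tau_ess=tau_ess, mu_wt=mu_wt, mu_ko=mu_ko)


def essentiality_confusion(predicted: set[str], reference: set[str],
                           universe: set[str]) -> ConfusionMatrix:
    if not predicted <= universe or not reference <= universe:
        raise ValueError("predicted and reference sets must be subsets of universe")
    tp = len(predicted & reference)
    fp = len(predicted - reference)
    fn = len(reference - predicted)
    tn = len(universe) - tp - fp - fn
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)
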