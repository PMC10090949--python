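"""Simplified resource balance analysis (RBA-lite).

Resource balance analysis extends FBA by making the proteome explicit: each
flux needs enzyme (|v_j| <= kapp_j * E_j), protein synthesis needs
translation machinery (mu * sum_p len_p * c_p <= k_transl * M_ribosome, and
analogously for other macromolecular processes), and the total protein pool
is pinned to the measured protein weight fraction of dry mass
(sum_p mass_p * c_p = P_total). At a fixed growth rate mu everything is
linear, so the maximal feasible mu is found by bisection over LP
feasibility checks. Apparent catalytic rates (kapp) are calibrated from
flux sampling and proteomics-derived enzyme concentrations; enzymes not
detected fall back to a default of 619,200 h^-1 (an average kcat of
172 s^-1).

This is deliberately "lite": one cytoplasmic density compartment, no
membrane-density constraint, and only the named macromolecular processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .lp import FluxSample
from .model import MetabolicModel, molecular_weight

#: default apparent catalytic rate for undetected enzymes: 172 s^-1 * 3600
DEFAULT_KAPP = 619_200.0
#: default protein weight fraction of dry mass (g protein / gDW)
DEFAULT_P_TOTAL = 0.47


@dataclass
class EnzymeSpec:
    """Catalytic capacity of one reaction's enzyme."""

    reaction_id: str
    composition: dict[str, float]  # protein id -> copies per complex
    kapp_forward: float = DEFAULT_KAPP
    kapp_backward: float = DEFAULT_KAPP

    def __post_init__(self) -> None:
        if self.kapp_forward <= 0 or self.kapp_backward <= 0:
            raise ValueError(f"enzyme {self.reaction_id!r}: kapp must be > 0")
        if not self.composition:
            raise ValueError(f"enzyme {self.reaction_id!r}: empty composition")


@dataclass
class MachinerySpec:
    """A macromolecular process (translation, folding, ...).

    ``capacity_rate`` is in elementary units per machine per hour (aa/h for
    translation); the process load is mu * sum over products of
    demand-per-product (protein length in aa for translation) times the
    product's concentration, plus mu * demand_constant for per-gDW demands
    such as DNA replication.
    """

    process: str
    composition: dict[str, float]  # protein id -> copies per machine
    capacity_rate: float
    demand_per_protein: str = "length"  # or "none"
    demand_constant: float = 0.0

    def __post_init__(self) -> None:
        if self.capacity_rate <= 0:
            raise ValueError(f"process {self.process!r}: capacity rate must be > 0")


@dataclass
class ProteinSpec:
    length_aa: float
    mass_g_per_mmol: float


@dataclass
class RbaProblem:
    model: MetabolicModel
    proteins: dict[str, ProteinSpec]
    enzymes: list[EnzymeSpec]
    machinery: list[MachinerySpec]
    p_total: float = DEFAULT_P_TOTAL
    #: metabolite drained by protein synthesis (mmol per aa), or None
    aa_species: str | None = None
    #: macrocomponent production targets: species -> g per gDW
    macro_targets: dict[str, float] = field(default_factory=dict)
    #: enforced secretion rates: exchange id -> mmol gDW^-1 h^-1
    enforced_secretion: dict[str, float] = field(default_factory=dict)
    #: non-catalytic proteins with free concentrations (storage, structural)
    free_proteins: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.p_total <= 1:
            raise ValueError("p_total must lie in (0, 1]")
        if any(t < 0 for t in self.macro_targets.values()):
            raise ValueError("macrocomponent targets must be >= 0")


@dataclass
class RbaSolution:
    mu: float
    fluxes: dict[str, float]
    enzyme_conc: dict[str, float]      # mmol/gDW per enzyme (by reaction id)
    machinery_conc: dict[str, float]   # mmol/gDW per process
    protein_conc: dict[str, float]     # mmol/gDW per protein
    bracket_exhausted: bool = False

    def substrate_uptake_g(self, exchange_id: str,
                           formula: str) -> float:
        """Uptake through an exchange in g gDW^-1 h^-1 (positive value)."""
        return -self.fluxes[exchange_id] * molecular_weight(formula) / 1000.0


class _RbaLp:
    """Assembled LP structure; mu enters the constraint matrix linearly."""

    def __init__(self, problem: RbaProblem):
        self.p = problem
        model = problem.model
        self.rxn_ids = model.reaction_ids
        self.enz_ids = [e.reaction_id for e in problem.enzymes]
        self.mach_ids = [m.process for m in problem.machinery]
        self.free_ids = list(problem.free_proteins)
        self.n_v = len(self.rxn_ids)
        self.n_e = len(self.enz_ids)
        self.n_m = len(self.mach_ids)
        self.n_f = len(self.free_ids)
        self.S = model.stoichiometric_matrix()
        self.lb, self.ub = model.bounds_arrays()
        for ex, rate in problem.enforced_secretion.items():
            j = self.rxn_ids.index(ex)
            self.lb[j] = max(self.lb[j], rate)

        # protein concentration as linear map of (E, M, F) variables
        prot_ids = sorted(problem.proteins)
        self.prot_ids = prot_ids
        self.P = np.zeros((len(prot_ids), self.n_e + self.n_m + self.n_f))
        for k, enz in enumerate(problem.enzymes):
            for prot, copies in enz.composition.items():
                self.P[prot_ids.index(prot), k] = copies
        for k, mach in enumerate(problem.machinery):
            for prot, copies in mach.composition.items():
                self.P[prot_ids.index(prot), self.n_e + k] = copies
        for k, prot in enumerate(self.free_ids):
            self.P[prot_ids.index(prot), self.n_e + self.n_m + k] = 1.0
        self.lengths = np.array([problem.proteins[p].length_aa for p in prot_ids])
        self.masses = np.array([problem.proteins[p].mass_g_per_mmol for p in prot_ids])

    def n_vars(self) -> int:
        return self.n_v + self.n_e + self.n_m + self.n_f

    def build(self, mu: float):
        p = self.p
        n = self.n_vars()
        nv, ne, nm = self.n_v, self.n_e, self.n_m

        # metabolite balance: S v - (aa drain + macro targets) * mu = 0
        A_eq = np.zeros((self.S.shape[0] + 1, n))
        A_eq[:self.S.shape[0], :nv] = self.S
        b_eq = np.zeros(self.S.shape[0] + 1)
        met_index = {m: i for i, m in enumerate(p.model.metabolite_ids)}
        if p.aa_species is not None:
            row = met_index[p.aa_species]
            # consumption of aa by protein dilution: -mu * len . (P x)
            A_eq[row, nv:] -= mu * (self.lengths @ self.P)
        for species, grams in p.macro_targets.items():
            met = p.model.metabolite(species)
            if met.formula is None:
                raise ValueError(f"macro target {species!r} has no formula")
            mmol = grams / molecular_weight(met.formula) * 1000.0
            b_eq[met_index[species]] += mu * mmol
        # density: mass . (P x) = P_total
        A_eq[-1, nv:] = self.masses @ self.P
        b_eq[-1] = p.p_total

        rows_ub = []
        rhs_ub = []
        # enzyme capacity: v_j <= kf * E_j ; -v_j <= kb * E_j
        for k, enz in enumerate(p.enzymes):
            j = self.rxn_ids.index(enz.reaction_id)
            r = np.zeros(n)
            r[j] = 1.0
            r[nv + k] = -enz.kapp_forward
            rows_ub.append(r)
            rhs_ub.append(0.0)
            r = np.zeros(n)
            r[j] = -1.0
            r[nv + k] = -enz.kapp_backward
            rows_ub.append(r)
            rhs_ub.append(0.0)
        # process capacity: mu * demand(c) <= rate * M
        for k, mach in enumerate(p.machinery):
            r = np.zeros(n)
            if mach.demand_per_protein == "length":
                r[nv:] += mu * (self.lengths @ self.P)
            r[nv + ne + k] -= mach.capacity_rate
            rows_ub.append(r)
            rhs_ub.append(-mu * mach.demand_constant)
        A_ub = np.array(rows_ub) if rows_ub else None
        b_ub = np.array(rhs_ub) if rows_ub else None

        bounds = list(zip(self.lb, self.ub)) + [(0, None)] * (ne + nm + self.n_f)
        return A_eq, b_eq, A_ub, b_ub, bounds

    def solve(self, mu: float, parsimonious: bool = False):
        A_eq, b_eq, A_ub, b_ub, bounds = self.build(mu)
        c = np.zeros(self.n_vars())
        if parsimonious:
            c[self.n_v:self.n_v + self.n_e + self.n_m] = 1.0
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                      bounds=bounds, method="highs")
        return res


def solve_rba(problem: RbaProblem, mu_lo: float = 1e-3, mu_hi: float = 5.0,
              tol: float = 1e-4) -> RbaSolution:
    """Largest feasible growth rate by bisection over LP feasibility.

    Feasibility is monotone in mu (growing faster only adds demands), so
    bisection converges to within ``tol``. Raises if already infeasible at
    ``mu_lo``; if still feasible at ``mu_hi`` the solution is returned with
    ``bracket_exhausted=True``. The final solve is parsimonious (minimal
    total enzyme + machinery), which leaves spare proteome in the free
    (non-catalytic) pool and makes binding capacities tight.
    """
    lp = _RbaLp(problem)
    if lp.solve(mu_lo).status != 0:
        raise ValueError(f"RBA problem infeasible at mu_lo={mu_lo}")
    exhausted = False
    if lp.solve(mu_hi).status == 0:
        mu_star = mu_hi
        exhausted = True
    else:
        lo, hi = mu_lo, mu_hi
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if lp.solve(mid).status == 0:
                lo = mid
            else:
                hi = mid
        mu_star = lo
    res = lp.solve(mu_star, parsimonious=True)
    if res.status != 0:  # pragma: no cover - should not happen
        raise RuntimeError("final RBA solve failed at the bisected optimum")
    x = res.x
    nv, ne, nm = lp.n_v, lp.n_e, lp.n_m
    conc = lp.P @ x[nv:]
    return RbaSolution(
        mu=mu_star,
        fluxes=dict(zip(lp.rxn_ids, map(float, x[:nv]))),
        enzyme_conc=dict(zip(lp.enz_ids, map(float, x[nv:nv + ne]))),
        machinery_conc=dict(zip(lp.mach_ids, map(float, x[nv + ne:nv + ne + nm]))),
        protein_conc=dict(zip(lp.prot_ids, map(float, conc))),
        bracket_exhausted=exhausted,
    )


def protein_concentrations(counts: dict[str, float],
                           masses: dict[str, float],
                           p_total: float = DEFAULT_P_TOTAL) -> dict[str, float]:
    """Scale relative spectral counts to absolute mmol/gDW concentrations.

    The mass share of protein p is count_p*mass_p / sum(count*mass); its
    concentration is P_total * share_p / mass_p. Doubling all counts leaves
    the result unchanged (only shares matter).
    """
    if not counts or all(v == 0 for v in counts.values()):
        raise ValueError("zero total spectral counts")
    if any(v < 0 for v in counts.values()):
        raise ValueError("negative spectral count")
    mass_total = sum(counts[p] * masses[p] for p in counts)
    return {p: p_total * (counts[p] * masses[p] / mass_total) / masses[p]
            for p in counts}


def enzyme_concentration(enzyme: EnzymeSpec,
                         protein_conc: dict[str, float]) -> float:
    """Limiting-subunit rule: min over subunits of concentration / copies."""
    return min(protein_conc.get(p, 0.0) / copies
               for p, copies in enzyme.composition.items())


def calibrate_kapp(flux_sample: FluxSample,
                   protein_conc: dict[str, float],
                   enzymes: list[EnzymeSpec],
                   default_kapp: float = DEFAULT_KAPP) -> list[EnzymeSpec]:
    """Apparent catalytic rates from sampled fluxes and enzyme abundance.

    kapp_j = mean |sampled flux_j| / E_j when both are positive, otherwise
    the default (undetected enzyme or zero flux).
    """
    if flux_sample.n < 1:
        raise ValueError("empty flux sample")
    mean_abs = flux_sample.mean_absolute_flux()
    out = []
    for enz in enzymes:
        e_conc = enzyme_concentration(enz, protein_conc)
        flux = mean_abs.get(enz.reaction_id, 0.0)
        if e_conc > 0 and flux > 0:
            kapp = flux / e_conc
        else:
            kapp = default_kapp
        out.append(EnzymeSpec(reaction_id=enz.reaction_id,
                              composition=dict(enz.composition),
                              kapp_forward=kapp, kapp_backward=kapp))
    return out


def allocation_summary(solution: RbaSolution,
                       proteins: dict[str, ProteinSpec],
                       category_map: dict[str, str]) -> dict[str, float]:
    """Fractions of total amino-acid mass per protein category.

    Uncategorized proteins land in "other"; translational machinery is
    conventionally ribosomal proteins plus elongation factors.
    """
    weights: dict[str, float] = {}
    for prot, conc in solution.protein_conc.items():
        cat = category_map.get(prot, "other")
        weights[cat] = weights.get(cat, 0.0) + conc * proteins[prot].length_aa
    total = sum(weights.values())
    if total <= 0:
        raise ValueError("no expressed protein mass to allocate")
    return {cat: w / total for cat, w in weights.items()}


def expressed_gene_coverage(solution: RbaSolution, detected: set[str],
                            threshold: float = 1e-6) -> float:
    """Fraction of predicted-expressed proteins that were also detected."""
    predicted = {p for p, c in solution.protein_conc.items() if c > threshold}
    if not predicted:
        raise ValueError(f"no protein above threshold {threshold}")
    return len(predicted & detected) / len(predicted)
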