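"""Linear-programming engine: FBA, FVA and near-optimal flux sampling.

Flux balance analysis solves max/min c.v subject to S.v = 0 and
lb <= v <= ub with the HiGHS solver. Flux variability analysis re-solves
per-reaction min/max problems under an added objective floor
c.v >= fraction * mu*. Sampling explores the same fraction-constrained
polytope with a seeded hit-and-run random walk restricted to the null space
of S, so every sample is mass-balanced by construction.

Only the objective *value* of an FBA solve is guaranteed deterministic;
the returned flux vector is one arbitrary optimal vertex (alternate optima
are ubiquitous in genome-scale models), so analyses that depend on a
specific flux should use FVA or sampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from scipy.optimize import linprog

from .model import MetabolicModel

#: feasibility tolerance handed to the solver
FEAS_TOL = 1e-9
#: tolerance used when *reporting* / asserting feasibility of results
REPORT_TOL = 1e-6


class InfeasibleProblemError(RuntimeError):
    """The LP (or its fraction-constrained restriction) has no solution."""


@dataclass
class FbaSolution:
    status: str  # optimal | infeasible | unbounded
    objective_value: float | None
    fluxes: dict[str, float] = field(default_factory=dict)

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def flux_vector(self, model: MetabolicModel) -> np.ndarray:
        return np.array([self.fluxes[r] for r in model.reaction_ids])


@dataclass
class FvaResult:
    fraction: float
    ranges: dict[str, tuple[float, float]]
    failed: list[str] = field(default_factory=list)

    def minimum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][0]

    def maximum(self, rxn_id: str) -> float:
        return self.ranges[rxn_id][1]


@dataclass
class FluxSample:
    n: int
    seed: int
    reaction_ids: list[str]
    matrix: np.ndarray  # shape (n, n_reactions)

    def fluxes(self, rxn_id: str) -> np.ndarray:
        return self.matrix[:, self.reaction_ids.index(rxn_id)]

    def mean_absolute_flux(self) -> dict[str, float]:
        means = np.abs(self.matrix).mean(axis=0)
        return dict(zip(self.reaction_ids, means))


_STATUS = {0: "optimal", 2: "infeasible", 3: "unbounded"}


def _solve(c, A_eq, b_eq, A_ub, b_ub, bounds):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq,
                  bounds=bounds, method="highs",
                  options={"primal_feasibility_tolerance": FEAS_TOL,
                           "dual_feasibility_tolerance": FEAS_TOL})
    return res


def solve_fba(model: MetabolicModel, objective_sense: str = "max") -> FbaSolution:
    """Maximize (or minimize) the model objective over {S.v = 0, lb<=v<=ub}."""
    if objective_sense not in ("max", "min"):
        raise ValueError(f"objective_sense must be 'max' or 'min', got {objective_sense!r}")
    S = model.stoichiometric_matrix()
    c = model.objective_vector()
    lb, ub = model.bounds_arrays()
    sign = -1.0 if objective_sense == "max" else 1.0
    res = _solve(sign * c, S, np.zeros(S.shape[0]), None, None, list(zip(lb, ub)))
    status = _STATUS.get(res.status, "failed")
    if status != "optimal":
        return FbaSolution(status=status, objective_value=None)
    return FbaSolution(
        status="optimal",
        objective_value=float(c @ res.x),
        fluxes=dict(zip(model.reaction_ids, (float(x) for x in res.x))),
    )


def run_fva(model: MetabolicModel, fraction: float,
            reaction_ids: list[str] | None = None) -> FvaResult:
    """Per-reaction flux min/max with the objective held at >= fraction*mu*.

    Reactions whose sub-problems fail numerically are flagged in
    ``result.failed`` and the run continues.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    base = solve_fba(model)
    if not base.optimal:
        raise InfeasibleProblemError(
            f"base FBA not optimal (status {base.status}); FVA undefined")
    mu_star = base.objective_value

    S = model.stoichiometric_matrix()
    cvec = model.objective_vector()
    lb, ub = model.bounds_arrays()
    bounds = list(zip(lb, ub))
    # objective floor: -c.v <= -fraction*mu*
    A_ub = -cvec.reshape(1, -1)
    b_ub = np.array([-fraction * mu_star])

    if reaction_ids is None:
        reaction_ids = model.reaction_ids
    idx = {r: model.reaction_ids.index(r) for r in reaction_ids}

    ranges: dict[str, tuple[float, float]] = {}
    failed: list[str] = []
    for rid in reaction_ids:
        obj = np.zeros(len(model.reactions))
        obj[idx[rid]] = 1.0
        lo = _solve(obj, S, np.zeros(S.shape[0]), A_ub, b_ub, bounds)
        hi = _solve(-obj, S, np.zeros(S.shape[0]), A_ub, b_ub, bounds)
        if lo.status != 0 or hi.status != 0:
            failed.append(rid)
            continue
        ranges[rid] = (float(lo.x[idx[rid]]), float(hi.x[idx[rid]]))
    return FvaResult(fraction=fraction, ranges=ranges, failed=failed)


def sample_fluxes(model: MetabolicModel, n: int, fraction: float = 1.0,
                  seed: int = 0, method: str = "hit-and-run",
                  warmup_steps: int = 100) -> FluxSample:
    """Sample ``n`` feasible flux vectors from the near-optimal polytope.

    ``hit-and-run``: a seeded random walk along null-space directions of S
    starting from an FBA vertex, taking ``warmup_steps`` chord steps per
    recorded sample. ``random-objective``: each sample optimizes a random
    secondary objective over the polytope (always a vertex). Both satisfy
    the same feasibility contract and are deterministic given the seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = solve_fba(model)
    if not base.optimal:
        raise InfeasibleProblemError("base FBA not optimal; polytope empty")
    mu_star = base.objective_value

    S = model.stoichiometric_matrix()
    cvec = model.objective_vector()
    lb, ub = model.bounds_arrays()
    floor = fraction * mu_star
    rng = np.random.default_rng(seed)

    if method == "random-objective":
        A_ub = -cvec.reshape(1, -1)
        b_ub = np.array([-floor])
        rows = []
        for _ in range(n):
            obj = rng.standard_normal(len(model.reactions))
            res = _solve(obj, S, np.zeros(S.shape[0]), A_ub, b_ub, list(zip(lb, ub)))
            if res.status != 0:
                raise InfeasibleProblemError("fraction-constrained polytope is empty")
            rows.append(res.x)
        return FluxSample(n=n, seed=seed, reaction_ids=list(model.reaction_ids),
                          matrix=np.array(rows))

    if method != "hit-and-run":
        raise ValueError(f"unknown sampling method {method!r}")

    x = base.flux_vector(model)
    N = linalg.null_space(S)
    if N.shape[1] == 0:
        return FluxSample(n=n, seed=seed, reaction_ids=list(model.reaction_ids),
                          matrix=np.tile(x, (n, 1)))
    # shrink the box a hair so accumulated round-off cannot leave it
    eps = 1e-9
    rows = []
    for _ in range(n):
        for _ in range(warmup_steps):
            d = N @ rng.standard_normal(N.shape[1])
            norm = np.linalg.norm(d)
            if norm < 1e-12:
                continue
            d /= norm
            t_lo, t_hi = _chord(x, d, lb + eps, ub - eps, cvec, floor)
            if t_hi <= t_lo:
                continue
            x = x + rng.uniform(t_lo, t_hi) * d
        rows.append(x.copy())
    return FluxSample(n=n, seed=seed, reaction_ids=list(model.reaction_ids),
                      matrix=np.array(rows))


def _chord(x, d, lb, ub, cvec, floor):
    """Feasible step range [t_lo, t_hi] along direction d from point x."""
    t_lo, t_hi = -np.inf, np.inf
    with np.errstate(divide="ignore", invalid="ignore"):
        for bound, is_upper in ((ub, True), (lb, False)):
            gap = bound - x
            t = gap / d
            pos = d > 1e-12 if is_upper else d < -1e-12
            neg = d < -1e-12 if is_upper else d > 1e-12
            if pos.any():
                t_hi = min(t_hi, np.min(t[pos]))
            if neg.any():
                t_lo = max(t_lo, np.max(t[neg]))
    # growth floor c.(x + t d) >= floor
    cd = float(cvec @ d)
    gap = float(cvec @ x) - floor
    if abs(cd) > 1e-12:
        t_star = -gap / cd
        if cd > 0:
            t_lo = max(t_lo, t_star)
        else:
            t_hi = min(t_hi, t_star)
    elif gap < -1e-9:
        return 0.0, 0.0
    # clamp around current point
    return max(t_lo, -1e6), min(t_hi, 1e6)


def active_reactions(sample: FluxSample, threshold: float = 1e-6) -> set[str]:
    """Reactions with |flux| >= threshold in at least one sampled vector.

    The conventional activity floor is 1e-6 mmol gDW^-1 h^-1, below the
    numerical noise of the solver.
    """
    if sample.n < 1 or sample.matrix.size == 0:
        raise ValueError("empty flux sample")
    active_mask = (np.abs(sample.matrix) >= threshold).any(axis=0)
    return {rid for rid, act in zip(sample.reaction_ids, active_mask) if act}
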