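"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: the LP oracle
enumerates basic feasible points of the flux polytope directly from the
stoichiometric matrix, and the gene-rule oracle evaluates the rule string
with the Python interpreter instead of the package's parser/evaluator.
"""

from __future__ import annotations

import itertools
import re

import numpy as np


def enumerate_polytope_optimum(model, tol: float = 1e-7) -> float:
    """Brute-force maximum of the objective over {S v = 0, lb <= v <= ub}.

    Every vertex of the bounded polytope has at least n - rank(S) variables
    pinned at a bound; all such pinnings are enumerated and the remaining
    square system solved. Practical only for tiny networks (<= ~8 reactions).
    """
    S = model.stoichiometric_matrix()
    lb, ub = model.bounds_arrays()
    c = model.objective_vector()
    n = S.shape[1]
    rank = np.linalg.matrix_rank(S)
    n_fix = n - rank
    best = None
    for fixed in itertools.combinations(range(n), n_fix):
        free = [j for j in range(n) if j not in fixed]
        A = S[:, free]
        for pattern in itertools.product((0, 1), repeat=n_fix):
            vals = np.array([lb[j] if p == 0 else ub[j]
                             for j, p in zip(fixed, pattern)])
            rhs = -S[:, list(fixed)] @ vals if n_fix else np.zeros(S.shape[0])
            sol, *_ = np.linalg.lstsq(A, rhs, rcond=None)
            v = np.zeros(n)
            v[list(fixed)] = vals
            v[free] = sol
            if np.abs(S @ v).max() > tol:
                continue
            if (v < lb - tol).any() or (v > ub + tol).any():
                continue
            val = float(c @ v)
            if best is None or val > best:
                best = val
    assert best is not None, "polytope appears empty (no vertex found)"
    return best


def eval_rule_string(rule: str, present: set[str]) -> bool:
    """Evaluate an and/or gene-rule string via the Python interpreter."""
    if not rule.strip():
        return True

    def sub(match: re.Match) -> str:
        tok = match.group(0)
        if tok.lower() in ("and", "or"):
            return tok.lower()
        return str(tok in present)

    expr = re.sub(r"[^\s()]+", sub, rule)
    return bool(eval(expr))  # noqa: S307 - controlled test input


def random_rule(rng: np.random.Generator, genes: list[str], depth: int = 0) -> str:
    """A random parenthesized and/or rule over the given gene pool."""
    if depth >= 3 or rng.random() < 0.4:
        return str(rng.choice(genes))
    op = " and " if rng.random() < 0.5 else " or "
    k = int(rng.integers(2, 4))
    parts = [random_rule(rng, genes, depth + 1) for _ in range(k)]
    body = op.join(parts)
    return f"({body})" if rng.random() < 0.5 else body
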