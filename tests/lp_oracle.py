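"""Independent LP oracles for cross-checking FBA/FVA results.

Two routes, both independent of the optlang/GLPK path the package
uses:  :func:`oracle_fba` / :func:`oracle_fva` solve the same LP with
``scipy.optimize.linprog`` (HiGHS), and :func:`brute_force_max`
enumerates candidate basic feasible solutions directly for the
smallest fixtures (a vertex of {S·v = 0, l <= v <= u} fixes at least
n - rank(S) variables at a bound; the remainder solves a linear
system).
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
from scipy.optimize import linprog


def _arrays(gem, objective=None):
    cm = gem.cobra_model
    S = gem.stoichiometric_matrix()
    lb = np.array([r.lower_bound for r in cm.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in cm.reactions], dtype=float)
    rids = [r.id for r in cm.reactions]
    obj = objective or gem.objective_id
    c = np.zeros(len(rids))
    c[rids.index(obj)] = 1.0
    return S, lb, ub, c, rids


def oracle_fba(gem, objective=None, sense="max"):
    """Max (or min) objective flux via scipy linprog; NaN if infeasible."""
    S, lb, ub, c, _ = _arrays(gem, objective)
    sign = -1.0 if sense == "max" else 1.0
    res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if not res.success:
        return float("nan")
    return float(sign * res.fun)


def oracle_fva(gem, reactions, gamma=1.0, objective=None):
    """Per-reaction [min, max] at >= gamma of the optimum, via linprog."""
    S, lb, ub, c_obj, rids = _arrays(gem, objective)
    z0 = oracle_fba(gem, objective)
    assert not np.isnan(z0), "oracle base problem infeasible"
    # w'V >= gamma*z0  as  -w'V <= -gamma*z0 (+ tiny slack)
    a_ub = -c_obj.reshape(1, -1)
    b_ub = np.array([-(gamma * z0 - 1e-9 * max(1.0, abs(z0)))])
    out = {}
    for rid in reactions:
        c = np.zeros(len(rids))
        c[rids.index(rid)] = 1.0
        lohi = []
        for sign in (1.0, -1.0):
            res = linprog(sign * c, A_eq=S, b_eq=np.zeros(S.shape[0]),
                          A_ub=a_ub, b_ub=b_ub,
                          bounds=list(zip(lb, ub)), method="highs")
            assert res.success, f"oracle FVA subproblem failed for {rid}"
            lohi.append(sign * res.fun)
        out[rid] = (float(lohi[0]), float(lohi[1]))
    return z0, out


def brute_force_max(gem, objective=None, tol=1e-8):
    """Exhaustive enumeration of candidate vertices (tiny models only).

    Returns the best feasible objective value, or None if no candidate
    vertex is feasible.  Only valid when every choice of n - rank(S)
    non-basic variables leaves a full-column-rank basic system — true
    for the mini fixtures this is applied to.
    """
    S, lb, ub, c, _ = _arrays(gem, objective)
    m, n = S.shape
    rank = np.linalg.matrix_rank(S)
    n_free = n - rank
    best = None
    for free in combinations(range(n), n_free):
        basic = [j for j in range(n) if j not in free]
        SB = S[:, basic]
        for vals in product(*[(lb[j], ub[j]) for j in free]):
            rhs = -S[:, list(free)] @ np.asarray(vals)
            sol, *_ = np.linalg.lstsq(SB, rhs, rcond=None)
            if np.linalg.norm(SB @ sol - rhs) > tol:
                continue
            v = np.zeros(n)
            v[list(free)] = vals
            v[basic] = sol
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                val = float(c @ v)
                if best is None or val > best:
                    best = val
    return best
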