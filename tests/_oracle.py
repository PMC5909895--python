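"""Independent solvers used only to cross-check the package's results.

Two routes, both bypassing the optlang/GLPK stack the package solves with:

* :func:`lp_solve` — scipy's HiGHS simplex on the raw stoichiometric matrix;
* :func:`enumerate_vertices` / :func:`vertex_optimum` — brute-force basic
  feasible solutions of {S·v = 0, lb ≤ v ≤ ub} for tiny networks, by fixing
  every choice of n − rank(S) coordinates at a bound and solving the square
  system.
"""

from __future__ import annotations

import itertools

import numpy as np
from cobra.util.array import create_stoichiometric_matrix
from scipy.optimize import linprog


def model_arrays(model):
    s_mat = create_stoichiometric_matrix(model)
    rids = [r.id for r in model.reactions]
    lb = np.array([r.lower_bound for r in model.reactions], dtype=float)
    ub = np.array([r.upper_bound for r in model.reactions], dtype=float)
    return s_mat, rids, lb, ub


def lp_solve(model, objective_rid, sense="max", extra_fix=None):
    """Solve the model's FBA problem with scipy HiGHS; returns (status, z, v)."""
    s_mat, rids, lb, ub = model_arrays(model)
    if extra_fix:
        for rid, (lo, hi) in extra_fix.items():
            i = rids.index(rid)
            lb[i], ub[i] = lo, hi
    c = np.zeros(len(rids))
    c[rids.index(objective_rid)] = -1.0 if sense == "max" else 1.0
    res = linprog(c, A_eq=s_mat, b_eq=np.zeros(s_mat.shape[0]),
                  bounds=list(zip(lb, ub)), method="highs")
    if res.status != 0:
        return ("infeasible" if res.status == 2 else "unbounded", np.nan, None)
    z = -res.fun if sense == "max" else res.fun
    return "optimal", float(z), dict(zip(rids, res.x))


def enumerate_vertices(model, tol=1e-9):
    """All vertices of the flux polytope of a tiny model (brute force)."""
    s_mat, rids, lb, ub = model_arrays(model)
    n = len(rids)
    rank = np.linalg.matrix_rank(s_mat)
    n_fix = n - rank
    vertices = []
    for free_idx in itertools.combinations(range(n), n_fix):
        basic_idx = [i for i in range(n) if i not in free_idx]
        for bounds_choice in itertools.product(*[(lb[i], ub[i]) for i in free_idx]):
            rhs = -s_mat[:, list(free_idx)] @ np.array(bounds_choice)
            a_basic = s_mat[:, basic_idx]
            sol, residual, rk, _ = np.linalg.lstsq(a_basic, rhs, rcond=None)
            v = np.empty(n)
            v[list(free_idx)] = bounds_choice
            v[basic_idx] = sol
            if np.max(np.abs(s_mat @ v)) > 1e-6:
                continue
            if np.all(v >= lb - tol) and np.all(v <= ub + tol):
                if not any(np.allclose(v, w, atol=1e-6) for w in vertices):
                    vertices.append(v)
    return rids, vertices


def vertex_optimum(model, objective_rid, sense="max"):
    """LP optimum by scanning all vertices (the LP optimum is at a vertex)."""
    rids, vertices = enumerate_vertices(model)
    i = rids.index(objective_rid)
    values = [v[i] for v in vertices]
    if not values:
        raise RuntimeError("polytope has no vertices (infeasible?)")
    return max(values) if sense == "max" else min(values)


def vertex_flux_range(model, reaction_id):
    """FVA range of one reaction from the vertex list."""
    rids, vertices = enumerate_vertices(model)
    i = rids.index(reaction_id)
    values = [v[i] for v in vertices]
    return min(values), max(values)
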