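"""FBA, FVA and the sensitivity analyses built on them.

All operations leave the model as they found it: temporary constraints
(fixed growth points, the isocitrate-partition row) are applied inside a
``model`` context and popped afterwards.  Infeasible grid points are
reported as NaN with an explicit status, never dropped or interpolated.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd
from cobra import Model
from cobra.flux_analysis import flux_variability_analysis

from .core import FluxDistribution, FluxRange
from .model_io import find_reaction

__all__ = [
    "fba",
    "fva",
    "robustness",
    "partition_constrained_fba",
    "phase_plane",
]

FEASIBILITY_TOL = 1e-9


def _solve(model: Model) -> FluxDistribution:
    solution = model.optimize()
    if solution.status != "optimal":
        return FluxDistribution(
            fluxes=pd.Series(dtype=float),
            objective_value=float("nan"),
            status=solution.status,
        )
    return FluxDistribution(
        fluxes=solution.fluxes.copy(),
        objective_value=float(solution.objective_value),
        status="optimal",
    )


def fba(model: Model, objective_reaction: str, sense: str = "max") -> FluxDistribution:
    """Solve min/max cᵀv subject to S·v = 0 and the current bounds."""
    if sense not in ("max", "min"):
        raise ValueError("sense must be 'max' or 'min'")
    rxn = find_reaction(model, objective_reaction)
    with model:
        model.objective = rxn.id
        model.objective_direction = "max" if sense == "max" else "min"
        model.solver.configuration.tolerances.feasibility = FEASIBILITY_TOL
        return _solve(model)


def fva(
    model: Model,
    reactions: Iterable[str] | None = None,
    fraction_of_optimum: float = 1.0,
) -> FluxRange:
    """Per-reaction flux minimum and maximum under the current constraints.

    When the model's current objective should constrain the ranges (the
    usual case after the iterative workflow has pinned μ, Q_ac and ATPM)
    the bounds already encode it, so ``fraction_of_optimum`` defaults to
    re-requiring the current optimum.
    """
    rxn_list = None
    if reactions is not None:
        rxn_list = [find_reaction(model, r) for r in reactions]
    if np.isnan(model.slim_optimize()):
        raise RuntimeError("model is infeasible; FVA aborted before per-reaction solves")
    df = flux_variability_analysis(
        model, reaction_list=rxn_list, fraction_of_optimum=fraction_of_optimum,
        processes=1,
    )
    return FluxRange(ranges=df)


def robustness(
    model: Model,
    control_reaction: str,
    values: Sequence[float],
    objective_reaction: str,
    sense: str = "max",
) -> pd.DataFrame:
    """Optimum of ``objective_reaction`` with ``control_reaction`` fixed at
    each grid value.

    Returns a tidy frame ``(value, optimum, status)``; infeasible points keep
    their row with ``optimum = NaN``.
    """
    ctrl = find_reaction(model, control_reaction)
    rows = []
    for value in values:
        with model:
            ctrl.lower_bound = value
            ctrl.upper_bound = value
            dist = fba(model, objective_reaction, sense=sense)
        rows.append({"value": float(value),
                     "optimum": dist.objective_value,
                     "status": dist.status})
    return pd.DataFrame(rows)


def _partition_constraint(model: Model, p: float, icl_id: str, icdh_id: str):
    """Build the row v_ICL − p·(v_ICL + v_ICDH) = 0, i.e. (1−p)·v_ICL − p·v_ICDH = 0."""
    icl = find_reaction(model, icl_id)
    icdh = find_reaction(model, icdh_id)
    cons = model.problem.Constraint(
        (1.0 - p) * icl.flux_expression - p * icdh.flux_expression,
        lb=0.0, ub=0.0, name="isocitrate_partition",
    )
    return cons


def partition_constrained_fba(
    model: Model,
    p: float,
    objective_reaction: str = "BIOMASS",
    icl_id: str = "ICL",
    icdh_id: str = "ICDHyr",
    sense: str = "max",
) -> FluxDistribution:
    """FBA with the isocitrate split toward ICL pinned at fraction ``p``.

    Adds the single equality v_ICL = p·(v_ICL + v_ICDH) for the solve and
    removes it afterwards.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("partition fraction must lie in [0, 1]")
    with model:
        model.add_cons_vars(_partition_constraint(model, p, icl_id, icdh_id))
        return fba(model, objective_reaction, sense=sense)


def phase_plane(
    model: Model,
    isocitrate_grid: Sequence[float],
    partition_grid: Sequence[float],
    qac: float,
    objective_reaction: str = "BIOMASS",
    icl_id: str = "ICL",
    icdh_id: str = "ICDHyr",
) -> pd.DataFrame:
    """Biomass-yield surface over isocitrate production and ICL partition.

    The isocitrate production rate is the total flux leaving the branch
    point, v_ICL + v_ICDH (at steady state this equals the aconitase input).
    For each cell the total is fixed, the partition row is added, biomass is
    maximized, and the yield μ/Q_ac recorded.  The caller is responsible for
    having pinned ATPM at its strain optimum first (the convention of this
    analysis).  Long-format output: ``(isocitrate_flux, p, yield, status)``.
    """
    icl = find_reaction(model, icl_id)
    icdh = find_reaction(model, icdh_id)
    rows = []
    for x in isocitrate_grid:
        for p in partition_grid:
            with model:
                total = model.problem.Constraint(
                    icl.flux_expression + icdh.flux_expression,
                    lb=x, ub=x, name="isocitrate_production",
                )
                model.add_cons_vars(
                    [total, _partition_constraint(model, p, icl_id, icdh_id)]
                )
                dist = fba(model, objective_reaction, sense="max")
            mu = dist.objective_value
            rows.append({
                "isocitrate_flux": float(x),
                "p": float(p),
                "yield": mu / qac if dist.ok else float("nan"),
                "status": dist.status,
            })
    return pd.DataFrame(rows)
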