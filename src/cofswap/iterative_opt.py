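"""Iterative optimization: a unique optimal flux distribution per strain.

With growth rate and acetate uptake fixed to their measured values, a plain
ATP-yield FBA still leaves massive degeneracy: alternate optima and internal
loops able to carry arbitrary flux.  The procedure here resolves both:

1.  release the ATP-maintenance reaction (ATPM) to (0, 50) mmol gDW⁻¹ h⁻¹;
2.  maximize ATPM by LP — the maximal ATP yield;
3.  pin that value as the ATPM lower bound;
4.  minimize the oxygen uptake magnitude by LP;
5.  fix the O₂ exchange at that minimum;
6–7.  enumerate the first ``n`` ATPM-optimal flux distributions by MILP
    (binary activation per reaction, big-M linking, integer cuts);
8.  select the one minimizing Σᵢ vᵢ²;
9.  fix every reaction with |v| below a threshold (500 by default) at its
    selected flux, leaving suspected loop carriers free;
10. re-enumerate ``n`` optima;
11. select the minimum-Σv² distribution again.

Steps 9–11 shrink loop fluxes: after the sub-threshold network is pinned,
the only remaining freedom is in the high-flux cycles, and the quadratic
selection drives them to their smallest enumerated value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model

from .core import FluxDistribution, PhysiologicalConstraints
from .model_edit import apply_strain
from .model_io import find_reaction
from .lp_engine import fba

__all__ = [
    "IterativeOptConfig",
    "EnumerationResult",
    "enumerate_alternate_optima",
    "min_sum_squares_select",
    "fix_subthreshold_fluxes",
    "iterative_optimize",
]

logger = logging.getLogger(__name__)

BIG_M = 1000.0  # default bound magnitude of the models


@dataclass(frozen=True)
class IterativeOptConfig:
    """Knobs of the iterative procedure (defaults = study conditions)."""

    atpm_release_bounds: tuple[float, float] = (0.0, 50.0)
    n_optima: int = 400
    loop_threshold: float = 500.0  # mmol gDW⁻¹ h⁻¹
    objective_tol: float = 1e-6
    support_tol: float = 1e-6
    milp_time_limit: float | None = 60.0  # seconds per integer cut
    atpm_id: str = "ATPM"
    o2_exchange_id: str = "EX_o2_e"

    def __post_init__(self) -> None:
        if self.n_optima < 1:
            raise ValueError("n_optima must be >= 1")
        if not self.loop_threshold > 0:
            raise ValueError("loop_threshold must be positive")


@dataclass
class EnumerationResult:
    """Alternate optima found by the integer-cut recursion, in discovery order."""

    solutions: list[FluxDistribution]
    exhausted: bool = False       # every support-distinct optimum was found
    hit_time_limit: bool = False  # partial list: a MILP solve timed out

    def __iter__(self):
        return iter(self.solutions)

    def __len__(self) -> int:
        return len(self.solutions)


def enumerate_alternate_optima(
    model: Model,
    objective_reaction: str,
    n: int,
    sense: str = "max",
    config: IterativeOptConfig | None = None,
) -> EnumerationResult:
    """Enumerate up to ``n`` support-distinct optima of an FBA problem.

    MILP formulation: one binary yⱼ per reaction with big-M linking
    ``−M·yⱼ ≤ vⱼ ≤ M·yⱼ``; optimality of the original objective is imposed
    as a constraint; each found solution adds the integer cut
    ``Σ_{j ∈ support} yⱼ ≤ |support| − 1``, excluding that active set and
    all its supersets.  Each MILP minimizes Σyⱼ, so solutions come out
    support-minimal and the recursion is deterministic.
    """
    cfg = config or IterativeOptConfig()
    base = fba(model, objective_reaction, sense=sense)
    if not base.ok:
        raise RuntimeError(
            f"cannot enumerate optima: base LP is {base.status}"
        )
    z_star = base.objective_value
    obj_rxn = find_reaction(model, objective_reaction)

    supports: list[list[str]] = []
    exhausted = False
    hit_time_limit = False
    with model:
        if cfg.milp_time_limit is not None:
            model.solver.configuration.timeout = int(cfg.milp_time_limit)
        interface = model.problem
        tol = cfg.objective_tol * max(1.0, abs(z_star))
        if sense == "max":
            opt_cons = interface.Constraint(
                obj_rxn.flux_expression, lb=z_star - tol, name="hold_optimum")
        else:
            opt_cons = interface.Constraint(
                obj_rxn.flux_expression, ub=z_star + tol, name="hold_optimum")
        model.add_cons_vars(opt_cons)

        indicators = {}
        to_add = []
        for rxn in model.reactions:
            y = interface.Variable(f"y_{rxn.id}", type="binary")
            indicators[rxn.id] = y
            to_add.append(y)
            to_add.append(interface.Constraint(
                rxn.flux_expression - BIG_M * y, ub=0.0, name=f"actub_{rxn.id}"))
            to_add.append(interface.Constraint(
                rxn.flux_expression + BIG_M * y, lb=0.0, name=f"actlb_{rxn.id}"))
        model.add_cons_vars(to_add)
        model.objective = interface.Objective(
            sum(indicators.values()), direction="min")

        rxn_ids = [r.id for r in model.reactions]
        for _ in range(n):
            status = model.solver.optimize()
            if status == "time_limit":  # pragma: no cover - heavy models only
                hit_time_limit = True
                logger.warning("MILP time limit hit after %d optima", len(supports))
                break
            if status != "optimal":
                exhausted = True
                break
            # net flux = forward − reverse optlang variable primals
            fluxes = pd.Series({r.id: float(r.flux) for r in model.reactions})
            support = [rid for rid in rxn_ids
                       if abs(fluxes[rid]) > cfg.support_tol]
            supports.append(support)
            cut = interface.Constraint(
                sum(indicators[rid] for rid in support),
                ub=len(support) - 1,
                name=f"integer_cut_{len(supports)}",
            )
            model.add_cons_vars(cut)
    if not supports:
        raise RuntimeError("enumeration found no optimum (inconsistent base LP)")

    # Polish each support into an exact optimum: with the inactive reactions
    # closed, the MILP's tolerance slack disappears and fluxes are the true
    # LP optimum restricted to that active set.
    solutions = []
    for support in supports:
        with model:
            active = set(support)
            for rxn in model.reactions:
                if rxn.id not in active:
                    rxn.lower_bound = 0.0
                    rxn.upper_bound = 0.0
            dist = fba(model, objective_reaction, sense=sense)
        if not dist.ok:  # pragma: no cover - defensive
            continue
        solutions.append(dist)
    return EnumerationResult(solutions, exhausted=exhausted,
                             hit_time_limit=hit_time_limit)


def min_sum_squares_select(solutions: list[FluxDistribution] | EnumerationResult,
                           ) -> FluxDistribution:
    """Pick the flux distribution with the smallest Σᵢvᵢ² (stable tie-break).

    This is a selection among the enumerated discrete set, not a QP over the
    whole optimal face.
    """
    if isinstance(solutions, EnumerationResult):
        solutions = solutions.solutions
    if not solutions:
        raise ValueError("no solutions to select from")
    sums = np.array([s.sum_of_squares() for s in solutions])
    return solutions[int(np.argmin(sums))]  # argmin returns first minimum


def fix_subthreshold_fluxes(
    model: Model, dist: FluxDistribution, threshold: float
) -> Model:
    """Pin lb = ub = flux for every reaction with |flux| < threshold.

    Reactions at or above the threshold — loop candidates — keep their
    original bounds so re-optimization can shrink them.  Comparison is on
    absolute values (reversible reactions carry signed flux).
    """
    for rxn in model.reactions:
        v = float(dist.fluxes[rxn.id])
        if abs(v) < threshold:
            rxn.lower_bound = v
            rxn.upper_bound = v
    return model


def iterative_optimize(
    model: Model,
    constraints: PhysiologicalConstraints | None = None,
    config: IterativeOptConfig | None = None,
) -> tuple[FluxDistribution, dict]:
    """Run the full 11-step procedure; returns (distribution, provenance).

    ``model`` is not modified: the workflow runs on a copy.  When
    ``constraints`` is given the strain edits and μ/Q_ac equalities are
    applied first; otherwise the model is assumed prepared.  The provenance
    dict records every intermediate objective value and enumeration size.
    """
    cfg = config or IterativeOptConfig()
    work = model.copy()
    if constraints is not None:
        apply_strain(work, constraints)
    prov: dict = {"config": {
        "atpm_release_bounds": cfg.atpm_release_bounds,
        "n_optima": cfg.n_optima,
        "loop_threshold": cfg.loop_threshold,
    }}

    # 1. release ATPM
    atpm = find_reaction(work, cfg.atpm_id)
    atpm.lower_bound, atpm.upper_bound = cfg.atpm_release_bounds

    # 2. maximal ATP yield
    step2 = fba(work, cfg.atpm_id, sense="max")
    if not step2.ok:
        raise RuntimeError(f"step 2 (maximize ATPM) is {step2.status}")
    prov["max_atpm"] = step2.objective_value

    # 3. pin as lower bound
    atpm.lower_bound = step2.objective_value

    # 4. minimal O2 uptake (uptake is negative exchange flux; minimizing its
    #    magnitude = maximizing the exchange flux toward zero)
    step4 = fba(work, cfg.o2_exchange_id, sense="max")
    if not step4.ok:
        raise RuntimeError(f"step 4 (minimize O2 uptake) is {step4.status}")
    prov["min_o2_exchange"] = step4.objective_value

    # 5. fix O2 exchange
    o2 = find_reaction(work, cfg.o2_exchange_id)
    o2.lower_bound = step4.objective_value
    o2.upper_bound = step4.objective_value

    # 6-7. first enumeration
    enum1 = enumerate_alternate_optima(
        work, cfg.atpm_id, cfg.n_optima, sense="max", config=cfg)
    prov["n_optima_first_pass"] = len(enum1)
    prov["first_pass_exhausted"] = enum1.exhausted

    # 8. quadratic selection
    pick1 = min_sum_squares_select(enum1)
    prov["sum_squares_first_pass"] = pick1.sum_of_squares()

    # 9. pin the sub-threshold network
    fix_subthreshold_fluxes(work, pick1, cfg.loop_threshold)

    # 10. re-enumeration over the remaining (loop) freedom
    enum2 = enumerate_alternate_optima(
        work, cfg.atpm_id, cfg.n_optima, sense="max", config=cfg)
    prov["n_optima_second_pass"] = len(enum2)
    prov["second_pass_exhausted"] = enum2.exhausted

    # 11. final quadratic selection
    final = min_sum_squares_select(enum2)
    prov["sum_squares_final"] = final.sum_of_squares()
    prov["final_atpm"] = float(final.fluxes[cfg.atpm_id])

    final = FluxDistribution(
        fluxes=final.fluxes,
        objective_value=float(final.fluxes[cfg.atpm_id]),
        status="optimal",
    )
    return final, prov
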