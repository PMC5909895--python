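"""Shared domain types for the cofactor-swap analysis.

The in-memory metabolic network is a :class:`cobra.Model` (stoichiometric
matrix ``S``, per-reaction bounds in mmol gDW⁻¹ h⁻¹, linear objective ``c``).
The helpers here wrap solver output in small immutable records so downstream
accounting never touches solver state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from cobra import Model

__all__ = [
    "FluxDistribution",
    "FluxRange",
    "PhysiologicalConstraints",
    "validate_model",
    "steady_state_residual",
]


@dataclass(frozen=True)
class FluxDistribution:
    """One steady-state flux vector.

    Attributes
    ----------
    fluxes : pandas.Series
        Reaction id -> flux (mmol gDW⁻¹ h⁻¹; biomass in h⁻¹).
    objective_value : float
        Optimum of the solved problem; ``nan`` when not optimal.
    status : str
        Solver status: ``optimal``, ``infeasible`` or ``unbounded``.
    """

    fluxes: pd.Series
    objective_value: float
    status: str = "optimal"

    def __getitem__(self, reaction_id: str) -> float:
        return float(self.fluxes[reaction_id])

    @property
    def ok(self) -> bool:
        return self.status == "optimal"

    def sum_of_squares(self) -> float:
        """Σᵢ vᵢ² over all reactions."""
        return float(np.square(self.fluxes.to_numpy()).sum())

    def support(self, tol: float = 1e-6) -> frozenset[str]:
        """Ids of reactions carrying flux above ``tol`` in magnitude."""
        return frozenset(self.fluxes.index[self.fluxes.abs() > tol])


@dataclass(frozen=True)
class FluxRange:
    """Per-reaction (minimum, maximum) flux under the current constraints."""

    ranges: pd.DataFrame  # columns: minimum, maximum; index: reaction id

    def __getitem__(self, reaction_id: str) -> tuple[float, float]:
        row = self.ranges.loc[reaction_id]
        return float(row["minimum"]), float(row["maximum"])

    def __post_init__(self) -> None:
        bad = self.ranges[
            self.ranges["minimum"] > self.ranges["maximum"] + 1e-9
        ]
        if len(bad):
            raise ValueError(f"min > max for reactions: {list(bad.index)}")


@dataclass(frozen=True)
class PhysiologicalConstraints:
    """Measured growth parameters plus the genetic edits of one strain.

    ``mu`` is the exponential growth rate (h⁻¹) and ``qac`` the specific
    acetate uptake rate (mmol gDW⁻¹ h⁻¹); both act as hard constraints.
    ``swap_fraction`` moves that fraction of the ICDH NADP⁺/NADPH
    stoichiometry onto NAD⁺/NADH; ``knockouts`` lists reaction ids forced
    to zero (e.g. the PntAB transhydrogenase for a ΔpntAB strain).
    """

    strain: str
    mu: float
    qac: float
    swap_fraction: float = 0.0
    knockouts: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.mu > 0:
            raise ValueError("mu must be positive")
        if not self.qac > 0:
            raise ValueError("qac must be positive")
        if not 0.0 <= self.swap_fraction <= 1.0:
            raise ValueError("swap_fraction must lie in [0, 1]")
        object.__setattr__(self, "knockouts", tuple(self.knockouts))

    @property
    def pntab_present(self) -> bool:
        return "THD2pp" not in self.knockouts

    @property
    def yield_xs(self) -> float:
        """Biomass yield Y_X/S = μ / Q_ac (gDW per mmol acetate)."""
        return self.mu / self.qac


def validate_model(model: Model) -> None:
    """Assert the structural invariants of a metabolic model.

    Checks unique reaction/metabolite ids, lb ≤ ub everywhere, and that every
    stoichiometric entry references a registered metabolite.
    """
    rxn_ids = [r.id for r in model.reactions]
    met_ids = [m.id for m in model.metabolites]
    if len(set(rxn_ids)) != len(rxn_ids):
        raise ValueError("duplicate reaction ids")
    if len(set(met_ids)) != len(met_ids):
        raise ValueError("duplicate metabolite ids")
    met_set = set(met_ids)
    for rxn in model.reactions:
        if rxn.lower_bound > rxn.upper_bound:
            raise ValueError(
                f"{rxn.id}: lower bound {rxn.lower_bound} exceeds upper "
                f"bound {rxn.upper_bound}"
            )
        for met in rxn.metabolites:
            if met.id not in met_set:
                raise ValueError(f"{rxn.id} references unknown metabolite {met.id}")


def steady_state_residual(model: Model, dist: FluxDistribution) -> float:
    """max |S·v| for a flux vector; ~0 at steady state."""
    v = dist.fluxes.reindex([r.id for r in model.reactions]).to_numpy()
    from cobra.util.array import create_stoichiometric_matrix

    s_mat = create_stoichiometric_matrix(model)
    return float(np.abs(s_mat @ v).max())
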