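"""Derived quantities from a flux distribution.

Net turnover of a metabolite at steady state is

    φᵢ = ½ Σⱼ |S(i,j) · vⱼ|

— half the summed absolute mass exchange, which equals both the total
production and the total consumption (they balance).  On top of φ the module
builds the ATP allocation split (maintenance vs growth-associated), the
per-reaction NADPH/NADH source breakdowns as percentages of acetate uptake,
and the isocitrate partition statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from cobra import Model

from .core import FluxDistribution, PhysiologicalConstraints
from .lp_engine import fba
from .model_edit import apply_strain, swap_cofactor
from .model_io import find_reaction

__all__ = [
    "TurnoverReport",
    "PartitionResult",
    "CofactorBreakdown",
    "net_turnover",
    "atp_allocation",
    "cofactor_sources",
    "isocitrate_partition",
    "swap_scan",
]


@dataclass(frozen=True)
class TurnoverReport:
    """Net production/consumption rate of one metabolite and its terms."""

    metabolite_id: str
    phi: float  # mmol gDW⁻¹ h⁻¹
    terms: pd.Series  # reaction id -> signed S(i,j)·vⱼ, nonzero entries

    @property
    def production_terms(self) -> pd.Series:
        return self.terms[self.terms > 0]

    @property
    def consumption_terms(self) -> pd.Series:
        return self.terms[self.terms < 0]


@dataclass(frozen=True)
class PartitionResult:
    """Split of isocitrate-consuming flux between ICL and ICDH."""

    p_icl: float
    p_icdh: float
    v_icl: float
    v_icdh: float

    @property
    def ratio(self) -> float:
        """V_ICDH / V_ICL."""
        return self.v_icdh / self.v_icl if self.v_icl != 0 else float("inf")


@dataclass(frozen=True)
class CofactorBreakdown:
    """Per-reaction production of a reduced cofactor, as flux and % of Q_ac."""

    cofactor: str
    sources: pd.DataFrame  # columns: flux, pct_of_qac; index: reaction id
    total: float
    qac: float

    @property
    def total_pct(self) -> float:
        return 100.0 * self.total / self.qac


def net_turnover(model: Model, dist: FluxDistribution, metabolite_id: str,
                 ) -> TurnoverReport:
    """φ = ½ Σⱼ |S(i,j)·vⱼ| for one metabolite."""
    met = model.metabolites.get_by_id(metabolite_id)
    terms = {}
    for rxn in met.reactions:
        term = float(rxn.metabolites[met]) * float(dist.fluxes[rxn.id])
        if term != 0.0:
            terms[rxn.id] = term
    series = pd.Series(terms, dtype=float).sort_index()
    phi = 0.5 * series.abs().sum() if len(series) else 0.0
    return TurnoverReport(metabolite_id=metabolite_id, phi=float(phi), terms=series)


def atp_allocation(model: Model, dist: FluxDistribution,
                   atp_id: str = "atp_c", atpm_id: str = "ATPM",
                   ) -> tuple[float, float]:
    """Split total ATP production into (ATPM, ATPμ).

    ATPM is the non-growth-associated maintenance flux; ATPμ — everything
    else, i.e. total ATP turnover minus ATPM — covers growth-associated
    maintenance and pathway costs such as gluconeogenesis.
    """
    total = net_turnover(model, dist, atp_id).phi
    atpm = float(dist.fluxes[atpm_id])
    return atpm, total - atpm


# reduced species of each cofactor pool
_REDUCED = {"NADPH": "nadph_c", "NADH": "nadh_c"}


def cofactor_sources(model: Model, dist: FluxDistribution, cofactor: str,
                     qac: float) -> CofactorBreakdown:
    """All reactions producing the reduced cofactor, with % of acetate uptake.

    Production is per reaction and per species: reaction j is a source when
    S(reduced, j)·vⱼ > 0.  A transhydrogenase therefore shows up as a
    producer on one ledger and a consumer on the other.
    """
    if cofactor not in _REDUCED:
        raise ValueError(f"cofactor must be one of {sorted(_REDUCED)}")
    report = net_turnover(model, dist, _REDUCED[cofactor])
    prod = report.production_terms.sort_values(ascending=False)
    df = pd.DataFrame({"flux": prod, "pct_of_qac": 100.0 * prod / qac})
    return CofactorBreakdown(cofactor=cofactor, sources=df,
                             total=float(prod.sum()), qac=qac)


def isocitrate_partition(dist: FluxDistribution, icl_id: str = "ICL",
                         icdh_id: str = "ICDHyr") -> PartitionResult:
    """Fractions of isocitrate flux through ICL vs ICDH, and their ratio."""
    v_icl = float(dist.fluxes[icl_id])
    v_icdh = float(dist.fluxes[icdh_id])
    total = v_icl + v_icdh
    if total <= 0:
        raise ValueError(
            f"isocitrate branch flux is {total}; partition undefined")
    return PartitionResult(p_icl=v_icl / total, p_icdh=v_icdh / total,
                           v_icl=v_icl, v_icdh=v_icdh)


def swap_scan(
    model: Model,
    constraints: PhysiologicalConstraints,
    fractions,
    tracked=("ATPM", "ICDHyr", "THD2pp", "NADTRHD"),
    icdh_id: str = "ICDHyr",
    atpm_id: str = "ATPM",
    atpm_release: tuple[float, float] = (0.0, 50.0),
) -> pd.DataFrame:
    """Scan the cofactor-swap fraction from 0 to 1 at fixed physiology.

    For each fraction the swap is applied to a fresh copy of the pristine
    model (never chained), the strain's remaining edits and μ/Q_ac
    equalities are imposed, ATPM is released and maximized, and the tracked
    fluxes recorded.  One row per fraction.
    """
    rows = []
    for f in fractions:
        work = model.copy()
        swap_cofactor(work, icdh_id, float(f))
        base = PhysiologicalConstraints(
            strain=constraints.strain, mu=constraints.mu, qac=constraints.qac,
            swap_fraction=0.0, knockouts=constraints.knockouts)
        apply_strain(work, base, icdh_id=icdh_id)
        atpm = find_reaction(work, atpm_id)
        atpm.lower_bound, atpm.upper_bound = atpm_release
        dist = fba(work, atpm_id, sense="max")
        row = {"fraction": float(f), "status": dist.status}
        for rid in tracked:
            row[rid] = float(dist.fluxes[rid]) if dist.ok else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
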