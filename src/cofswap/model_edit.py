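"""Genetic and constraint edits: cofactor swap, knockouts, irreversibility.

The cofactor swap moves a fraction of the NADP⁺/NADPH stoichiometry of a
dehydrogenase onto NAD⁺/NADH within the *same* reaction, so a partial swap
is mixed stoichiometry rather than two parallel reactions and the LP keeps
its dimensionality across a 0–100% scan.  Swaps are always expressed
relative to the pristine coefficients, which are stashed on the reaction the
first time it is edited: applying swap(0.3) then swap(1.0) yields a fully
swapped reaction, not 30% of 70%.
"""

from __future__ import annotations

from collections.abc import Iterable

import yaml
from cobra import Model

from .core import PhysiologicalConstraints
from .model_io import find_reaction

__all__ = [
    "swap_cofactor",
    "knockout",
    "make_irreversible",
    "apply_strain",
    "load_strains",
    "STRAIN_PHYSIOLOGY",
]

_NADP, _NADPH, _NAD, _NADH = "nadp_c", "nadph_c", "nad_c", "nadh_c"
_PRISTINE_KEY = "pristine_cofactor_coefficients"


def _cofactor_coeff(reaction, met_id: str) -> float:
    for met, coeff in reaction.metabolites.items():
        if met.id == met_id:
            return float(coeff)
    return 0.0


def swap_cofactor(model: Model, reaction_id: str, fraction: float) -> Model:
    """Move ``fraction`` of a reaction's NADP⁺/NADPH stoichiometry to NAD⁺/NADH.

    For pristine NADP⁺ coefficient ``a`` and NADPH coefficient ``b``::

        NADP⁺ → (1−f)·a     NAD⁺  → original + f·a
        NADPH → (1−f)·b     NADH  → original + f·b

    All non-cofactor coefficients are untouched; exact-zero entries are
    pruned.  The model is edited in place and returned.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError(f"swap fraction must lie in [0, 1], got {fraction}")
    rxn = find_reaction(model, reaction_id)

    pristine = rxn.annotation.get(_PRISTINE_KEY)
    if pristine is None:
        pristine = {m: _cofactor_coeff(rxn, m)
                    for m in (_NADP, _NADPH, _NAD, _NADH)}
        if pristine[_NADP] == 0.0 and pristine[_NADPH] == 0.0:
            raise ValueError(
                f"{rxn.id} carries no NADP+/NADPH stoichiometry to swap"
            )
        rxn.annotation[_PRISTINE_KEY] = pristine

    a, b = pristine[_NADP], pristine[_NADPH]
    target = {
        _NADP: (1.0 - fraction) * a,
        _NADPH: (1.0 - fraction) * b,
        _NAD: pristine[_NAD] + fraction * a,
        _NADH: pristine[_NADH] + fraction * b,
    }
    mets = {m.id: m for m in model.metabolites}
    for met_id, coeff in target.items():
        current = _cofactor_coeff(rxn, met_id)
        if coeff != current:
            rxn.add_metabolites({mets[met_id]: coeff - current})
    # prune exact zeros left behind
    zeros = {m: c for m, c in rxn.metabolites.items() if c == 0.0}
    if zeros:
        rxn.subtract_metabolites(zeros)
    return model


def knockout(model: Model, reaction_ids: str | Iterable[str]) -> Model:
    """Zero the bounds of each listed reaction (gene-deletion constraint)."""
    if isinstance(reaction_ids, str):
        reaction_ids = [reaction_ids]
    for rid in reaction_ids:
        rxn = find_reaction(model, rid)
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
    return model


def make_irreversible(model: Model, reaction_id: str) -> Model:
    """Forbid the reverse direction: lb ← max(lb, 0), ub unchanged."""
    rxn = find_reaction(model, reaction_id)
    rxn.lower_bound = max(rxn.lower_bound, 0.0)
    return model


def apply_strain(
    model: Model,
    constraints: PhysiologicalConstraints,
    icdh_id: str = "ICDHyr",
    por5_id: str = "POR5",
    acetate_exchange_id: str = "EX_ac_e",
    biomass_id: str = "BIOMASS",
    fix_growth: bool = True,
) -> Model:
    """Prepare a model for one strain, in a fixed deterministic order.

    1. fractional cofactor swap of ICDH;
    2. knockouts (ΔpntAB → THD2pp);
    3. POR5 irreversibility (skipped when the reaction is absent);
    4. acetate uptake fixed as an equality, lb = ub = −Q_ac;
    5. growth fixed to the measured μ when ``fix_growth`` (the iterative
       workflow wants it fixed; sensitivity analyses pass ``False`` and
       manage the biomass bounds themselves).

    Idempotent for fixed ``constraints`` (the swap works from pristine
    coefficients; every other edit sets absolute bounds).
    """
    if constraints.swap_fraction > 0.0:
        swap_cofactor(model, icdh_id, constraints.swap_fraction)
    if constraints.knockouts:
        knockout(model, constraints.knockouts)
    if any(model.reactions.has_id(r) for r in (por5_id,)):
        make_irreversible(model, por5_id)
    ac = find_reaction(model, acetate_exchange_id)
    ac.lower_bound = -constraints.qac
    ac.upper_bound = -constraints.qac
    if fix_growth:
        bm = find_reaction(model, biomass_id)
        bm.lower_bound = constraints.mu
        bm.upper_bound = constraints.mu
    return model


#: Measured exponential-phase physiology of the four strains (growth rate μ
#: in h⁻¹, acetate uptake Q_ac in mmol gDW⁻¹ h⁻¹) plus their genetic edits.
STRAIN_PHYSIOLOGY: dict[str, PhysiologicalConstraints] = {
    "wild_type": PhysiologicalConstraints("wild_type", 0.196, 7.88),
    "pntab_ko": PhysiologicalConstraints(
        "pntab_ko", 0.191, 7.6, knockouts=("THD2pp",)),
    "icd_nad": PhysiologicalConstraints("icd_nad", 0.135, 8.0, swap_fraction=1.0),
    "icd_nad_pntab_ko": PhysiologicalConstraints(
        "icd_nad_pntab_ko", 0.1203, 7.0, swap_fraction=1.0,
        knockouts=("THD2pp",)),
}


def load_strains(path) -> dict[str, PhysiologicalConstraints]:
    """Load strain definitions from a YAML/JSON config.

    Schema per entry: ``{strain, mu, qac, swap_fraction, knockouts: [...]}``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = {}
    for entry in raw["strains"]:
        pc = PhysiologicalConstraints(
            strain=entry["strain"],
            mu=float(entry["mu"]),
            qac=float(entry["qac"]),
            swap_fraction=float(entry.get("swap_fraction", 0.0)),
            knockouts=tuple(entry.get("knockouts", ())),
        )
        out[pc.strain] = pc
    return out
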