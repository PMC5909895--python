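"""Hand-solvable fixture networks for testing every analysis stage offline.

Three generators:

* :func:`core_acetate_model` — a ~25-reaction acetate-fed network with the
  isocitrate bifurcation (NADP⁺-ICDH vs ICL), both transhydrogenases, an
  internal succinate/fumarate-style loop, a duplicated acetate transporter
  (degenerate optima), oxidative phosphorylation, ATP maintenance, and an
  NADPH-consuming biomass reaction.  It reproduces the *mechanisms* the
  genome-scale analysis relies on (glyoxylate-shunt essentiality, cofactor
  swap propagating to growth), not iJO1366 magnitudes.
* :func:`loopy_toy_model` — a linear pathway with a superimposed two-reaction
  futile cycle able to carry arbitrary flux.
* :func:`degenerate_optima_model` — ``k`` stoichiometrically equivalent
  parallel routes, hence exactly ``k`` support-distinct optima.

Each generator has a companion ``*_sidecar`` dict of independently derived
optima frozen at construction time; tests assert solver output against them.
"""

from __future__ import annotations

from cobra import Metabolite, Model, Reaction

__all__ = [
    "core_acetate_model",
    "core_acetate_sidecar",
    "loopy_toy_model",
    "loopy_toy_sidecar",
    "degenerate_optima_model",
]

BOUND = 1000.0  # default bound magnitude, genome-scale convention

# Biomass demand per unit growth (mmol per gDW): oxaloacetate and
# 2-oxoglutarate as carbon precursors, ribose-5-P for nucleotides, explicit
# NADPH so cofactor-swap effects propagate to growth, and a large ATP cost so
# energy limits biomass the way it does on a poor substrate.
BIOMASS_STOICH = {"oaa": 6.0, "akg": 2.0, "r5p": 0.8, "nadph": 16.0, "atp": 80.0}


def _rxn(model: Model, rid: str, stoich: dict[str, float],
         lb: float = 0.0, ub: float = BOUND, name: str = "") -> Reaction:
    rxn = Reaction(rid, name=name or rid, lower_bound=lb, upper_bound=ub)
    model.add_reactions([rxn])
    rxn.add_metabolites({model.metabolites.get_by_id(m): c for m, c in stoich.items()})
    return rxn


def core_acetate_model() -> Model:
    """Build the core acetate network (fresh instance each call)."""
    model = Model("core_acetate")
    mets = {
        "ac_e": "e", "o2_e": "e", "co2_e": "e",
        "ac_c": "c", "accoa_c": "c", "oaa_c": "c", "icit_c": "c",
        "akg_c": "c", "succ_c": "c", "mal_c": "c", "glx_c": "c",
        "pyr_c": "c", "g6p_c": "c", "r5p_c": "c",
        "nad_c": "c", "nadh_c": "c", "nadp_c": "c", "nadph_c": "c",
        "atp_c": "c", "adp_c": "c", "o2_c": "c", "co2_c": "c",
    }
    model.add_metabolites(
        [Metabolite(mid, compartment=comp) for mid, comp in mets.items()]
    )

    # exchanges and transport
    _rxn(model, "EX_ac_e", {"ac_e": -1}, lb=-10.0, name="Acetate exchange")
    _rxn(model, "EX_o2_e", {"o2_e": -1}, lb=-BOUND, name="O2 exchange")
    _rxn(model, "EX_co2_e", {"co2_e": -1}, lb=-BOUND, name="CO2 exchange")
    _rxn(model, "O2t", {"o2_e": -1, "o2_c": 1})
    _rxn(model, "CO2t", {"co2_c": -1, "co2_e": 1})
    # duplicated acetate transporters: a built-in degenerate-optimum pair
    _rxn(model, "ACUP1", {"ac_e": -1, "ac_c": 1}, name="Acetate uptake (proton symport)")
    _rxn(model, "ACUP2", {"ac_e": -1, "ac_c": 1}, name="Acetate uptake (alternate system)")

    # acetate activation and TCA cycle (lumped where linear)
    _rxn(model, "ACS", {"ac_c": -1, "atp_c": -1, "accoa_c": 1, "adp_c": 1},
         name="Acetyl-CoA synthetase (lumped)")
    _rxn(model, "CS", {"accoa_c": -1, "oaa_c": -1, "icit_c": 1},
         name="Citrate synthase + aconitase (lumped)")
    _rxn(model, "ICDHyr",
         {"icit_c": -1, "nadp_c": -1, "akg_c": 1, "nadph_c": 1, "co2_c": 1},
         lb=-BOUND, name="Isocitrate dehydrogenase (NADP)")
    _rxn(model, "AKGDH",
         {"akg_c": -1, "nad_c": -1, "adp_c": -1,
          "succ_c": 1, "nadh_c": 1, "co2_c": 1, "atp_c": 1},
         name="2-oxoglutarate dehydrogenase + succinyl-CoA synthetase (lumped)")
    _rxn(model, "SUCDi", {"succ_c": -1, "nad_c": -1, "mal_c": 1, "nadh_c": 1},
         name="Succinate dehydrogenase + fumarase (lumped)")
    _rxn(model, "FRD7", {"mal_c": -1, "nadh_c": -1, "succ_c": 1, "nad_c": 1},
         name="Fumarate reductase (lumped); forms an internal loop with SUCDi")
    _rxn(model, "MDH", {"mal_c": -1, "nad_c": -1, "oaa_c": 1, "nadh_c": 1},
         lb=-BOUND, name="Malate dehydrogenase")

    # glyoxylate shunt — the only anaplerotic route on acetate
    _rxn(model, "ICL", {"icit_c": -1, "succ_c": 1, "glx_c": 1},
         name="Isocitrate lyase")
    _rxn(model, "MALS", {"accoa_c": -1, "glx_c": -1, "mal_c": 1},
         name="Malate synthase")

    # NADP-malic enzyme and pyruvate oxidation
    _rxn(model, "ME2", {"mal_c": -1, "nadp_c": -1, "pyr_c": 1, "nadph_c": 1, "co2_c": 1},
         name="Malic enzyme (NADP)")
    _rxn(model, "POR5",
         {"pyr_c": -1, "nad_c": -1, "accoa_c": 1, "nadh_c": 1, "co2_c": 1},
         lb=-BOUND, name="Pyruvate oxidoreductase (reversible until constrained)")

    # gluconeogenesis and oxidative PPP (lumped)
    _rxn(model, "GLUNEO",
         {"oaa_c": -2, "atp_c": -2, "nadh_c": -2,
          "g6p_c": 1, "adp_c": 2, "nad_c": 2, "co2_c": 2},
         name="Gluconeogenesis (lumped, PEPCK + reverse glycolysis)")
    _rxn(model, "OXPPP",
         {"g6p_c": -1, "nadp_c": -2, "r5p_c": 1, "nadph_c": 2, "co2_c": 1},
         name="Oxidative pentose phosphate pathway (G6PDH + 6PGDH, lumped)")

    # transhydrogenases: PntAB costs energy (proton-motive force proxy),
    # UdhA is the free spill valve — together they are NOT a free loop
    _rxn(model, "THD2pp",
         {"nadh_c": -1, "nadp_c": -1, "atp_c": -0.75,
          "nad_c": 1, "nadph_c": 1, "adp_c": 0.75},
         name="PntAB membrane transhydrogenase (energy-coupled)")
    _rxn(model, "NADTRHD",
         {"nadph_c": -1, "nad_c": -1, "nadp_c": 1, "nadh_c": 1},
         name="UdhA soluble transhydrogenase")

    # energy metabolism
    _rxn(model, "OXPHOS",
         {"nadh_c": -1, "o2_c": -0.5, "adp_c": -2, "nad_c": 1, "atp_c": 2},
         name="Oxidative phosphorylation (lumped, P/O = 2)")
    _rxn(model, "ATPM", {"atp_c": -1, "adp_c": 1}, lb=3.15,
         name="ATP maintenance requirement")

    bm = {f"{m}_c": -c for m, c in BIOMASS_STOICH.items()}
    bm["adp_c"] = BIOMASS_STOICH["atp"]
    bm["nadp_c"] = BIOMASS_STOICH["nadph"]
    _rxn(model, "BIOMASS", bm, name="Biomass (precursors + NADPH + ATP)")

    model.objective = "BIOMASS"
    return model


# Frozen reference optima for the core network, derived with an independent
# LP route (scipy HiGHS on the raw S matrix) at construction time.
# Conditions: POR5 irreversible, acetate uptake fixed at 10, ATPM at its
# 3.15 lower bound unless stated.
core_acetate_sidecar: dict[str, float] = {
    "qac_fixed": 10.0,
    "max_biomass": 0.3147388059701495,           # native ICDH
    "max_biomass_swapped": 0.30303627760252383,  # swap_fraction = 1
    "max_biomass_icl_blocked": 0.0,              # ICL lb = ub = 0
    "optimal_p_icl": 0.43297116947557507,        # v_ICL/(v_ICL+v_ICDH) at optimum
}


def loopy_toy_model() -> Model:
    """Linear chain A→B→sink with a 3-reaction internal cycle on B.

    The cycle (B→C, C→D, D→B) has net-zero stoichiometry and can carry any
    flux up to the bound, inflating naive FBA solutions and Eq-style
    turnover numbers; the loop-free solution is recorded in the sidecar.
    """
    model = Model("loopy_toy")
    model.add_metabolites(
        [Metabolite(m, compartment="c") for m in ("A", "B", "C", "D")]
    )
    _rxn(model, "SRC", {"A": 1}, ub=10.0)
    _rxn(model, "CONV", {"A": -1, "B": 1})
    _rxn(model, "SINK", {"B": -1})
    _rxn(model, "LOOP1", {"B": -1, "C": 1}, lb=-BOUND)
    _rxn(model, "LOOP2", {"C": -1, "D": 1}, lb=-BOUND)
    _rxn(model, "LOOP3", {"D": -1, "B": 1}, lb=-BOUND)
    model.objective = "SINK"
    return model


loopy_toy_sidecar: dict[str, float] = {
    "max_sink": 10.0,
    "loop_free_fluxes": {"SRC": 10.0, "CONV": 10.0, "SINK": 10.0,
                         "LOOP1": 0.0, "LOOP2": 0.0, "LOOP3": 0.0},
}


def degenerate_optima_model(k: int) -> Model:
    """``k`` stoichiometrically equivalent parallel routes A→B.

    Exactly ``k`` support-distinct optimal flux distributions exist when the
    sink is maximized (the uptake saturates and any single path, or convex
    mixture, attains it; vertices are the single-path solutions).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    model = Model(f"degenerate_{k}")
    model.add_metabolites(
        [Metabolite(m, compartment="c") for m in ("A", "B")]
    )
    _rxn(model, "SRC", {"A": 1}, ub=10.0)
    for i in range(1, k + 1):
        _rxn(model, f"PATH{i}", {"A": -1, "B": 1})
    _rxn(model, "SINK", {"B": -1})
    model.objective = "SINK"
    return model
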