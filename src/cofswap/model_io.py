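"""Read and write metabolic models and flux results.

SBML (Level 3 / FBC, Level 2) and a JSON dialect are supported through
cobrapy's I/O layer; JSON is the repo-internal canonical fixture format
because it is solver-agnostic and diffable.  Flux tables are plain TSV with
an optional percent-of-acetate-uptake column matching how the study reports
fluxes (every rate as % of Q_ac).
"""

from __future__ import annotations

import math
from pathlib import Path

import cobra.io
import pandas as pd
from cobra import Model

from .core import FluxDistribution, FluxRange, validate_model

__all__ = [
    "read_sbml",
    "read_json",
    "read_model",
    "write_model",
    "write_flux_table",
    "find_reaction",
]

# The study mixes parenthesis-style exchange ids (EX_ac(e)) with BiGG
# underscore style (EX_ac_e); both are accepted everywhere a reaction id
# is looked up.
def _id_dialects(reaction_id: str) -> list[str]:
    alts = [reaction_id]
    if reaction_id.endswith("(e)"):
        alts.append(reaction_id[:-3] + "_e")
    elif reaction_id.endswith("_e"):
        alts.append(reaction_id[:-2] + "(e)")
    return alts


def find_reaction(model: Model, reaction_id: str):
    """Resolve a reaction id, accepting EX_x(e) and EX_x_e dialects."""
    for rid in _id_dialects(reaction_id):
        if model.reactions.has_id(rid):
            return model.reactions.get_by_id(rid)
    raise KeyError(f"reaction {reaction_id!r} not in model {model.id!r}")


def read_sbml(path: str | Path) -> Model:
    """Load an SBML model (L3/FBC or L2 with kinetic-law bounds)."""
    model = cobra.io.read_sbml_model(str(path))
    validate_model(model)
    return model


def read_json(path: str | Path) -> Model:
    model = cobra.io.load_json_model(str(path))
    validate_model(model)
    return model


def read_model(path: str | Path) -> Model:
    """Dispatch on extension: .json → JSON dialect, anything else → SBML."""
    path = Path(path)
    if path.suffix == ".json":
        return read_json(path)
    return read_sbml(path)


def write_model(model: Model, path: str | Path, format: str | None = None) -> Path:
    """Serialize a model losslessly (S entries, bounds, objective).

    ``format`` is ``"sbml"`` or ``"json"``; inferred from the extension when
    omitted.
    """
    path = Path(path)
    fmt = format or ("json" if path.suffix == ".json" else "sbml")
    validate_model(model)
    if fmt == "json":
        cobra.io.save_json_model(model, str(path))
    elif fmt == "sbml":
        cobra.io.write_sbml_model(model, str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")
    return path


def write_flux_table(
    result: FluxDistribution | FluxRange,
    path: str | Path,
    qac: float | None = None,
    sep: str = "\t",
) -> Path:
    """Write one row per reaction: id, flux (or min/max), % of Q_ac.

    The percentage column is sign-preserving, ``100 · flux / qac``, and only
    present when ``qac`` is given.  Percentages are raw in the file; display
    rounding is the consumer's concern.
    """
    path = Path(path)
    if isinstance(result, FluxDistribution):
        df = pd.DataFrame({"reaction_id": result.fluxes.index,
                           "flux": result.fluxes.to_numpy()})
        if qac is not None:
            df["pct_of_qac"] = 100.0 * df["flux"] / qac
    else:
        df = result.ranges.reset_index(names="reaction_id")
        if qac is not None:
            df["pct_min"] = 100.0 * df["minimum"] / qac
            df["pct_max"] = 100.0 * df["maximum"] / qac
    if qac is not None and (qac <= 0 or math.isnan(qac)):
        raise ValueError("qac must be a positive rate")
    df.to_csv(path, sep=sep, index=False)
    return path
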