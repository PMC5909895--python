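"""Sub-optimal flux-space characterization by hit-and-run sampling.

Growth is only required to reach 90% of the measured rate (sub-optimal
conditions), acetate uptake stays fixed, and the feasible polytope is
sampled with the artificially centered hit-and-run (ACHR) chain.  Post-hoc
filtering on one reaction's flux (e.g. keeping samples with PntAB below 75%
of its optimal flux) probes how the rest of the network redistributes when
the primary balancing response is unavailable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from cobra import Model
from cobra.sampling import ACHRSampler

from .core import PhysiologicalConstraints
from .model_edit import apply_strain
from .model_io import find_reaction

__all__ = [
    "SampleSet",
    "sample_fluxes",
    "filter_samples",
    "flux_histogram",
]


@dataclass(frozen=True)
class SampleSet:
    """Matrix of sampled flux vectors (rows = samples, columns = reactions)."""

    samples: pd.DataFrame
    seed: int
    thinning: int
    strain: str = ""
    growth_fraction: float = 1.0

    def __len__(self) -> int:
        return len(self.samples)

    def __getitem__(self, reaction_id: str) -> pd.Series:
        return self.samples[reaction_id]


def sample_fluxes(
    model: Model,
    constraints: PhysiologicalConstraints | None = None,
    growth_fraction: float = 0.9,
    n_samples: int | None = None,
    seed: int = 0,
    thinning: int = 100,
    biomass_id: str = "BIOMASS",
    atpm_id: str = "ATPM",
    atpm_bounds: tuple[float, float] | None = (0.0, 50.0),
    validate: bool = True,
) -> SampleSet:
    """Sample the sub-optimal flux polytope with ACHR.

    The biomass lower bound is set to ``growth_fraction·μ`` (its upper bound
    released), acetate uptake is fixed at −Q_ac, and ATPM is left free on
    ``atpm_bounds`` — only growth is constrained to sub-optimality, not
    energy.  ``n_samples`` defaults to twice the reaction count.
    Reproducible for a fixed seed.
    """
    work = model.copy()
    strain = ""
    if constraints is not None:
        strain = constraints.strain
        apply_strain(work, constraints, fix_growth=False)
        bm = find_reaction(work, biomass_id)
        bm.lower_bound = growth_fraction * constraints.mu
        bm.upper_bound = max(bm.upper_bound, constraints.mu)
    if atpm_bounds is not None and work.reactions.has_id(atpm_id):
        atpm = work.reactions.get_by_id(atpm_id)
        atpm.lower_bound, atpm.upper_bound = atpm_bounds
    if np.isnan(work.slim_optimize()):
        raise RuntimeError("constraints are infeasible; nothing to sample")
    if n_samples is None:
        n_samples = 2 * len(work.reactions)

    sampler = ACHRSampler(work, thinning=thinning, seed=seed)
    if sampler.n_warmup < 2:
        # degenerate (point) polytope: every sample is the unique solution
        sol = work.optimize()
        df = pd.DataFrame(
            [sol.fluxes.to_numpy()] * n_samples,
            columns=sol.fluxes.index)
    else:
        df = sampler.sample(n_samples)
    if validate:
        check = df.sample(min(50, len(df)), random_state=seed)
        flags = sampler.validate(check.to_numpy())
        if not all(f == "v" for f in flags):
            warnings.warn(
                f"{sum(f != 'v' for f in flags)} of {len(flags)} checked "
                "samples violate bounds/steady state beyond tolerance"
            )
    return SampleSet(samples=df, seed=seed, thinning=thinning,
                     strain=strain, growth_fraction=growth_fraction)


def filter_samples(
    samples: SampleSet, reaction_id: str, upper_bound: float
) -> SampleSet:
    """Keep rows whose flux through ``reaction_id`` is ≤ ``upper_bound``."""
    kept = samples.samples[samples.samples[reaction_id] <= upper_bound]
    if kept.empty:
        warnings.warn(
            f"filter {reaction_id} <= {upper_bound} removed every sample"
        )
    return replace(samples, samples=kept.reset_index(drop=True))


def flux_histogram(
    samples: SampleSet, reaction_id: str, bins: int = 30
) -> tuple[np.ndarray, np.ndarray, float]:
    """Histogram of one reaction's sampled fluxes.

    Returns ``(bin_edges, counts, mode)`` where the mode is the midpoint of
    the highest-count bin (ties resolved to the lowest bin).
    """
    if len(samples) == 0:
        raise ValueError("empty sample set")
    values = samples[reaction_id].to_numpy()
    counts, edges = np.histogram(values, bins=bins)
    imode = int(np.argmax(counts))  # first maximum = lowest bin on ties
    mode = 0.5 * (edges[imode] + edges[imode + 1])
    return edges, counts, mode
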