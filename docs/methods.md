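# Methods

## Model and constraints

The analysis operates on a stoichiometric model at steady state: fluxes
`v` (mmol gDW⁻¹ h⁻¹; the biomass flux in h⁻¹) satisfy `S·v = 0` within
per-reaction bounds, and objectives are linear (FBA). The in-memory
container is a `cobra.Model`; SBML (L3/FBC and L2) and a JSON dialect are
read and written through cobrapy's I/O layer. JSON is the repo-internal
canonical fixture format because it is solver-agnostic and diffable. Both
exchange-id dialects, `EX_ac(e)` and `EX_ac_e`, are accepted wherever a
reaction is looked up.

A strain is a `PhysiologicalConstraints` record: measured growth rate μ,
measured acetate uptake Q_ac, a cofactor-swap fraction, and knockout ids.
Strain edits are applied in a fixed order — swap, knockouts, POR5
irreversibility, bounds — so preparation is deterministic and idempotent.
Acetate uptake is imposed as an equality (lb = ub = −Q_ac), and so is μ in
the iterative workflow; sensitivity analyses manage the biomass bounds
themselves. Treating Q_ac as an equality rather than a cap is a design
choice: with uptake capped instead, any energy-maximizing solve would leave
it at the cap anyway, and the equality keeps infeasibilities explicit.

The fractional cofactor swap rewrites one reaction's stoichiometry in
place: a fraction f of the pristine NADP⁺/NADPH coefficients moves onto
NAD⁺/NADH, so a partial swap is mixed stoichiometry in a single reaction
and LP dimensionality is constant across a 0–100% scan. Pristine
coefficients are stashed on the reaction at first edit; every swap is
expressed from them, never chained, and the summed coefficient of each
redox pair (oxidized and reduced) is invariant for any f.

## Iterative optimization

With μ and Q_ac fixed, maximal-ATP-yield FBA is massively degenerate:
alternate optima and internal loops able to carry arbitrary flux. The
procedure resolving this:

1. release ATPM to (0, 50) mmol gDW⁻¹ h⁻¹;
2. maximize ATPM (LP) — the maximal ATP yield;
3. pin the result as the ATPM lower bound;
4. minimize the O₂ uptake magnitude (LP), i.e. maximize the negative
   exchange flux toward zero;
5. fix the O₂ exchange at that minimum;
6–7. enumerate the first n = 400 ATPM-optimal distributions by MILP;
8. select the one minimizing Σᵢvᵢ²;
9. pin lb = ub = v for every reaction with |v| < 500 mmol gDW⁻¹ h⁻¹
   (absolute value: reversible reactions carry signed flux), leaving
   suspected loop carriers free;
10–11. re-enumerate and re-select.

The MILP enumeration attaches one binary yⱼ per reaction with big-M linking
(−M·yⱼ ≤ vⱼ ≤ M·yⱼ, M = 1000 — the default bound magnitude), adds
objective optimality as a constraint, minimizes Σyⱼ so each iterate is
support-minimal, and excludes each found active set and its supersets with
the integer cut Σ_{j∈support} yⱼ ≤ |support| − 1. Each support is then
"polished": inactive reactions are closed and the original LP re-solved, so
reported distributions attain the optimum exactly rather than within the
MILP tolerance. Discovery order is the enumeration order; no secondary
ranking exists. The Σv² selection is over the enumerated discrete set (not
a QP over the optimal face), with ties broken by first index, which
together with a deterministic solver (GLPK) makes reruns bit-identical.
Per-cut MILP time limit: 60 s, configurable; hitting it yields a flagged
partial enumeration, not an error.

Key invariants, all tested: the final ATPM equals the step-2 maximum; the
final distribution satisfies S·v = 0, all bounds and the pinned μ, Q_ac,
O₂; on a fixture with a unique optimum the procedure reduces to plain FBA
plus lexicographic O₂ minimization; on loop fixtures the selected solution
carries zero cycle flux.

## Sensitivity analyses

`robustness` fixes a control reaction on a value grid and re-optimizes;
infeasible points are reported with status, never dropped or interpolated.
`partition_constrained_fba` adds the single equality
v_ICL − p·(v_ICL + v_ICDH) = 0 for one solve and removes it afterwards.
`phase_plane` grids (isocitrate production) × (partition p), where
isocitrate production is measured as v_ICL + v_ICDH — at steady state the
total flux leaving the branch point equals the aconitase input — with ATPM
pinned at its strain optimum first, reporting biomass yield μ/Q_ac per
cell. FVA follows the same convention (μ, Q_ac fixed and ATPM lower-bounded
at its optimum) unless the caller overrides it; this is what makes results
like "maximal UdhA flux is zero after the swap" well-posed.

Requested solver tolerances are 10⁻⁹ (feasibility); test comparisons are at
10⁻⁶.

## Sub-optimal sampling

`sample_fluxes` bounds biomass below by 0.9·μ (only growth is constrained
to sub-optimality — ATPM stays free on (0, 50)), fixes Q_ac, and runs
cobrapy's artificially-centered hit-and-run sampler (warmup 2× reaction
count from FVA-extreme points, the sampler's convention; thinning 100 by
default; reversible reactions sampled as single signed dimensions). The
default sample count is twice the reaction count. A random subsample of
rows is validated against bounds and S·v = 0. A zero-dimensional polytope
(all bounds fixed) is handled by replicating the unique solution. Sampling
is reproducible per seed; histogram modes are bin midpoints with ties to
the lowest bin. Warmup and thinning of the original published chains are
not reported anywhere, so sampled histograms are compared only in ordering
and direction, never numerically.

## Accounting

Net turnover of metabolite i is φᵢ = ½ Σⱼ |S(i,j)·vⱼ|; at steady state this
equals both total production and total consumption, an identity tested on
random null-space vectors. ATP allocation splits φ(ATP) into the ATPM flux
(non-growth maintenance) and ATPμ = φ(ATP) − ATPM. A reaction is a source
of a cofactor when S(reduced species, j)·vⱼ > 0, so a transhydrogenase
appears as producer on one ledger and consumer on the other. Percentages
are 100·flux/Q_ac, sign-preserving; tables round to one decimal, machine
output keeps full precision.

## The core acetate fixture

`core_acetate_model()` is a ~25-reaction network: acetate exchange with a
duplicated transporter pair (a built-in degenerate-optimum structure),
acetyl-CoA activation, a lumped TCA cycle with NADP⁺-ICDH, the glyoxylate
shunt as the only anaplerotic route, an NADP⁺-malic enzyme, lumped
gluconeogenesis and oxidative PPP (2 NADPH per G6P), both
transhydrogenases, a lumped oxidative phosphorylation (P/O = 2), ATPM, and
a biomass reaction that consumes OAA, 2-oxoglutarate, ribose-5-P, 16 NADPH
and 80 ATP per unit growth — NADPH explicitly, so the swap propagates to
growth. The succinate-dehydrogenase/fumarate-reductase pair forms a genuine
internal loop able to carry flux at bound scale. PntAB carries an explicit
0.75 ATP cost per NADPH as a proton-motive-force proxy; it makes PntAB
strictly the cheapest NADPH source after the swap (the alternative
malic-enzyme route costs 3 ATP-equivalents per NADPH at these
coefficients), so the optimal balancing response is unique and the
UdhA-off/PntAB-on switch is reproduced rather than left to solver
tie-breaking. Stoichiometric coefficients are rational, bounds ±1000, and
the biomass composition was chosen once so that all four strain constraint
sets are simultaneously feasible with slack for maintenance ATP.

Companion sidecar dicts freeze reference optima (maximal biomass native and
swapped, zero biomass with ICL blocked, the optimal ICL partition at
Q_ac = 10) computed through an independent LP route — scipy's HiGHS on the
raw matrix — and tests assert the package's GLPK results against them. The
partition-vs-yield curve of the fixture shows the three regimes the
genome-scale analysis finds: a strictly rising limb (carbon lost as CO₂
when the TCA branch dominates), a slightly declining plateau, and a
collapse to zero at 100% ICL.

What the fixture does not emulate: genome-scale magnitudes. Measured μ and
Q_ac act as constraints, but quantities like the ATPM ratio between swapped
and wild-type strains (~1.9 here) or partition vertices (32%/20% here) are
properties of the toy stoichiometry; passing tests demonstrate the
mechanisms and the machinery, not iJO1366 numbers. Runs against a
genome-scale SBML use exactly the same code paths via `read_sbml`.

## Problem sizes and defaults

Defaults mirror the study conditions: ATPM release (0, 50), 400 enumerated
optima, 500 threshold, 0.9 growth fraction, 0.75 PntAB filter, strain
parameters as packaged. On the core fixture the enumeration exhausts after
a handful of support-distinct optima, so the full four-strain pipeline
including the acceptance script completes in seconds; sampling in tests
uses a few hundred points with thinning 10–50, which is ample for the
qualitative assertions made. The uniformity check runs 2000 samples on a
one-dimensional segment (KS test).

## Known limitations

- Loop removal is the thresholding heuristic of the procedure, not
  loopless-FBA; a cycle entirely below threshold would be pinned, not
  removed (none exists in the fixtures).
- "First 400 optima" is well-defined only up to the enumeration order of
  the integer-cut recursion.
- The Σv² step selects among enumerated solutions; a QP over the whole
  optimal face could select a point off the enumerated set and is
  deliberately not the default.
- Gene–protein–reaction logic beyond direct reaction knockouts is out of
  scope, as are kinetics and regulation (ICDH phosphorylation, PntAB
  expression control).
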