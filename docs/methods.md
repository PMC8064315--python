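# Methods

## The integration model

A genome-scale metabolic model is interrogated as a linear program:
maximize the biomass flux `Z = c'V` subject to steady state `S·V = 0`
and bounds `l ≤ V ≤ u`.  All biological content beyond stoichiometry
enters through the bounds, and this package sets them from two data
sources at once.

**Expression side (RAS).**  Each reaction's Boolean gene–protein–
reaction rule is evaluated quantitatively over TPM values: `or`
(isozymes) sums, `and` (complex subunits) takes the minimum, a single
gene passes its TPM through.  This assumes enzyme capacity (Vmax) is
proportional to transcript abundance with one common constant for all
reactions — differential translation, post-translational regulation
and kcat differences are deliberately ignored.  The bound of a
gene-associated reaction *i* becomes `b_i = α·RAS_i`: a reversible
reaction gets `[−b_i, +b_i]`, an irreversible one `[0, +b_i]` (or
`[−b_i, 0]`), with direction read from the model's *default* bounds so
that later constraining stages never flip admissible directions.
Geneless reactions keep their defaults (±1000); boundary reactions and
the biomass pseudo-reaction are never RAS-bounded.  A RAS of 0 closes
its reaction — no epsilon floor is applied, because the zero-rescue
step (below) is the mechanism that deals with spurious zeros.

**Medium side (MUR).**  The maximal uptake rate of nutrient *j* is
`|Δ[S_j]| / Δt` over the culture duration (default 48 h).  By default
the final concentration is taken as 0 (everything offered could be
consumed), so MUR is numerically the starting concentration on the
mM-per-2-days scale; per-metabolite final concentrations can be
supplied for the general form.  MUR enters as the exchange lower bound
`l_j = −MUR_j` (uptake-negative convention).  A nutrient at 0 mM — or
absent from the table — has its uptake closed, but its *transport*
reaction is untouched: transport flux is zero for lack of substrate,
not by constraint.  Export bounds are never modified, so whatever the
source model allows to be net produced stays exportable.

**The scaling factor α.**  RAS and MUR live on incommensurate scales;
α is the single conversion constant and the model's only fitted
parameter.  No other normalization is applied, which keeps the
composition transparent: `(α·k, TPM*/k)` provably yields bit-identical
bounds to `(α, TPM*)` (a tested invariant).  α is chosen by scanning a
logarithmic grid (default 61 points over [3·10⁻⁴, 1.6]) from the
uptake-limited regime downwards and selecting the largest grid value
at which a designated set of conditions converges to equal maximal
biomass while still strictly dominating a second set.  Convergence is
assessed per expression profile at a relative tolerance (default
1e-3); an α satisfying dominance but not convergence is reported as
absent rather than approximated.

## Preprocessing

Order of operations in `build_gensi_model`: block sinks/demands →
lipid-pool patch (optional) → zero-adjust → gene matching → RAS →
block non-medium uptakes → MUR → exchange bounds → α·RAS bounds.
Every bound change is appended to a provenance log (stage, reaction,
old and new bounds).

*Zero rescue.*  RNA-seq zero inflation is corrected against a
microarray dataset: for each gene with TPM 0 that the microarray did
measure, `TPM* = (intensity / microarray genome-wide median) ×
(RNA-seq genome-wide median)`.  Both medians are taken over **all**
genes of the respective dataset, not only metabolic genes.  Zeros
without microarray coverage stay 0 and are reported.  A zero
microarray median is an error (the ratio is ill-defined).

*Gene matching.*  Model symbols are resolved directly, then through an
alias table (dataset symbol → model symbol); genes still unmatched are
assigned the maximum TPM* among matched genes, so that an unmeasured
gene can never be the limiting factor of any reaction.  Zero-rescue
runs *before* max-assignment, so unmatched genes inherit the maximum
of adjusted scores.  Duplicate input rows (transcript-level tables)
are summed to gene level and logged.

*Curation patches.*  Sink and demand reactions bypass mass balance and
are closed to [0, 0]; identification is by id prefix (`sink_`/`SK_`,
`DM_`) on single-metabolite boundary reactions, with a configurable
override list.  The acyl-pool patch merges positional Rtotal-type
species into one pool and adds the reversible pooling reaction
`1 stearoyl-CoA + 1 palmityl-CoA + 1 oleoyl-CoA + 1 octadecadienoyl-CoA
↔ 4 Rtotal-CoA` (a fixed 1:1:1:1 tail ratio), which restores lipid and
hence biomass synthesis in reconstructions whose triglyceride pathway
otherwise depends on a sink.

## Optimization

COBRApy with the GLPK backend solves all LPs.  FBA reports
infeasible/unbounded through a status field, never an exception.  The
FVA loop is implemented in this package: after the base solve, the
biomass lower bound is raised to `γ·Z0` (minus a 1e-9 relative slack
so γ = 1 survives LP round-off) and each target reaction is minimized
and maximized in turn.  Implementing the loop in-house is what allows
the ATP protocol to be exact: the irreversible probe
`ATP + H2O → ADP + Pi + H+` is added only for its own capacity
measurement and removed afterwards, so no maintenance drain exists
during any other analysis.  Objective values are the canonical
outputs; individual fluxes of non-extreme reactions are degenerate on
the optimal face and are never asserted in tests.

Growth rates from cell counts use the linear reading of
"reciprocal doubling time": a least-squares line `N(t) = a + b·t`,
doubling time `a/b` (the time to add the intercept's worth of cells),
rate `b/a` per hour.  An exponential fit would be the other defensible
reading; the linear one is fixed here and flat/declining fits return
rate 0 with a flag.

## The toy fixture family

`make_toy_gem` emits a 20-reaction, 19-metabolite model with one
extracellular and one cytosolic compartment: exchanges for glucose,
glutamine, phenylalanine, lactate, pyruvate, O2, CO2 and a proton
vent; gene-bearing transporters for glucose/glutamine/phenylalanine;
lumped glycolysis (AND complex, 2 ATP + 2 pyruvate per glucose),
lactate dehydrogenase (OR isozyme pair), glutaminolysis (1 pyruvate +
2 CO2 per glutamine, no net substrate-level ATP — surplus ATP would
have no sink, as the model deliberately carries no maintenance
ATPase), oxidative phosphorylation (AND complex, 15 ATP per pyruvate
at 3 O2), and a biomass reaction consuming 1 phenylalanine + 5 ATP.
ADP/Pi/H2O cycle as conserved moieties.  All stoichiometry is
integer.  Optional variants add (a) a sink/demand pair — the sink is a
hidden phenylalanine source when open, so blocking it measurably
lowers the optimum — and (b) an acyl-pool dead end that makes biomass
infeasible until the pooling patch is applied.

The fixture's quantitative design makes the full-scale phenomenology
reproducible at desk scale:

- Media NA1–NA6 vary glucose/glutamine as (25, 4), (25, 0), (5.6, 4),
  (5.6, 0), (0, 4), (0, 0) mM over 48 h on a background of 10 mM
  phenylalanine and 3 mM O2.  The O2 ceiling caps respiration (at most
  1 pyruvate oxidized per 2d), so carbon-rich media are limited by the
  phenylalanine supply and carbon-poor ones by ATP — giving the
  high-α ordering NA1 = NA2 > NA3 = NA4 > NA5 > NA6.
- Designed model-gene TPMs place phenylalanine transport (RAS 10) as
  the shared low-α bottleneck of every glucose-containing medium
  (glycolytic ATP capacity 2·30 comfortably exceeds the 5·10 the
  phenylalanine-limited biomass needs), while the glutamine pathway
  (RAS 2) keeps the glutamine-only medium strictly below — the same
  convergence-with-dominance pattern the α-selection rule looks for.
- Carbon accounting is exact: at maximal biomass the FVA lactate
  maximum equals `2·MUR_glc + 1·MUR_gln` and the minimum is 0, since
  the ATP demand can be met by glycolysis alone and surplus pyruvate
  may leave as pyruvate.

The synthetic expression tables force a seeded fraction (default 10%)
of genes to TPM 0, drawn from the below-median stratum — where
dropouts occur, and which leaves the dataset median invariant so that
the microarray (the true expression on an arbitrary intensity scale)
rescues every zero back to its designed value exactly.  A log-normal
background population (median ~1 TPM) emulates genome-wide context for
the median computations.

What the fixtures do *not* emulate: the size and redundancy of a human
reconstruction (thousands of reactions, extensive isozyme overlap),
realistic transcriptome covariance, element/charge balancing, proton
and osmotic effects, transporter kinetics, or noise in medium
composition.  Passing tests therefore demonstrate correctness of the
integration machinery and the qualitative regime structure, not
quantitative agreement with any particular cell line.

## Numerical conventions

- Solver: GLPK via optlang; deterministic for identical inputs.
  Objective values are reproducible to ~1e-9; flux vectors only up to
  the optimal face.
- FVA γ defaults to 1 (the analysis regime of interest); 0 ≤ γ < 1 is
  exposed for sub-optimal analyses.
- Feasibility slack on the γ·Z0 constraint: 1e-9 relative.
- Test tolerance against independent LP oracles (scipy/HiGHS linprog,
  plus exhaustive candidate-vertex enumeration on the smallest
  fixtures): 1e-6 absolute.
- Problem sizes: the toy model (20 reactions) and six mini fixtures
  (≤ 12 reactions each); α-scans in tests use 21–31 grid points over
  [3·10⁻⁴, 1.6] across six media, a few hundred LP solves per scan.

## Known limitations

- The linear Vmax–transcript assumption and the equal-kcat assumption
  are strong; RAS magnitudes are only meaningful relative to one
  another and to α.
- MUR treats the medium table as exhaustive (serum-derived trace
  nutrients are unquantified) and ignores transporter saturation;
  uptake bounds scale linearly with concentration.
- α-selection depends on the grid resolution; the reported α* is a
  grid point, not an interpolated root.
- Sink/demand identification relies on id conventions plus structure;
  nonstandard reconstructions may need the override list.
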