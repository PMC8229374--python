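# Methods

This note documents the models, algorithms and design choices behind
`cgemkit`: what each stage computes, which parameters matter, what the
synthetic data generator does and does not emulate, and where the design was
genuinely open.

## Scope and workflow

The package benchmarks context-specific metabolic model ("CGEM") extraction.
Given a flux-consistent genome-scale metabolic model (GEM) and per-sample
expression profiles, it (1) maps gene expression onto reactions through GPR
rules, (2) extracts a context-specific submodel per sample with one of four
algorithms (GIMME, iMAT, INIT, FASTCORE), (3) computes each submodel's FBA
flux state, and (4) quantifies heterogeneity across submodels: Warburg flux
ratios and hallmark-gene activation per CGEM, subsystem-averaged Jaccard and
Bland-Altman agreement per CGEM pair, and PCA + random-forest flux
fingerprinting per dataset-algorithm cell.

## Constraint-based core

**FBA.** `fba` maximizes the objective (biomass) subject to steady state
`S v = 0` and flux bounds. An LP optimum is generally a degenerate vertex:
which one a solver returns is arbitrary, yet the downstream statistics
consume whole flux vectors. The returned vector is therefore refined by a
secondary L1-norm flux minimization at the fixed optimal objective (a
pFBA-style tie-break), making flux states reproducible across runs and
platforms. Infeasibility and unboundedness are reported as a status on the
returned `FluxState`, not as exceptions.

**FVA** solves the per-reaction min/max LPs, optionally holding the objective
at a fraction of its optimum. It exists mainly as a simple, independent
characterization of attainable fluxes.

**FASTCC.** A reaction is flux-consistent iff some feasible flux distribution
carries at least `epsilon` absolute flux through it. The implementation
certifies blocks with LP-7-style support maximization (auxiliary variables
`0 <= z_r <= epsilon`, `v_r >= z_r`, maximize `sum z`), then settles
stragglers with singleton probes in both orientations of reversible
reactions. Because a blocked reaction carries no flux in any feasible
distribution, removing it never changes any other reaction's status; the
resulting partition is independent of examination order and equals the
FVA-derived set `{ r : max attainable |v_r| >= epsilon }` (verified against a
brute-force oracle in the acceptance suite).

**Numerics.** All LPs and MILPs go through one scipy/HiGHS backend with a
single `SolverConfig`: feasibility tolerances of 1e-9 requested from the
solver, 1e-6 asserted on returned solutions (steady-state residual and bound
violations), activity threshold `epsilon = 1e-4`. Thresholds below the 1e-6
floor are clamped with a warning — an activity threshold below LP feasibility
tolerance (such as the 1e-10 sometimes quoted for consistency checking) is
not meaningful at solver precision.

## Expression preprocessing and GPR mapping

Technical replicates are averaged with missing entries ignored, then each
profile is min-max scaled, `(value - min) / (max - min)`, independently per
sample. Per-sample scaling was chosen (the scope of the normalization was an
open question) because every downstream threshold is a quantile *within* a
profile, making the analysis invariant to per-sample scale anyway.

GPR mapping evaluates the boolean tree recursively: AND (enzyme complex)
takes the minimum of its children, OR (isozymes) the maximum. Genes without
data are MISSING; MISSING children are dropped at each node and a node with
no informative child is itself MISSING, matching common COBRA mapping
behavior for partial coverage. A reaction with no GPR has no activity value.
Mapping is monotone: raising any gene's expression never lowers any
reaction's activity (property-tested on random trees).

## Extraction algorithms

All four algorithms share an `ExtractionConfig`. The expression thresholds
are quantiles of the non-missing mapped activities of the sample at hand:

| parameter | default | used by | meaning |
|---|---|---|---|
| `expression_threshold` | 0.25 | GIMME, INIT | activity quantile separating "expressed" |
| `high_quantile` / `low_quantile` | 0.75 / 0.25 | iMAT | highly/poorly expressed sets |
| `core_quantile` | 0.75 | FASTCORE | core = confidently active reactions |
| `epsilon_active` | 1e-4 | all | flux level defining an active reaction |
| `biomass_fraction` | 0.9 | GIMME | objective retention in stage 2 |

FASTCORE gets its own core quantile: its contract is to *add* the minimal
support around a core of confidently active reactions, so the core must be
the strongly expressed set (matching iMAT's high set), not everything above
the loose GIMME/INIT threshold — with a 0.25-quantile core FASTCORE would
return the largest models of all four algorithms, inverting its character.

**GIMME** solves two LPs: the biomass optimum `z*`, then minimization of
`sum_r w_r |v_r|` over below-threshold reactions (`w_r = threshold -
activity_r`) subject to `biomass >= biomass_fraction * z*`. Kept reactions
are the expressed ones, the flux carriers of the stage-2 solution, the
protected set — and reactions with MISSING activity. Only reactions the data
actively classifies as inactive are removal candidates: whether an *unmapped*
reaction happens to carry flux in the stage-2 solution is a property of the
solver's vertex choice, not of the data, and must not decide membership.

**iMAT** solves a MILP maximizing agreement with the high/low classification:
per high reaction one binary per direction rewarding `|v_r| >= epsilon` (at
most one active), per low reaction a binary rewarding `v_r = 0`.
Unclassified reactions are retained. The reported agreement equals the
exhaustively enumerated optimum on small fixtures.

**INIT** solves a MILP maximizing `sum_r w_r y_r` with `w_r = activity_r -
threshold` and `y_r` indicating `|v_r| >= epsilon` (big-M linking with a
direction binary for reversible reactions). The steady-state condition can
be relaxed to a bounded net accumulation `0 <= b_m <= accumulation_max` for a
configurable metabolite set (empty by default in toy mode). Zero-weight
(unmapped) reactions carry no binary and are kept iff they carry flux at the
optimum; with no usable weights at all the result degenerates to the
protected closure.

**FASTCORE** implements the sparse-mode loop: LP-7 support maximization over
the remaining core, then an L1-sparsity LP over non-core reactions with the
certified core fluxes forced well above `epsilon`, flipping the orientation
of reversible core reactions that fail forward activation, falling back to
singleton targets before declaring a core reaction inconsistent (an error
naming the reaction). A final deterministic compaction pass greedily drops
non-core support reactions whose removal leaves the core flux-consistent;
the union of sparse modes otherwise occasionally carries a few redundant
reactions. The output contains core and protected sets and is
flux-consistent; near-minimality is a heuristic property, checked against an
exhaustive minimal-superset search on small random networks.

**Protected reactions and finalization.** The six reserved reactions
(biomass, ATP demand, GAPD, ATPS4mi, D_LACt2, O2t — or their configured
analogues) can never be removed. Every extraction ends the same way: the
kept set is augmented with the protected set plus the support of one
L1-minimal flux distribution that activates all protected reactions
simultaneously (so they are not just present but operational), the induced
submodel is re-checked with FASTCC at `epsilon_active`, and inconsistent
leftovers are pruned. Whether published pipelines re-checked their
context models for consistency is not documented; this package enforces it
so that FBA on every CGEM is well-posed, and records the pruned count in the
diagnostics.

## Heterogeneity statistics

**Warburg scores.** AFR = flux(GAPD)/flux(ATPS4mi) (glycolytic vs oxidative
ATP), EOR = flux(D_LACt2)/flux(O2t) (lactate transport vs oxygen transport).
Transport fluxes are positive for uptake, so a lactate-secreting,
oxygen-consuming state has EOR < 0. A zero denominator yields NaN plus a
flag, never a silent zero.

**Hallmark activation** is the percentage of hallmark-list genes, among
those present in the parent model, that remain linked through a GPR to any
kept reaction — the denominator mirrors the fact that curated hallmark lists
contain genes absent from any given reconstruction.

**Jaccard.** Computed per subsystem and averaged over subsystems with a
non-empty union, so small pathways weigh as much as large ones. Reactions
without a subsystem annotation live in the sentinel subsystem `unassigned`,
keeping the average total. The subsystem inventory always comes from the
loaded model, never from a hard-coded count.

**Bland-Altman.** Flux vectors are aligned over the union of reactions with
absent-in-CGEM reactions imputed as zero (they can carry none); an
intersection-only alignment is available. Differences are raw (`a - b`) or
percent (`100 (a-b)/mean`, zero-mean pairs dropped and counted). Limits of
agreement are `mean(d) +/- 1.96 sd(d)`; the p-value is a two-sided one-sample
t-test of the differences against zero (Wilcoxon available). Note the
location test detects *systematic* (one-sided) flux differences; two models
differing by equal-and-opposite blocks of reactions have mean difference
near zero and are not flagged — visible in the synthetic benchmark, where
symmetric marker designs yield low disagreement fractions and graded
(nested) designs yield high ones.

**PCA + k-means.** Columns are centered but not variance-scaled — flux
magnitudes are the signal; a scaling option exists. Cluster count is the k
in 2..max_k maximizing the mean silhouette of k-means on the first two PC
scores, with two guards: k never exceeds the number of *distinct* score
points (extra clusters would only split coincident fingerprints), and a
single cluster is declared when the best silhouette is below 0.55. The floor
was calibrated on structure-free data: k-means on the first two PCs of
isotropic Gaussian matrices attains max silhouettes around 0.44 (maximum
0.51 over 60 null draws), while genuinely planted clusters score above 0.9,
so 0.55 separates the regimes with margin. Fluxes are rounded at the 1e-6
solver tolerance when the flux matrix is assembled; differences below it are
numerical dust.

**Random forest.** `ntree = 500` trees, `floor(sqrt(p))` candidate features
per split, impurity importance, fixed seed (bit-reproducible). The response
variable is the PCA cluster labels; cells with fewer than two clusters are
excluded (attempting RF on one class is an error). The top k = 15 reactions
(matching the feature-list size used in this kind of benchmark) are
aggregated by subsystem; summing these frequencies across dataset-algorithm
cells gives the subsystem "barcode" of most-affected pathways.

## Synthetic data

`make_toy_model` builds a deterministic 40-reaction, 8-subsystem network
whose six reserved reactions carry the canonical ids directly. The core
couples glucose uptake and lumped glycolysis (net 2 ATP, 2 NADH, 2 pyruvate
per glucose) to a biomass reaction (10 ATP per unit), with two NADH sinks:
oxidative phosphorylation at P/O 2.5 behind a capped oxygen exchange (5 flux
units vs 10 for glucose), and lactate dehydrogenase plus lactate export.
Because oxygen — not glucose — limits ATP, the biomass optimum always
oxidizes at capacity *and* secretes lactate: AFR > 0 and EOR < 0 hold at any
optimum by construction, which is the designed analogue of the universal
Warburg signs in real cancer CGEMs. A pentose-phosphate bypass and a lumped
TCA branch provide alternative routes, and `n_pathways` (default 6) optional
nutrient modules (exchange + transporter + catabolic step, each in its own
subsystem with its own genes) provide small ATP bonuses. Module uptake
capacities differ between nutrients with compensating molar yields, so each
module contributes the same bonus to the core while its own flux magnitudes
stay module-specific — group fingerprints stay in general position for PCA
without leaking group identity into the shared core fluxes.

`simulate_expression` draws a per-gene log-normal baseline (`LogNormal(1,
0.6)`) shared by a dataset, floored at 1.5 for core genes and fixed at 4.5
for module genes, applies each group's planted fold changes (default 4-fold
up, 4-fold down) to the genes of the planted subsystems, multiplies
per-sample log-normal jitter and adds per-replicate Gaussian noise
(`noise_sd = 0.1`), and censors genes per sample at the platform's
missingness rate (rnaseq 2%, microarray 8%, proteome 35% — proteome profiles
cover far fewer genes). The fixed module baselines make planted fold changes,
not lucky baseline draws, decide a marker's rank relative to the expression
thresholds: at baseline modules sit above the lower quartile, down-regulated
they fall below the core floor. The default design gives each of
`n_groups` (default 4, 5 samples, 2 replicates) groups one up-regulated
marker module and down-regulates the other groups' markers; the ground-truth
record lists the planted genes and the reactions of every subsystem whose
fold differs between groups.

What the generator does *not* emulate: probe-level microarray artifacts,
sequencing depth, protein-to-transcript discordance, batch effects,
within-group biological pathway heterogeneity, or anything about real human
metabolism's scale (40 reactions vs ~13,000). Passing tests therefore show
that the pipeline's machinery is correct and that its statistics behave as
designed under controlled conditions — not that the biological conclusions
drawn from real compendia would replicate.

## Benchmark orchestration

`run_benchmark` executes load → FASTCC → mapping → extraction → FBA → scores
→ pairwise metrics → PCA/RF per dataset-algorithm cell, writes TSV report
tables plus a JSON summary keyed by a SHA-256 hash of the canonical
configuration, and logs one structured record per CGEM. Per-sample failures
are recorded and skipped, never fatal. All randomness (k-means, random
forest) derives from the single configured seed; text outputs use fixed
float formatting and sorted keys, so a rerun with the same configuration is
byte-identical.

## Known limitations

- The iMAT and INIT MILPs are exact only up to the solver's time limit
  (60 s per sample by default); a timeout returns the incumbent flagged
  non-optimal. At toy scale the limit is never reached.
- The Bland-Altman location test is blind to symmetric flux differences (see
  above); the Jaccard index and the flux fingerprinting carry that signal
  instead.
- FASTCORE's output is near-minimal, not minimal; the acceptance suite
  bounds the gap (≤ 2 reactions on 12-reaction networks) empirically, not
  analytically.
- Absolute score values (mean AFR, hallmark percentages, Jaccard means)
  depend on the toy network's stoichiometry and the generator's defaults;
  only their signs, orderings and calibration properties are designed
  outcomes.
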