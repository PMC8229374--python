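# cgemkit

Context-specific metabolic model extraction and flux-pattern heterogeneity
analysis for cancer genome-scale metabolic models (GEMs).

Cancer cells rewire metabolism — most famously toward aerobic glycolysis
(the Warburg effect) — and constraint-based modelling makes that rewiring
computable: integrating a sample's expression profile into a generic GEM
yields a cancer-specific model (CGEM) whose flux balance analysis (FBA)
state acts as a metabolic fingerprint. `cgemkit` is for computational
biologists who want to benchmark that whole chain with controlled, fully
reproducible inputs: which reactions survive extraction, what fluxes they
carry, and how distinguishable the resulting flux states are across samples,
platforms and extraction algorithms.

## What it computes

Given a model (SBML L3-FBC, or the package's JSON/TSV dialects) and
gene-by-sample expression tables, the pipeline:

1. reduces the model to its flux-consistent part (FASTCC: every kept
   reaction can carry `|v| >= eps` for some feasible `v` with `S v = 0`);
2. maps expression onto reactions through GPR rules (AND -> min for enzyme
   complexes, OR -> max for isozymes, missing data propagated);
3. extracts a CGEM per sample with **GIMME** (penalize flux through
   unexpressed reactions while holding biomass at a fraction of its
   optimum), **iMAT** (MILP maximizing agreement with a high/low expression
   classification), **INIT** (MILP maximizing summed expression evidence of
   active reactions), or **FASTCORE** (minimal flux-consistent superset of a
   confidently-expressed core) — six reserved reactions (`biomass_reaction`,
   `DM_atp_c_`, `GAPD`, `ATPS4mi`, `D_LACt2`, `O2t`) are never removed;
4. computes each CGEM's FBA flux state `v` (with a parsimonious tie-break so
   `v` is reproducible) and scores it:
   - AFR = v(GAPD) / v(ATPS4mi) — glycolytic vs oxidative ATP flux,
     positive in Warburg-like states;
   - EOR = v(D_LACt2) / v(O2t) — lactate transport vs oxygen transport,
     negative when lactate is secreted while oxygen is consumed;
   - hallmark activation — % of a cancer-hallmark gene list (among genes
     present in the parent model) still linked to kept reactions;
5. compares CGEMs pairwise: subsystem-averaged Jaccard index
   `J = |A ∩ B| / |A ∪ B|` of kept-reaction sets, and Bland–Altman
   agreement of flux vectors (limits of agreement `mean(d) ± 1.96·sd(d)`,
   one-sample test of `d` against 0);
6. clusters the sample-by-reaction flux matrix on its first two principal
   components (silhouette-selected k-means) and ranks
   cluster-discriminative reactions with a random forest (500 trees,
   `⌊√p⌋` features per split), aggregating top reactions into a per-subsystem
   "barcode".

A synthetic-data module supplies a desk-scale stand-in for a curated human
GEM: a 40-reaction Warburg-capable network (oxygen-limited, so its biomass
optimum provably secretes lactate while respiring) plus an expression
simulator with planted group structure, platform-specific missingness and
recorded ground truth.

## Worked example

```bash
cgemkit make-toy --out toy.json --hallmark hallmark.txt
cgemkit simulate --model toy.json --out-dir ds --groups 2 --samples 3 --seed 0
cgemkit score --model toy.json --expression ds/expression.tsv \
    --metadata ds/metadata.tsv --algorithm gimme \
    --hallmark hallmark.txt --out scores.tsv
```

`scores.tsv`:

```text
sample     algorithm  afr          eor           hallmark_percent  flags
group1_s1  gimme      1.824528304  -2.771698051  90.90909091
group1_s2  gimme      1.824528304  -2.771698051  81.81818182
group1_s3  gimme      1.824528304  -2.771698051  81.81818182
group2_s1  gimme      1.824528304  -2.771698051  81.81818182
group2_s2  gimme      1.824528304  -2.771698051  90.90909091
group2_s3  gimme      1.824528304  -2.771698051  90.90909091
```

Every CGEM shows the Warburg signature — AFR ≈ 1.82 > 0 (glycolytic ATP flux
exceeds oxidative) and EOR ≈ −2.77 < 0 (lactate secreted, oxygen consumed) —
and retains 82–91% of the hallmark genes; the variation in hallmark
retention tracks which planted nutrient modules each sample's CGEM kept.

```bash
cgemkit compare --model toy.json --expression ds/expression.tsv \
    --metadata ds/metadata.tsv --algorithm gimme --out-prefix cmp
# 0.0% of pairs disagree (p < 0.05)
cgemkit cluster --model toy.json --expression ds/expression.tsv \
    --metadata ds/metadata.tsv --algorithm gimme --out-prefix cl --seed 0
# 2 cluster(s), silhouette 1.000
```

Within-group CGEM pairs overlap at Jaccard ≈ 0.92, cross-group pairs at
0.77–0.85 (`cmp.jaccard.tsv`), and the flux fingerprints separate the two
planted groups perfectly. `cgemkit run-all --config config.json` executes
the full dataset × algorithm grid and writes deterministic report tables
(scores, pairwise metrics, clusters, feature importances, barcode).

The same workflow is available as a library (`cgemkit.extraction.extract`,
`cgemkit.pattern_metrics`, `cgemkit.clusterability`,
`cgemkit.pipeline.run_benchmark`, ...); see `docs/methods.md` for the models
and numerical choices.

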