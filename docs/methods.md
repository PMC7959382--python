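# Methods

## Phenotype: maximum hourly acidification rate

Microplate milk fermentations are followed by scanning the colour of a pH
indicator every 6 minutes (0.1 h). A degree-4 polynomial pH(hue) is fitted by
least squares to calibration pairs measured with an electrode over roughly
pH 6.5–4.0; the fit is checked numerically for monotonicity over the fitted
hue range and flagged (not rejected) when non-monotone, since dye responses
can wiggle at the edges of their useful range. Hues outside the fitted range
are converted by polynomial extrapolation with a warning.

V_max is the most negative slope of the pH curve over a sliding window of 10
consecutive measurements. Two readings of "slope over 1 hour" are possible
and both are implemented: the default is the ordinary least-squares slope of
the 10 window points (robust to single-point noise); the alternative
(`slope_method="endpoint"`) is the endpoint difference over the elapsed
time. Ten points at 6-minute spacing span 54 minutes; the window length in
points, not in time, is treated as the operational definition and is
configurable (`window_points`). A curve with no downward window returns 0.
Acidifying curves give negative V_max in pH·h⁻¹; the fastest plausible rates
in this system are around −0.96 h⁻¹ and the slowest around −0.05 h⁻¹.

## Genomic representations

Four representations of a strain's genome feed the regression:

1. **gene** — binary presence/absence of pangenome gene families, parsed
   from a Roary-style `gene_presence_absence` table. Any non-empty strain
   cell (including multi-locus paralog cells) scores 1.
2. **pfam** — copy numbers of Pfam domains from a pfam_scan-style hit
   table; the versioned accession (e.g. `PF02502.13`) is the feature id and
   the cell counts hits across all of the strain's genes.
3. **kmer8 / kmer9** — counts of canonical k-mers over all contigs.
   Assemblies are strand-agnostic, so a k-mer and its reverse complement are
   one feature, represented by the alphabetically first of the pair
   (for A<C<G<T this equals the numerically smaller base-4 code, which is
   how the counter canonicalizes). Windows containing non-ACGT characters
   are skipped and windows never span contig boundaries. The canonical
   spaces hold 32 896 (k=8) and 131 072 (k=9) distinct features.

Before modelling, each matrix is **pruned** — a feature is dropped iff the
fraction of strains where it is present (value > 0), or absent, strictly
exceeds 0.98 — and then **collapsed**: features with identical value
profiles across all strains merge into one column named by comma-joining the
member ids in original column order. "Present" for count-valued features
means count > 0, applying the same presence notion uniformly. Pruning
decisions depend only on value profiles, so prune∘collapse = collapse∘prune
on binary matrices; this package prunes first. Pangenome summaries classify
families by presence fraction p: core p ≥ 0.99, soft core 0.95 ≤ p < 0.99,
shell 0.15 ≤ p < 0.95, cloud p < 0.15 (exact boundaries go to the higher
category).

## Regression model

One row per (strain, condition) with an observed V_max; predictors are the
genomic features plus three condition features — Temperature as a single
numeric predictor (25/30/40), Volume (deepwell = 1) and Yeast (yeast
extract = 1). Genomic predictor columns are sorted by name before fitting so
predictions never depend on input column order.

Splitting is at the **strain** level: a uniform random partition with
|train| = ⌈0.75·n⌉, which yields 257/85 for n = 342 (the ceiling, not the
floor, reproduces that published partition). All of a strain's rows fall on
one side, ruling out genome leakage; this is asserted at evaluation time.

The regressor is scikit-learn's `RandomForestRegressor` with bootstrap
resampling and **all** features considered at every split
(`max_features=1.0`). Hyperparameters come from a randomized 3-fold
cross-validated search over the grid {n_estimators: 10, 50, …, 750} ×
{max_depth: None, 10, …, 150} × {min_samples_split: 2, 4, …, 16} ×
{min_samples_leaf: 1, …, 9} × {oob_score: True, False} — 36 864
combinations, of which `n_draws` (default 100) are sampled and scored by
mean held-out R² (the estimator's default score; the search metric is
otherwise a free choice). The per-representation optima found on the real
342-strain data are shipped as presets (gene: 450 trees, unlimited depth;
pfam: 650/70; kmer8: 650/110; kmer9: 550/120) so reproduction runs can skip
the search. Default seeds (split = 1, search = 1, forest = 1) are fixed and
overridable. Evaluation reports Pearson correlation (PC), explained
variance (EV) and RMSE (h⁻¹) between predicted and observed V_max on the
held-out rows.

## Permutation tests of genomic-signal reliance

A model could score well using the condition features alone. Two nulls
probe this, both operating at the strain level and then broadcasting to the
strain's condition rows, so a strain always carries one (possibly shuffled)
genome; target values and condition features are never touched:

* **feature permutation** — within each replicate every genomic feature
  column is permuted independently across test strains, destroying both
  genome–phenotype and feature–feature structure (all columns jointly per
  replicate, one histogram per model);
* **profile switch** — one random permutation reassigns whole genomic
  profiles among test strains, preserving within-genome correlations.

Each replicate records the test PC; the original PC is compared with the
empirical 2.5th/97.5th percentiles of the null (the "95% interval" is taken
as these empirical percentiles). 1000 replicates is the reference setting;
the pipeline default is 200, which resolves the 97.5th percentile to ±½
percentile-rank while keeping a full run in tens of seconds. No stochastic
ordering between the two nulls is asserted — none is implied by the design.

## Feature importance and consensus

Per-prediction attributions are exact Shapley values for tree ensembles
under tree-path-dependent expectations: a coalition's value is the tree
expectation obtained by following fixed features and splitting weight by
training cover otherwise, and the polynomial-time path algorithm computes
the exact Shapley average over all feature orderings. The kernel
(`_treeshap.py`) is written against scikit-learn's tree arrays, JIT-compiled
with numba, and verified in the test suite against brute-force coalition
enumeration on small trees; forest attributions are tree averages, so
`base value + Σ attributions = prediction` holds to 1e−6 on every explained
row (asserted). Attributions are computed on held-out test rows; the
pipeline caps the number of explained rows (default 300, deterministic
subsample) because the kernel's cost grows with leaves × depth² per row and
tree — the cap bounds a full run at minutes while leaving rankings stable.

Because V_max is negative, a **negative** attribution pushes the prediction
toward faster acidification. Importance tables carry an explicit
`direction` column ("faster"/"slower", from the sign of the value↔
attribution correlation) instead of a bare sign.

Features of different representations do not map one-to-one onto genes: a
domain occurs in several genes, a k-mer in several genes or none. k-mers
are resolved by exact substring search (both strands) across per-strain gene
sequences with per-gene strain counts; domains resolve through the hit
table with per-gene occurrence counts. Reporting thresholds of 40 strains
(k-mers) and 10 occurrences (domains) match the published tables and are
configurable. The consensus report expands collapsed columns, resolves
features to gene labels, and flags labels supported by ≥ 2 representations.

## Synthetic populations

The generator emulates the structure of a two-subspecies dairy collection
well enough to exercise every pipeline stage, with these reference
conditions (the defaults): 200 strains, 67% in clade A (mirroring the
230:112 subspecies ratio of the real collection); 30 core gene families
(present in every strain) and 100 accessory families drawn per strain with
clade-specific probabilities (0.8 in clade A, 0.2 in B), which makes the
clades separable by presence-profile clustering as in real data; two causal
blocks of co-occurring gene families (3 and 2 genes) with carrier
probabilities {A: 0.70, B: 0.35} and {A: 0.40, B: 0.60} and an effect of
0.15 h⁻¹ each; strain-level Gaussian noise of 0.03 h⁻¹; 5% of measurements
missing completely at random (the real missing-data mechanism is unknown;
MCAR is the neutral choice).

Phenotypes follow an additive model on a positive speed scale — baseline
0.35 h⁻¹ at 30 °C/lowwell/no yeast, plus causal-block effects, a per-clade
temperature shift (30 °C optimal for both clades; 40 °C mildly penalised in
clade A and strongly in clade B), +0.12 for yeast extract, +0.05 for
deepwell, and a small clade-A-only yeast×40 °C recovery term — clipped to
[0.05, 0.96] and negated, so emitted V_max lies within the observed real
range [−0.96, −0.05] h⁻¹.

Sequences are i.i.d. uniform nucleotides per gene family (one contig per
present gene, lengths 300–600 bp by default), shared across carriers with
0.5% per-base substitution per strain copy — enough divergence to create
realistic near-duplicate k-mer features. Each causal block plants a tag
9-mer once per member gene; tag regions are mutation-free and the tag (and
its reverse complement) is scrubbed from every other sequence, so the tag's
canonical k-mer column equals the block's carrier set exactly. Kinetic
curves are logistic pH declines from pH 6.5 to 4.3 over 12 h whose
steepness is solved by root-finding so the extracted V_max matches the
target (closed-loop accurate to ≪1%); hue variants go through the inverse
of the calibration polynomial by dense monotone interpolation.

For null-calibration experiments, `null_config()` zeroes the causal effects
**and** makes the condition responses clade-symmetric. Both are necessary:
with clade-specific temperature responses the accessory genome legitimately
predicts phenotype through clade, and a permutation null would rightly
reject even with no planted causal locus.

What the generator does **not** emulate: phylogenetic sequence evolution,
recombination, plasmids, assembly errors, annotation noise, and the
saturation of the k-mer space by megabase-scale genomes (synthetic genomes
are tens of kilobases, so core-gene k-mers mutate in and out of ubiquity
rather than being uniformly pruned). Passing tests therefore demonstrate
correctness of the pipeline's machinery and recoverability of planted
signal under realistic noise — not performance on real genomes.

## Problem sizes and numerical choices

The reference synthetic runs use 200 strains for the gene/Pfam models
(forest of 200 trees, min_samples_leaf 2) and 80 strains with shorter genes
for the k-mer models, whose matrices still hold ~15 000 features after
pruning; these sizes keep a full pipeline run and the acceptance script in
the minutes range on one CPU. Tie-breaks and degenerate inputs: a flat
curve returns V_max = 0; an empty hit table yields a zero-column matrix;
collapsing keeps first-seen column order; the logistic-curve solver rejects
targets steeper than the achievable window slope for the given pH drop and
duration. All randomness flows from named integer seeds, and identical
configurations reproduce outputs bit for bit (asserted for emitted files).

## Known limitations

* Printed reproduction scores for the real supplementary matrices depend on
  the (unpublished) split seed; agreement is expected only up to
  split-to-split variability.
* Shapley attributions dilute among correlated features (pervasive in
  pangenomes); the consensus report mitigates but does not remove this.
* The attribution kernel currently covers single-output regression trees.
* The randomized-search draw count and CV metric of the original analysis
  are unknown; the presets sidestep both for reproduction purposes.
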