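# Methods

This note records the models, parameter choices and numerical conventions
behind `magprof`, and what the synthetic validation does and does not
demonstrate about real data.

## Bin refinement

Depth is mean coverage, `total_mapped_reads × average_read_length /
total_bin_length`; GC is (G+C)/(A+C+G+T) with ambiguous bases excluded from
the denominator. Two same-sample bins are merge-compatible when

- `|d1 − d2| / mean(d1, d2) ≤ depth_tol` (default 0.10). The "±10% between
  each other" rule is operationalised as a relative gap to the pair mean:
  symmetric, so neither bin is a privileged reference;
- `|gc1 − gc2| ≤ gc_tol` (default 0.02);
- the species-rank lineage names are identical and non-empty.

Compatibility is closed transitively (single linkage over the compatibility
graph). Transitive closure is the only merge rule that is independent of the
order in which bins are visited, which we verify by permutation tests.
Merged bins pool contigs; depth, GC, completeness and contamination are
recombined length-weighted and the quality record is flagged `merged` —
a cheap surrogate for re-running a marker-gene quality estimator, which is
out of scope. Merge tolerances are evaluated on the raw per-bin depths, not
re-normalised ones.

`QS = completeness − 5 × contamination` exactly. MIMAG tiers: high
(completeness ≥ 90, contamination < 5), medium (≥ 70, < 5, QS ≥ 60), low
(≥ 50), else fail. The QS threshold for dereplication eligibility defaults
to ≥ 60 and is configurable. The size filter (> 200 kb by default) is
applied to raw bins *before* merging, mirroring the order of the original
workflow; the fixture generator rescales it to 8% of its genome length, the
same ratio 200 kb bears to a typical 2.5 Mb gut bacterial genome. Low-tier
bins stay in the catalogue and audit trail but never become species
representatives.

## ANI and dereplication

ANI is estimated from bottom-s MinHash sketches (defaults k = 21,
s = 5,000) over canonical k-mers (the smaller of k-mer and reverse
complement, 2-bit packed, hashed with splitmix64). The Jaccard index j is
computed Mash-style on the bottom-s of the union of two sketches, and
`ANI = 100·(1 + ln(2j/(1+j))/k)`, clamped to [0, 100]. For substitution-only
divergence d this estimates `100·(1 + ln((1−d)^k)/k) ≈ 100·(1 − d)` with a
bias below ~0.15 ANI points for d ≤ 0.05, and sampling noise ≈ 0.1 points
at s = 5,000 — an order of magnitude inside the ±1-point tolerance we test
against exact-alignment identity (edlib global alignment). Alignment-based
ANI engines (dRep's Mash+gANI two-stage pipeline) are deliberately not
reimplemented: at desk scale, with substitution-only synthetic truth, the
sketch estimator plus an exact-alignment oracle covers the same decision.

Clustering is greedy in descending (QS, size) order: each MAG joins the
first existing cluster whose *representative* exceeds the ANI threshold
(default 95%), else founds a cluster. This is deterministic, single-pass,
and guarantees the representative is the highest-QS member; ties in
representative selection break by larger genome size, then lexicographic id.
Cluster lineage is the representative's lineage; member disagreements at the
species rank are logged, not resolved.

## Abundance and function profiles

Species abundance is depth-normalised: per sample,
`abundance_i = depth_i / Σ_j depth_j` on the nonredundant catalogue, which
removes genome-length bias that raw read counts would carry. Taxon profiles
sum member-species relative abundances, so row mass is conserved exactly at
every rank. A feature counts as "present" iff abundance > 0; a configurable
detection floor exists and defaults to 0. Rarefaction draws, for each subset
size, 30 random sample subsets without replacement and reports the median
and quartiles of the union richness.

KO assignment keeps hits with e-value < 1e-10 and protein coverage > 50%,
then takes the minimal e-value (ties: higher coverage, then lexicographic
KO). Gene abundance is the carrying species' relative abundance times the
gene's copy number in the species representative — the simplest model
consistent with summing gene abundances into category abundances when genes
are single-copy; per-gene read mapping is not modelled. Categories may
overlap (KEGG pathways share KOs) and deliberately double-count shared KOs;
category matrices are therefore not renormalised and are tagged
non-relative. Species contributions divide a species' in-category gene
abundance by the category total; unrestricted contributions sum to 1
wherever the category is present, and restricting the report to a species
subset makes columns sum below 1 by construction.

## Community statistics

Bray-Curtis `d = Σ|x−y| / Σ(x+y)`; PCoA is the classical eigendecomposition
of the double-centred Gower matrix, axes ordered by eigenvalue, negative
eigenvalues reported and excluded from the %variance denominator unless
requested otherwise. PERMANOVA uses the one-factor adonis formulation on
squared distances; the p-value is `(1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`
under uniform seeded label permutation, with all permutation statistics
computed vectorised (einsum over permutation one-hots), which makes
500-simulation calibration runs cheap. Mantel correlates off-diagonal upper
triangles with row/column permutations of one matrix (two-sided by
default).

Differential features use the two-sided Wilcoxon rank-sum test: exact
enumeration when both groups have ≤ 25 samples and the feature has no ties,
else the normal approximation with continuity and tie correction. Constant
features get p = 1 and a flag. Fold changes are log2 ratios of group means
with a pseudocount of half the smallest positive matrix value (zeros are
otherwise unloggable). Benjamini-Hochberg q-values are computed directly
(sort, scale by m/rank, running minimum, cap at 1) so that the arithmetic
agrees term-for-term with the textbook step-up definition; statsmodels
serves as an independent oracle in the tests. Species-level calls default to
raw p < 0.05 and functional categories to q < 0.05, both configurable.
Direction labels name the enriched *group*; under a case/control swap the
fold-change signs flip while p-values and the named enriched group are
invariant. The upstream literature variously reports fdrtool-based and BH
FDR values; plain BH is what this package computes.

## Classifier

The random forest grows `n_trees` (default 1,000) CART trees with
`sqrt(p)` feature subsampling on *class-stratified* bootstraps: each class
is resampled to its own size, so every tree sees the cohort's class balance.
With plain bootstraps, per-tree class imbalance leaks into the out-of-bag
votes and biases the null OOB AUC to ≈ 0.42 on 20+20 cohorts; stratification
(the `strata`/`sampsize` idiom of R's randomForest) restores ≈ 0.46–0.50 in
our simulations. A sample's score is the fraction of case votes (hard
per-tree majority votes) among trees where it was out of bag; OOB scoring is
used because it needs no separate split at cohort sizes of tens of samples.
AUC is the trapezoidal ROC area, identical to the normalised Mann-Whitney U
with half credit for ties; the 95% CI uses DeLong's structural-component
variance, matching pROC's default (cross-checked against Rscript/pROC in
the tests). Feature importance is mean decrease in impurity averaged over
trees, reported with an enrichment direction from group means (top 30 by
default).

## Synthetic communities: what they emulate, and what they do not

Genomes are i.i.d. base sequences with a GC target; derived genomes apply
i.i.d. substitutions at a set rate, so expected ANI is analytically
`100·(1−d)` — no indels, rearrangements or horizontal transfer, which is
exactly what keeps the dereplication ground truth exact. Bins tile a genome
into contigs (≥ 2 kb, capped at length/60) and retain a random subset
hitting a completeness target within ±2 points; contamination adds contig
windows cut from *other* community genomes, mirroring cross-binning.
Mapped-read counts are multinomial with probability ∝ abundance × genome
length; per-sample abundance is
`log2(base) + effect·[group = PE] + Normal(0, σ)` with σ = 1 log2 unit by
default — on the low side of real between-subject gut variation, chosen as
a single realistic operating point. Gene tables plant a configurable
fraction (default 10%) of hits just outside the best-hit filter so the
filter is always exercised, plus strictly worse decoy hits.

Because abundances are compositional, a planted fold change on a dominant
species is attenuated by renormalisation; planted-effect recovery statements
hold for minor community members (the validation suite uses 1-of-40
communities, attenuation ≈ 0.07 log2).

The reference cohort design (40 PE vs 37 HC, 400 species, ~40 planted
effects of 1–2 log2 units, log-normal baseline) reproduces the *scale* of a
published preeclampsia cohort, not its difficulty: with 10% of features
carrying 2–4-fold effects the classes are nearly separable and the OOB AUC
saturates near 1.0, whereas real cohorts with subtler, correlated effects
sit far lower. Passing these checks therefore demonstrates correctness of
the chain (bookkeeping, calibration, recovery of known truth), not expected
performance on clinical data. FASTQ-level read simulation with error models,
multi-mapping reads and CLR/ILR compositional transforms are out of scope.

## Problem sizes and numerical conventions

Validation runs use: 1,750-row quality survey; 30 genomes × 100 kb from 8
ancestors over 5 seeds; 50 ANI pairs × 10 kb; 40-species × 40-sample
abundance recovery at 1e5 reads/sample; 500 PERMANOVA null simulations ×
1,000 permutations (n = 20+20, 50 features); 1,000 BH vectors (length
≤ 20); 300 power simulations (+1.5 log2 planted effect, q < 0.05); 100
null-classifier simulations and 20 cohort-scale replicates at 1,000 trees.
Rounding of tier percentages follows one-decimal reporting. All generators
and permutation tests consume `numpy.random.default_rng` seeds derived from
a single run seed; reruns are byte-identical. Degenerate inputs fail loudly:
empty sequences, all-zero samples, mixed-sample merges, single-class labels
and non-symmetric distance matrices raise with the offending ids named.
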