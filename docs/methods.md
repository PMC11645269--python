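# Methods

This note documents the statistical procedures implemented in `dissocsig`,
the choices made where the design was genuinely open, and what the bundled
simulator does and does not establish about real data.

## Synthetic data generator

`simulate_dataset` draws a gene × cell UMI matrix from a gamma–Poisson
(negative-binomial) model:

    counts[g, c] ~ NB(mean = mu_g · ell_c · 2^(e_g · a_c),  Var = mu + alpha_g · mu²)

- **Base means** `mu_g` are lognormal (default meanlog 0, sdlog 1.5),
  giving a realistic several-decade spread of expression; with the default
  3,000 genes this yields cell totals of a few thousand UMIs.
- **Library factors** `ell_c` are lognormal per cell (default sdlog 0.35),
  making per-cell normalisation non-trivial without claiming to model any
  particular instrument.
- **Dispersion** `alpha` defaults to 0.3 (scalar or per gene); `alpha = 0`
  degrades to Poisson.
- **Structure**: a configurable set of groups (default the four protocol
  groups ENZ-NONE, ENZ-INHIB, DNC-NONE, DNC-INHIB), replicates per group
  (default 4) and cells per replicate (default 1,000); three cell classes of
  unequal abundance (myeloid 0.25, astrocyte 0.35, neuron 0.40) allocated by
  largest remainder so per-sample composition is exact and identical.
- **Activation program**: `program_size` genes (default 25, named after
  IEG/heat-shock/chemokine genes so simulated signatures read naturally)
  with per-gene log2 effects `e_g` (default 1.5) applied multiplicatively to
  the NB mean in activated cells. Activated cells are the first
  `floor(fraction · n)` cells of each (group, class) stratum after a seeded
  shuffle, so realised fractions are exact up to rounding; the default
  condition activates 85% of ENZ-NONE myeloid cells and nothing else.
  Program genes draw moderately high base means (lognormal meanlog 1.0,
  sdlog 0.5), reflecting that stress-response genes are well detected once
  induced.
- **Mitochondrial genes**: 2% of genes carry the `mt-`/`MT-` prefix with a
  3× mean scale, so QC filtering has signal to act on.

All randomness flows from one `numpy` Generator seeded by the config, so a
config + seed pair fully determines the dataset; the returned ground truth
records activated barcodes, program genes/effects, base means and class
labels.

**What the simulator does not model**: doublets, ambient RNA, batch effects
beyond group structure, gene–gene correlation, and — deliberately — any
baseline expression difference between cell classes (classes differ only in
abundance and activation eligibility). Passing tests therefore demonstrate
that the procedures recover known signals under the stated noise model, not
that they are robust to every artefact of real droplet data. In particular,
class-identity signatures cannot be studied on simulated data; the scoring
machinery treats them identically to activation signatures.

## Preprocessing

QC keeps a cell iff genes detected ≥ `min_genes_per_cell`,
`min_umis` ≤ total UMIs ≤ `max_umis`, and mitochondrial fraction ≤
`max_mito_fraction`. Thresholds are dataset-specific and must be supplied —
there are no hidden defaults. Mitochondrial genes are recognised by
case-insensitive prefix (default `mt-`/`MT-`), configurable for other
species conventions. Filtering is idempotent and never touches the gene set.

Normalisation is the standard CP10K log transform
`ln(1 + scale · count / cell_total)` (scale 10,000), chosen because module
scores downstream assume that convention's magnitude. Sparse zeros are
preserved exactly; raw counts are immutable.

The subclustering-eligibility rule admits a cell class only with strictly
more than 80 cells in **every** replicate and strictly more than 300 cells
overall (both bounds configurable, both strict).

## Pseudobulk NB-Wald differential expression

Counts are summed per replicate (optionally within a class filter);
normalisation uses median-of-ratios size factors over genes expressed in
all samples, rescaled to geometric mean 1. For each gene nonzero in at
least one sample of each group:

- group means `m_A`, `m_B` of normalised counts;
- fold change `log2((m_B + eps) / (m_A + eps))` with
  `eps = 0.5 × (smallest positive normalised value)`, bounding statistics on
  sparse pseudobulk without dropping genes;
- dispersion by residual method of moments,
  `alpha = max(1e-8, [n/(n-2)] · (Σ_g [n_g/(n_g-1)] SS_g − Σ m) / Σ m²)`,
  where `SS_g` is the within-group residual sum of squares. The per-group
  df factor removes the downward bias of the plug-in estimator; the overall
  `n/(n-2)` factor compensates for the noise of a dispersion estimated from
  6–8 samples entering a normal-theory Wald statistic. With both factors the
  test's empirical type-I error at α = 0.05 is ≈ 0.054 in the null
  simulation shipped in the test suite (4 vs 4 samples, NB(50, 0.05)); with
  neither it reaches ≈ 0.09.
- delta-method standard error
  `se² = (1/ln²2) [ (1/n_A)(1/m_A + alpha) + (1/n_B)(1/m_B + alpha) ]`,
  two-sided normal p, Benjamini–Hochberg adjustment across tested genes.

This is a deliberately simple test: no shrinkage of dispersions or fold
changes, no covariates, no independent filtering. Its calibration and power
are established by simulation rather than by equivalence to any external
tool, and it should be read as "the pseudobulk design with honest
replication", not as a drop-in for a full bulk-RNA-seq package.

Significance gates default to padj ≤ 0.05 and |log2FC| ≥ 0.58 (1.5-fold),
inclusive at the boundary. The consensus signature is the intersection of
the significant-up sets of every supplied comparison, ordered by mean log2
fold change; intersection makes the signature robust to any single
comparison's false positives and can only shrink as comparisons are added.

## Module scoring

Genes are ranked by mean log-normalised expression over the current
(post-QC) cells and cut into `n_bins` equal-size bins (default 25, stable
ties). For each signature gene, `ctrl_per_gene` control genes (default 100)
are drawn from its bin, seeded, without replacement, with all signature
genes excluded from every pool; a pool smaller than `ctrl_per_gene` falls
back to sampling with replacement and warns. The score is
`mean(signature expression) − mean(pooled control expression)` per cell,
with duplicates in the pooled draws counted. Control draws iterate over
signature genes in canonical (matrix) order, so the score is invariant to
the order in which a signature is written. With the default 3,000-gene
simulated universe, bins hold ~120 genes and the without-replacement regime
is preserved.

Defaults (25 bins, 100 controls) follow the established binned-control
convention; both are exposed in configs because the appropriate values
scale with the universe size.

Cross-species transfer without an ortholog table is a case heuristic
(mouse→human upper-case, human→mouse title-case) intersected with the
target universe, with dropped symbols reported. This resolves the large
majority of one-to-one mouse/human symbol pairs but no others; a mapping
table is the supported escape hatch for curated orthologs.

## Enrichment calibration

Per dataset: (1) the gene universe is the matrix's gene set, or the
intersection across several matrices when thresholds must be comparable
between datasets; (2) cell classes are downsampled (seeded, without
replacement) to the minimum class size so composition cannot influence
outlier detection; (3) `n_lists` (default 1,000) random gene lists of the
signature's length are scored, and each list's outlier threshold is
`median + 3 × MAD` of its scores pooled across all cells and classes. The
MAD is unscaled — no 1.4826 consistency constant — matching the literal
definition of a median absolute deviation; the constant is exposed as
`mad_scale` for sensitivity analyses.

The cutoff is an **order statistic**: the `(n − floor(tail·n))`-th smallest
threshold, so exactly `floor(tail·n)` thresholds lie strictly above it when
values are distinct (tail defaults to 0.025, i.e. "top 2.5%"). An
interpolated percentile would be an equally defensible reading; the order
statistic was chosen because it is unambiguous and reproduces "top k of n"
counting exactly. "Enriched" is strict inequality (`score > cutoff`), so
boundary cells are not enriched and counts are exactly reproducible.

One seed stream (deterministically split) governs downsampling, list
sampling and control-gene draws; the calibration result records the seed
and a fingerprint of the gene universe. Empirically the cutoff is
conservative on null data: fresh random lists exceed it at ≈ the nominal
tail rate, and per-sample enrichment fractions of an unspiked signature
stay near zero (median ≤ 0.02 across seeds in the test suite).

Calibration runs per dataset. Whether several datasets should instead be
pooled before thresholding is a design question the data cannot settle;
per-dataset thresholds are the default and pooling is available by
concatenating matrices over the intersected universe.

## Abundance and cell-level DE

Cluster proportions per sample are compared between groups on the
arcsine-square-root scale with a Welch (unequal-variance) two-sample
*t*-test per cluster and BH correction across the clusters of one
comparison; multi-group designs are handled as the requested pairwise
comparisons, each corrected separately. Welch-on-arcsin√ is a conservative,
fully specifiable substitute for moderated compositional models; batch
covariates are out of scope. A cluster with zero variance in both groups is
reported at p = 1 when the means agree (and p = 0 otherwise) rather than
NaN.

The cell-level test is the two-sided Wilcoxon rank-sum: exact enumeration
when `n_A + n_B ≤ 10` and the gene has no tied values, otherwise a normal
approximation with tie correction and continuity correction. Fold change is
`log2((mean(expm1 x_A) + 1) / (mean(expm1 x_B) + 1))` on the normalised
scale, and adjustment is Bonferroni (`min(1, p·G)`) over all genes in the
matrix.

## Pipeline and reproducibility

The `run` driver executes stages in a fixed dependency order, hands data
between stages through plain files (Matrix Market triplets, TSV, JSON) so
every intermediate is inspectable, and derives one seed per stage from the
global seed. Rerunning an identical config reproduces every result file
byte for byte; stage metadata (parameters, seed, input hashes, package
version) differs only in its timestamp. Config validation rejects unknown
keys, missing required parameters, out-of-range tail masses, and missing
input paths before any computation starts.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at sizes chosen to exercise the
asymptotics the procedures rely on while staying desk-scale: the
calibration-coverage check uses 6 samples × 1,500 cells (3,000 genes) with
1,000 null and 2,000 fresh 38-gene lists; parameter recovery uses
2 groups × 4 samples × 2,000 cells with a 25-gene program at log2FC 1.5 in
30% of one class; signature recovery uses 4 groups × 4 samples × 600 cells
at activation 0.8 over 10 seeds; type-I simulations use 200–500 replicates.

## Known limitations

- The NB-Wald test's calibration is established for the simulated regimes
  (moderate dispersion, ≥ 2 — realistically ≥ 3 — replicates per group);
  with very low counts or extreme dispersion the normal approximation will
  degrade before a shrinkage-based tool would.
- The ortholog heuristic is symbol-case only; paralog families and
  non-orthologous symbol collisions must be handled via a mapping table.
- The simulator's classes share a baseline expression profile, so
  class-identity scores and class-specific normalisation effects are not
  exercised.
- Factor loadings are consumed as given (two-column TSV); the factorisation
  that produces them is out of scope.
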