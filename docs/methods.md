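# Methods

This note documents the models implemented in `murideconv`, the
parameter choices that matter, what the simulator does and does not
emulate, and the numerical decisions a maintainer should know about.

## The deconvolution problem

A bulk RNA-seq profile is modeled as a mixture of cell-type-specific
expression profiles. Writing `b` for the mixture over the genes shared
with a signature matrix `S` (genes × cell types) and `f` for the
per-type proportions, the regression engines assume `b ≈ S f` in linear
expression space. The scoring engines make a weaker assumption: that a
cell type's marker genes rise and fall with its abundance, without any
mixing model. This split carries through the whole API as the
`fraction` / `score` distinction: fractions live on the simplex and are
comparable within and between samples; scores are per-cell-type,
arbitrary-scale quantities comparable between samples only, and are
never rescaled into pseudo-fractions.

## Engines

### Constrained least squares (fractions, unknown content)

Per sample, solve

    min_f ‖W^{1/2}(S f − b)‖²   s.t.  f ≥ 0  and  Σf = 1  (or Σf ≤ 1)

with optional non-negative per-gene weights `W`. With the inequality
constraint, the slack `1 − Σf` is reported as the `uncharacterized`
fraction — cell content present in the mixture but absent from the
signature.

Scale handling: *both* the mixture and every signature column are
re-normalized to sum 10⁶ (TPM scale) over the shared genes before
solving. Re-normalizing only the mixture would make the simplex
constraint meaningless whenever a signature column's total differs from
10⁶ — the exact self-mixture `b = S_t` must return `f_t = 1`, which
only holds when both sides share the same scale. Consequently the
recovered fractions are proportions of *mRNA on the shared-gene set*;
with per-type mRNA scaling factors supplied, `mrna_renormalize=True`
divides by them and rescales the known part (leaving the
uncharacterized slack untouched), yielding cell-count proportions.

The solver is SLSQP on the smooth quadratic objective with analytic
gradient, inputs pre-scaled to O(1), `ftol = 1e-16`; tiny negative
round-off is clipped and the equality case renormalized. Exactness is
verified two ways in the tests: noiseless mixtures are recovered to
1e-6 per fraction (measured ≈ 2e-8), and solutions agree with an
exhaustive 0.01-step simplex grid search within 0.02 on noisy
instances. A singular signature (duplicate columns) is warned about but
solved — the constrained problem remains well posed even when the
unconstrained normal equations do not.

Unknown-content estimates are *lower bounds* in practice: the slack is
only detected insofar as the missing profile cannot be mimicked by a
combination of the known columns. In the simulated benchmark, a type
mixed in at ~10% (mRNA) but removed from the signature is reported at
~3%, because all simulated types share the same background expression
and the solver absorbs most of the missing type's signal into the known
columns. Profiles orthogonal to the signature span are recovered
exactly (tested).

### ν-SVR (fractions)

Per sample, the mixture and each signature column are z-scored over the
shared genes, and a linear ν-SVR (regularization fixed at `C = 1`, as
in common reference implementations) is fitted for each ν in
{0.25, 0.5, 0.75}; the ν minimizing the RMSE between fitted and
observed mixture wins. Negative coefficients are clipped to zero and
the rest normalized to sum 1. An all-zero coefficient vector falls back
to uniform fractions with a warning.

### Elastic net (scores)

Per sample, elastic-net regression (`l1_ratio = 0.05`, regularization
path selected by 3-fold internal cross-validation over 30 alphas) of
the z-scored mixture on z-scored signature columns, repeated 10 times
on random subsets of 50% of the shared genes (seeded; default seed 0)
and averaged. Coefficients are deliberately left signed and
unnormalized: they are relative-abundance scores, not fractions. The
repeat count, subset fraction and mixing parameter are package
defaults, stated here because no canonical values exist for this engine
family; all are exposed as options.

### Median marker scoring (scores)

`score(t, s)` = median over the present markers of `log2(TPM+1)`
(default) or raw TPM. The median makes the score robust to a single
aberrant marker; absent markers are ignored (logged), a type with no
present marker yields an all-missing row, and only when *every* type is
uncovered does the engine refuse to run. Whether the median should be
taken on log or linear scale is genuinely ambiguous in the field; both
modes are exposed, log is the default as the variance-stabilized
choice.

### Signed rank scoring (scores)

Per sample, genes are ranked ascending with mid-ranks for ties and
normalized to (0, 1] by division by the gene count G;
`score = mean_rank(up) − mean_rank(down)`, or `mean_rank(up) − 0.5` for
up-only sets. The exact null mean of an up-only set is `(G+1)/(2G)`, so
subtracting 0.5 leaves a bias of `1/(2G)` — about 5·10⁻⁴ at G = 1000 —
accepted for the simpler contract; the up/down form is exactly
centered. The statistic is invariant under any strictly monotone
per-sample transform and insensitive to library size by construction.

**Known limitation.** The mean normalized rank is a bounded, strongly
concave function of the underlying abundance: once a type's markers
clear the bulk of the background distribution, further abundance gains
move them only within the top of the ranking. On the simulated
benchmark with broad Dirichlet(1) compositions, per-type Spearman ρ is
≈ 0.96 but per-type Pearson r falls to 0.53–0.72 — the score is an
excellent monotone estimator whose linear correlation with the truth is
degraded by curvature, not by noise. Rank scores should be compared
with rank-based statistics, or used on cohorts whose composition range
is narrow.

## Ortholog mapping

Conversion to human gene space uses explicit (source, target) symbol
tables. Policies: many mouse genes → one human gene are combined by
`sum` (default; conserves total signal), `mean` or `max`; one mouse
gene → many human genes is resolved by `first` (alphabetically smallest
target, default — avoids double counting), `duplicate` or `drop`.
Conversion is defined in linear space only; log-scale input is
rejected, since summing log values is meaningless. The bundled table
(565 curated immune/stromal-relevant pairs, mostly the standard case
convention plus known non-trivial pairs such as `H2-Ab1 → HLA-DQB1`) is
adequate for tests and demos; production analyses should supply a full
ortholog download. Below 60% mapped genes a warning is logged; zero
mapped genes is a hard error (wrong species or wrong table). The
`case_convention_fallback` (uppercasing) is available when no table is
at hand and is correct for most one-to-one protein-coding orthologs.

## Bundled resources and cell-type ontology

The three bundled resources (14-cell-type marker roster, 10-cell-type
signature, 190-phenotype fine-grained roster) are curated by the
package authors from standard immunology markers. They reproduce the
cardinalities and structure of the well-known murine resources, not
their exact gene lists — they are structural stand-ins, adequate for
exercising every code path and for teaching, and replaceable by user
resources everywhere.

The ontology layer separates *harmonization* (per-method raw label →
controlled vocabulary; collisions within one method are an error) from
*grouping* (fine phenotype → one of 19 major immune cell types).
Fractions group by SUM (mass is additive; column sums are conserved to
1e-12), scores by MEAN (summing would inflate types with many
sub-phenotypes); both defaults are overridable. Labels outside the
hierarchy pool into `unassigned` with a warning — the bundled major
roster is immune-only, so e.g. endothelial estimates surface there
rather than disappearing.

## Simulator

`simulate_sc_reference` draws per-cell gene counts from a negative
binomial with variance `μ + μ²/φ` (dispersion φ; `φ = inf` is the
Poisson limit). Each of T cell types owns a disjoint block of M marker
genes at `marker_fold ×` the genome-wide `base_mean`; per-cell library
factors are LogNormal(0, σ). Defaults — 5 types, 2000 genes, 40
markers/type, fold 6, φ = 2, σ = 0.3, 100 cells/type — define the
package's reference benchmark conditions: marker fold and dispersion in
the range reported for sorted immune populations, library-size spread
typical of droplet data.

`simulate_pseudobulk` mixes cells into bulk samples: per-sample type
counts are multinomial at the requested proportions (default: symmetric
Dirichlet(1) per sample), cells are drawn **with replacement** so
requested fractions need not respect the per-type inventory, and their
count vectors are summed, optionally scaled by per-type mRNA-content
factors. Ground truth is returned in two flavors: realized cell-count
fractions, and mRNA-weighted fractions (counts × mRNA bias × per-type
mean library size, renormalized). Regression engines on un-normalized
signatures estimate mRNA proportions, so the mRNA flavor is the default
benchmark target; the distinction matters whenever cell types differ in
mRNA content.

What the simulator does **not** emulate: doublets, ambient RNA, batch
effects, gene–gene correlation beyond the type structure, gene-length
effects (so counts ≈ TPM up to scale), or realistic marker overlap
between related cell types. Passing the benchmark therefore shows that
the engines are implemented correctly and behave as designed under
their own model assumptions — not that they reach the same accuracy on
real tissue.

## Evaluation protocol

Per cell type, across samples: Pearson r between estimated and true
values, plus RMSE for fraction-type estimates only (scores are on an
arbitrary scale, so an RMSE against fractions would be meaningless
while the correlation is not). Correlations are withheld (flagged
absent) below 3 paired samples or at zero variance on either side; NA
estimate/truth pairs are dropped pairwise and counted. Labels are
aligned by harmonization first, then by fine-to-major grouping when no
direct overlap exists. Benchmark sizes in the tests and acceptance
script (20 samples × 500 cells; 25 solver instances; 1000 null draws)
were chosen as the smallest sets at which the measured quantities are
stable across seeds.

## Determinism

Every stochastic component (simulator, elastic-net subsets, ν-SVR has
none) takes an explicit integer seed, defaults included, and uses its
own `numpy` Generator; identical configuration + seed reproduces
results byte-identically, which the test suite asserts on written TSVs.
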