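# Methods

This note documents the models behind deconvkit, the parameters that matter,
what the synthetic data does and does not emulate, and the numerical choices
made where the design was genuinely open.

## The deconvolution model

A bulk expression profile `b` (one sample, genes × 1) is modeled as a
non-negative combination of cell-type signature columns,

    b ≈ S f,   f ≥ 0,

where `S` (genes × types) holds the mean CPM expression of each cell type
over a selected marker gene set and `f` are the cell fractions. Both the
signature and the bulk columns are placed on the CPM scale (each column
scaled to 10⁶) before solving, and estimates are normalized to sum to one per
sample — the sum-to-100% constraint shared by signature-based deconvolution
methods. Because the solver core is literally a constrained linear model fit,
it is exposed in the statsmodels idiom: `DeconvolutionModel(signature,
bulk).fit(method=...)` returns a `DeconvolutionResults` object carrying the
fraction estimates, per-sample convergence diagnostics, residuals and a
`summary()` table. The simulator and the benchmark experiments are procedural
(they are protocols, not fitted models) and are plain functions.

### NNLS baseline

Each sample is solved independently with non-negative least squares
(`scipy.optimize.nnls`). This is the simplest member of the signature-based
family and serves as the reference point for every stress experiment.

### Dampened weighted least squares (DWLS)

Plain least squares is dominated by highly expressed genes; markers of rare
cell types contribute almost nothing to the residual and their signal is
drowned out. DWLS counters this with iteratively re-weighted NNLS:

1. initialize `f⁰` from NNLS (normalized to sum one);
2. per-gene weights `w_g = 1 / max((S fᵏ)_g, ε)²` with `ε = 1e-8`
   (the floor avoids division by zero for types estimated at zero);
3. *dampening*: raw weights span many orders of magnitude and would let
   near-zero genes dominate, so they are capped at `min(w) · 2ʲ`. The
   exponent `j ∈ {1, …, 30}` is chosen once per sample by 5-fold
   cross-validation over genes: for each `j`, weighted NNLS is fitted on the
   training folds and the held-out weighted squared residual is accumulated;
   the minimizing `j` is kept. Folds come from a seeded RNG (default seed 0),
   so results are deterministic;
4. solve weighted NNLS (`nnls(√w·S, √w·b)`), normalize, and iterate until
   `‖fᵏ⁺¹ − fᵏ‖∞ < 1e-6` or 100 iterations. Non-convergence is recorded as a
   flag in the results provenance, never raised, so benchmark sweeps do not
   abort on a hard sample.

When all capped weights are equal the weighted problem coincides with plain
NNLS; when the data satisfy `b = S f*` exactly, `f*` is a fixed point of the
iteration. Both properties are exercised in the tests, as is the design goal:
on mixtures with a 2% rare type under 10% multiplicative noise, DWLS attains
strictly lower rare-type RMSE than NNLS.

## The synthetic single-cell reference

### Count model

Counts are gamma-Poisson (negative binomial): for a cell of type *t*, gene
*g* has mean `lib_c · profile_t[g]`, where `profile_t` sums to the type's
mean library size, `lib_c` is a per-cell lognormal factor
(σ = 0.45, mean 1 — the typical log-spread of droplet library sizes), and
the NB shape parameter is 2 (moderate overdispersion; the underlying studies
do not characterize their references' dispersions, so this is a convention,
not an estimate).

### mRNA content control

The benchmark's mRNA-content proxy is the number of expressed (nonzero)
genes per cell, so the generator must hit a per-type `expressed_gene_target`
*and* a per-type `mean_library_size` independently. A single multiplicative
scale on gene means cannot do that — it moves both quantities together.
Instead each type expresses a *support*: its own markers first, then
background genes in descending abundance. Given a candidate support size the
expected nonzero count per cell has a closed form from the NB zero
probability, `E[#nonzero] = Σ_g (1 − (θ/(θ+μ_g))^θ)`, and is monotone in the
support size, so the support size is solved by bisection after renormalizing
the support means to the library size. Realized per-type means land within
10% of target on the stock fixtures; an unreachable target (library too
small to express that many genes) raises a configuration error instead of
silently missing.

### Marker structure

Each type owns a disjoint block of marker genes whose baseline relative
abundance is floored at the distribution median and then multiplied by
`marker_fold` (default 16). The floor guarantees that every marker ranks in
the top decile of its own type's mean expression — without it, a marker
planted on a lognormal-tail gene can stay mid-distribution even after a
16-fold boost. Other types carry foreign markers at `marker_background`
(default 0.02) of baseline, which keeps the planted markers strongly
differential while leaving a shared background for realistic spillover.
Donor labels are assigned round-robin; mitochondrial fractions are drawn
Beta(2, 40) per cell (a typical healthy range) so the QC filter has
realistic input.

### What the generator does not emulate

No doublets, no ambient RNA, no batch effects beyond the donor label, no
UMI-versus-read distinction, and no gene-length structure (hence no TPM:
counts and CPM are the only emitted scales). Marker blocks are cleanly
disjoint, which real references never are; spillover and similarity
experiments therefore construct *deliberately* overlapping types (few, weak
markers) rather than relying on incidental overlap. Consequently, passing
the experiments here demonstrates that the machinery isolates each confounder
correctly — not that any method will reach the same scores on real tissue.

## Preprocessing

**QC.** A cell is an outlier if a metric deviates from the metric's median by
more than k unscaled MADs (`MAD = median |x − median x|`). Following the
standard single-cell QC recipe, total counts and expressed-gene numbers are
tested on the log1p scale, two-sided, with k = 5; the mitochondrial fraction
on its raw scale, upper-sided, with k = 3. The log scale matters: raw-scale
MADs on a mixture of cell types flag entire high-mRNA-content types as
"outliers", which is a composition effect, not a quality problem.

**Subsampling.** Three rules, all guarding types below `min_guard = 20`
cells from any reduction: `fraction_per_type` keeps `⌈f·n_t⌉` cells per type
(ceiling, so no small type is silently emptied); `total_proportional`
apportions a target total by the largest-remainder rule (ties broken by
descending fractional part, then label order); `cap_per_type` truncates each
type at a maximum. Sampling is without replacement and seed-deterministic.

## Pseudo-bulk simulation

Per sample, per-type cell counts come from deterministic largest-remainder
rounding of the target fractions times `n_cells`; cells are then drawn
uniformly with replacement within each type. Each drawn cell contributes its
*library-normalized* count vector multiplied by its mRNA scaling factor, and
the aggregate is rescaled so total counts equal the configured depth
(default 10⁷; scenario defaults are 10,000 cells, 1,000 for pure samples).
The library normalization makes the scaling factor the *only* mRNA-content
knob: with factors disabled every cell carries equal mRNA mass and the
expression shares equal the cell-count fractions, which is what makes the
bias-free regime essentially solvable and the bias experiments
interpretable. A pure sample of one cell at the cell's own library depth
reproduces that cell's count vector exactly.

Scaling factors in `expressed_genes` mode are each cell's nonzero-gene count
divided by the reference mean (mean one, so bias shifts relative, not
absolute, contributions); mode `none` sets all factors to one. Ground truth
is always recorded as cell-count fractions — under bias, expression shares
deviate from it by design, and that asymmetry is the quantity under study.

Sample *i* of a run uses RNG seed `seed + i` for both its composition draw
and its cell draw, and the cell draw does not consume randomness from the
factor computation; two runs differing only in `bias_mode` therefore pair
exactly (identical ground truths, bit-identical expression when all factors
are one). Random compositions use a flat Dirichlet; the `weighted_spike`
scenario fixes the spike type's fraction exactly and splits the remainder by
flat Dirichlet over the other sampled types.

## Signature building and scores

Markers are selected per type by a one-vs-rest Wilcoxon rank-sum test on CPM
values (ranks computed once per gene and reused across contrasts; normal
approximation with tie correction and continuity correction), BH-adjusted
p < 0.05 and positive log2 fold-change (1-count pseudo), ranked by
fold-change and capped at 200 genes per type; the union is returned in gene
order. The rank-based test replaces heavier hurdle-model machinery; at desk
scale it is adequate for marker gating and is the deliberate design choice
here.

Scores: entropy specificity is `1 − H(p)/log₂C` per gene (p the gene's
across-type profile, H in bits, 0·log 0 ≡ 0), so 1 marks a one-hot marker
and 0 uniform expression. The Gini index uses the sorted identity
`Σᵢ(2i−n−1)x₍ᵢ₎ / (n² x̄)`, algebraically equal to the pairwise double sum.
κ is the singular-value ratio σ_max/σ_min, the rectangular generalization of
‖M‖‖M⁻¹‖; exact collinearity reports ∞ with a diagnostic naming the
collinear columns. One subtlety: adding a *single* one-hot gene can slightly
worsen κ if it lands on an already-strong type (rank-one updates only
guarantee σ_min does not decrease); adding one one-hot gene *per type* at
equal magnitude shifts every squared singular value equally and provably
never increases κ, and that is the invariant the tests assert.

## Evaluation

RMSE is computed per sample (across types) and per type (across samples);
MAE per type; MAPE per type excludes zero-truth entries and reports how many
were excluded (no pseudo-counts — the exclusion count makes the omission
visible). Pearson correlation is pooled over all sample×type pairs (global)
or taken per type; constant vectors — e.g. a type estimated as exactly zero
everywhere — yield an explicit undefined flag rather than a propagated NaN.

The experiments fix the protocol sizes used throughout: unknown content runs
9 spike levels (0–90%) × 5 replicates × 10 samples = 450 pseudo-bulks with a
signature trained on the known types only, capped at 500 cells per type, and
reports both the unnormalized-truth comparison (primary — the inflation of
known-type estimates *is* the effect) and a renormalized secondary variant.
The mRNA-bias compendium pairs bias/no-bias arms of 50 random-composition
samples over 8 references (800 samples). Spillover simulates 50 pure
replicates of 1,000 cells per type and reports the mean estimated percentage
matrix (rows compositional by construction). Granularity simulates at fine
resolution, deconvolves independently at fine/normal/coarse, and compares
direct coarse estimates with fine estimates aggregated through the label
hierarchy. Leave-one-out rebuilds the signature without each type in turn
and reports the per-type RMSE change against the full-reference run.

## Problem sizes and determinism

The stock fixture is 2,500 cells × 2,000 genes with six blood-like types
under a two-branch hierarchy and a 2× expressed-gene spread between
monocytes and T cells; experiment defaults in the test-suite and acceptance
script use this fixture (the compendium uses eight 300-cell references).
These sizes keep every protocol's statistical structure intact — the
conclusions of each experiment are about directions, conservation laws and
orderings, which stabilize well below atlas scale. All randomness flows
through explicit integer seeds; identical seeds give bit-identical
references, simulations and solver outputs.

## Known limitations

* The generator's types are conditionally independent given the shared
  background profile; there is no continuous differentiation structure, so
  "similar types" must be constructed explicitly.
* TPM input is undefined without gene lengths and deliberately unsupported;
  bulk matrices are CPM-normalized internally before solving.
* The DWLS dampening-constant selection is a contract of this package
  (cross-validated power-of-two capping); other implementations of the same
  family may select differently, and agreement is expected only up to the
  documented invariants.
* MAPE is reported but unstable whenever true fractions are near zero; use
  the per-type RMSE/MAE for rare types.
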