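# deconvkit

A self-contained toolkit for **benchmarking single-cell-informed bulk RNA-seq
deconvolution**. Deconvolution methods model the expression profile of a bulk
tissue sample as a weighted sum of cell-type-specific profiles,
`b ≈ S f`, and estimate the unknown cell fractions `f ≥ 0` from a signature
matrix `S` learned from annotated single-cell RNA-seq data. Whether those
estimates can be trusted depends on confounders that are hard to isolate with
real data: cell-type-specific mRNA content, transcriptionally similar cell
types ("spillover"), cell types missing from the training reference, and the
granularity of the cell-type annotation.

deconvkit makes these questions testable on a laptop, with no downloads:

* a **synthetic reference generator** — annotated gamma-Poisson single-cell
  count matrices with planted marker genes, a coarse→normal→fine label
  hierarchy, donor labels, and controlled per-type mRNA content (proxied by
  the number of expressed genes per cell);
* **preprocessing** — MAD-based QC outlier filtering, CPM normalization, and
  three reference subsampling rules (per-type fraction, proportional total,
  per-type cap, all guarding rare types);
* a **pseudo-bulk simulator** — cells drawn with replacement under five
  composition scenarios (`mirror_fractions`, `mirror_db`, `random`, `pure`,
  `weighted_spike`), fixed sequencing depth, and optional mRNA-content bias
  via per-cell scaling factors proportional to expressed-gene counts; paired
  seeds guarantee that bias and no-bias arms draw identical cells;
* **signature building and QC** — one-vs-rest Wilcoxon rank-sum marker
  selection (BH-adjusted p < 0.05, positive log2 fold-change), mean-CPM
  profiles, and the standard signature scores: per-gene entropy specificity,
  per-gene Gini index, and the condition number κ = σ_max/σ_min;
* **reference solvers** — per-sample non-negative least squares and dampened
  weighted least squares (iteratively re-weighted NNLS with cross-validated
  weight capping), exposed as `DeconvolutionModel.fit() →
  DeconvolutionResults`;
* **evaluation** — sample-wise and type-wise RMSE, MAE, MAPE, global and
  per-type Pearson correlation (with explicit undefined flags for constant
  vectors), and the benchmark experiments: paired mRNA-bias ΔRMSE, spillover
  on pure pseudo-bulks, unknown-content spiking, annotation-granularity
  comparison with fine→coarse aggregation, and leave-one-cell-type-out.

## Worked example

```python
import deconvkit as dk

ref = dk.example_reference(seed=1)          # 2,500 cells, 6 blood cell types
sig = dk.make_signature(ref)                # rank-sum markers + mean-CPM profile
print(f"signature: {sig.n_genes} genes x {len(sig.cell_types)} types, "
      f"kappa = {dk.condition_number(sig):.2f}")

config = dk.SimulationConfig(scenario="random", n_samples=20, n_replicates=1,
                             n_cells=10_000, depth=1e7, seed=7)
ds = dk.simulate_dataset(ref, config)       # 20 pseudo-bulks, known fractions

model = dk.DeconvolutionModel(sig, ds.expression)
res = model.fit(method="dwls")
report = dk.evaluate_fractions(ds.ground_truth, res.fractions.values)
print(f"global r = {report.global_pearson:.4f}, "
      f"mean per-sample RMSE = {report.mean_rmse_s:.4f}")
```

prints

```
signature: 866 genes x 6 types, kappa = 2.63
global r = 1.0000, mean per-sample RMSE = 0.0009
```

The near-perfect recovery is expected: deconvolving bias-free pseudo-bulks
with a signature from the *same* reference is the easiest possible setting,
and it is the baseline against which the stress experiments are read. Turning
on mRNA bias breaks it in a predictable direction — the high-mRNA-content
type is overestimated because its cells contribute more reads than their
cell-count share:

```python
with_bias, without = dk.paired_bias_datasets(ref, n_samples=20,
                                             n_cells=5000, seed=11)
rep_b = dk.evaluate_fractions(with_bias.ground_truth,
                              dk.nnls_deconvolve(sig, with_bias.expression).values,
                              provenance={"seed": 11})
rep_n = dk.evaluate_fractions(without.ground_truth,
                              dk.nnls_deconvolve(sig, without.expression).values,
                              provenance={"seed": 11})
print(dk.delta_rmse_bias(rep_b, rep_n).round(3).to_dict())
```

```
{'B cells': 0.019, 'Monocytes': 0.084, 'NK cells': 0.012,
 'T CD4': 0.029, 'T CD8': 0.035, 'Tregs': 0.032}
```

A positive ΔRMSE (= RMSE with bias − RMSE without) means the solver does not
correct the mRNA bias for that type; monocytes, generated with twice the
expressed-gene content of T cells, degrade the most.

## Command line

Every step is also available from a shell; all stochastic commands require
`--seed` and write a provenance JSON:

```bash
deconvkit fixtures generate --config spec.yaml --seed 1 --out ref/
deconvkit prep qc --reference ref/ --out ref_qc/
deconvkit simulate --reference ref_qc/ --scenario random --seed 3 --out sim/
deconvkit signature build --reference ref_qc/ --out sig.csv
deconvkit deconv run --solver dwls --signature sig.csv \
    --bulk sim/expression.csv --out fractions.csv
deconvkit evaluate metrics --fractions fractions.csv \
    --truth sim/ground_truth.csv --out report.json
```

References travel as Matrix Market counts plus TSV annotations; expression,
signatures and fractions as labeled CSV (genes × samples, samples × types).

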