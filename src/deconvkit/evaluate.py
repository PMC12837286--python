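"""Performance metrics and the benchmark experiments.

Metrics compare a ground-truth fraction table against estimates aligned by
sample and cell-type label: global Pearson correlation (pooled over all
sample x type pairs), per-type Pearson over samples, per-sample RMSE over
types, per-type RMSE / MAE / MAPE over samples. Correlations on constant
vectors (e.g. a type estimated as all zeros) are reported as undefined via an
explicit flag instead of propagating NaN silently.

Experiments
-----------
* paired mRNA-bias runs and their per-type RMSE difference (positive means
  the solver does not correct the bias for that type);
* spillover: deconvolve pure single-type pseudo-bulks and measure how much
  mass lands on the wrong types;
* unknown content: spike an untrained type at increasing levels and track
  the inflation of the known-type estimates;
* annotation granularity: deconvolve at fine/normal/coarse resolution and
  compare direct coarse estimates with aggregated fine ones;
* leave-one-cell-type-out: remove one type from the training reference and
  measure the per-type RMSE change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .deconv import (
    AggregationMap,
    FractionMatrix,
    aggregate_fractions,
    dwls_deconvolve,
    nnls_deconvolve,
)
from .errors import ConfigurationError, DomainError
from .preprocess import subsample_reference
from .reference import SingleCellReference
from .signature import make_signature
from .simulate import PseudoBulkDataset, SimulationConfig, simulate_dataset

__all__ = [
    "EvaluationReport",
    "SpilloverReport",
    "evaluate_fractions",
    "pearson_r",
    "rmse_per_sample",
    "rmse_per_type",
    "mae_per_type",
    "mape_per_type",
    "delta_rmse_bias",
    "paired_bias_datasets",
    "mrna_bias_compendium",
    "spillover_experiment",
    "unknown_content_experiment",
    "granularity_experiment",
    "leave_one_out_experiment",
    "get_solver",
]

UNKNOWN_CONTENT_LEVELS = (0.0, 0.05, 0.10, 0.20, 0.30, 0.50, 0.70, 0.80, 0.90)


# ---------------------------------------------------------------------------
# alignment and elementary metrics


def _as_frame(x) -> pd.DataFrame:
    return x.values if isinstance(x, FractionMatrix) else pd.DataFrame(x)


def _align(truth, est) -> tuple[pd.DataFrame, pd.DataFrame]:
    t, e = _as_frame(truth), _as_frame(est)
    sym_types = set(t.columns) ^ set(e.columns)
    sym_samples = set(t.index) ^ set(e.index)
    if sym_types or sym_samples:
        raise ConfigurationError(
            f"label mismatch between truth and estimate; "
            f"types difference: {sorted(sym_types)}, samples difference: {sorted(sym_samples)}"
        )
    e = e.loc[t.index, t.columns]
    return t.astype(float), e.astype(float)


def _pearson(x: np.ndarray, y: np.ndarray) -> tuple[float, bool]:
    """(r, defined) with an undefined flag for constant inputs."""
    if x.size < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), False
    r = np.corrcoef(x, y)[0, 1]
    return float(r), True


def pearson_r(truth, est, scope: str = "global"):
    """Pearson correlation, pooled (``global``) or per cell type (``per_type``).

    Global scope returns ``(r, defined)``. Per-type scope returns a Series of
    r values (NaN where undefined) whose ``.attrs['undefined']`` lists the
    cell types with constant truth or estimate vectors.
    """
    t, e = _align(truth, est)
    if scope == "global":
        return _pearson(t.to_numpy().ravel(), e.to_numpy().ravel())
    if scope != "per_type":
        raise ConfigurationError(f"unknown scope {scope!r}")
    values, undefined = {}, []
    for c in t.columns:
        r, ok = _pearson(t[c].to_numpy(), e[c].to_numpy())
        values[c] = r
        if not ok:
            undefined.append(c)
    out = pd.Series(values, name="pearson_r")
    out.attrs["undefined"] = undefined
    return out


def rmse_per_sample(truth_row, est_row) -> float:
    """Root-mean-square error over cell types for one sample."""
    x, y = np.asarray(truth_row, float), np.asarray(est_row, float)
    if x.shape != y.shape or x.size == 0:
        raise DomainError(f"length mismatch or empty vectors: {x.shape} vs {y.shape}")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def rmse_per_type(truth_col, est_col) -> float:
    """Root-mean-square error over samples for one cell type."""
    return rmse_per_sample(truth_col, est_col)


def mae_per_type(truth_col, est_col) -> float:
    """Mean absolute error over samples for one cell type."""
    x, y = np.asarray(truth_col, float), np.asarray(est_col, float)
    if x.shape != y.shape or x.size == 0:
        raise DomainError(f"length mismatch or empty vectors: {x.shape} vs {y.shape}")
    return float(np.mean(np.abs(x - y)))


def mape_per_type(truth_col, est_col) -> tuple[float, int]:
    """Mean absolute percentage error over samples with nonzero truth.

    Returns ``(mape, n_excluded)`` where ``n_excluded`` counts the zero-truth
    entries left out of the mean; all-zero truth yields ``(nan, n)``.
    """
    x, y = np.asarray(truth_col, float), np.asarray(est_col, float)
    if x.shape != y.shape or x.size == 0:
        raise DomainError(f"length mismatch or empty vectors: {x.shape} vs {y.shape}")
    nonzero = x > 0
    n_excluded = int((~nonzero).sum())
    if not nonzero.any():
        return float("nan"), n_excluded
    return float(np.mean(np.abs((x[nonzero] - y[nonzero]) / x[nonzero]))), n_excluded


# ---------------------------------------------------------------------------
# report


@dataclass
class EvaluationReport:
    """Global and per-cell-type agreement between truth and estimates."""

    global_pearson: float
    global_pearson_defined: bool
    per_type_pearson: pd.Series
    undefined_types: list[str]
    rmse_s: pd.Series
    rmse_c: pd.Series
    mae_c: pd.Series
    mape_c: pd.Series
    mape_excluded: pd.Series
    n_samples: int
    n_types: int
    provenance: dict = field(default_factory=dict)

    @property
    def mean_rmse_s(self) -> float:
        return float(self.rmse_s.mean())

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: cell_type, metric, value, flag."""
        rows = [("__all__", "global_pearson", self.global_pearson,
                 "" if self.global_pearson_defined else "undefined")]
        for c in self.per_type_pearson.index:
            flag = "undefined" if c in self.undefined_types else ""
            rows.append((c, "pearson", self.per_type_pearson[c], flag))
            rows.append((c, "rmse", self.rmse_c[c], ""))
            rows.append((c, "mae", self.mae_c[c], ""))
            rows.append((c, "mape", self.mape_c[c],
                         f"excluded={int(self.mape_excluded[c])}"))
        return pd.DataFrame(rows, columns=["cell_type", "metric", "value", "flag"])


def evaluate_fractions(truth, est, provenance: dict | None = None) -> EvaluationReport:
    """Full metric report for aligned truth/estimate fraction tables."""
    t, e = _align(truth, est)
    g, g_ok = pearson_r(t, e, "global")
    per_type = pearson_r(t, e, "per_type")
    rmse_s = pd.Series(
        {s: rmse_per_sample(t.loc[s], e.loc[s]) for s in t.index}, name="rmse_s"
    )
    rmse_c = pd.Series({c: rmse_per_type(t[c], e[c]) for c in t.columns}, name="rmse_c")
    mae_c = pd.Series({c: mae_per_type(t[c], e[c]) for c in t.columns}, name="mae_c")
    mape_vals, mape_excl = {}, {}
    for c in t.columns:
        mape_vals[c], mape_excl[c] = mape_per_type(t[c], e[c])
    return EvaluationReport(
        global_pearson=g,
        global_pearson_defined=g_ok,
        per_type_pearson=per_type,
        undefined_types=per_type.attrs["undefined"],
        rmse_s=rmse_s,
        rmse_c=rmse_c,
        mae_c=mae_c,
        mape_c=pd.Series(mape_vals, name="mape_c"),
        mape_excluded=pd.Series(mape_excl, name="mape_excluded"),
        n_samples=t.shape[0],
        n_types=t.shape[1],
        provenance=provenance or {},
    )


# ---------------------------------------------------------------------------
# solvers as pluggable callables


def get_solver(solver):
    """Resolve 'nnls' / 'dwls' / callable into a (signature, bulk) -> FractionMatrix."""
    if callable(solver):
        return solver
    if solver == "nnls":
        return nnls_deconvolve
    if solver == "dwls":
        return dwls_deconvolve
    raise ConfigurationError(f"unknown solver {solver!r}; use 'nnls', 'dwls' or a callable")


# ---------------------------------------------------------------------------
# mRNA-bias experiment


def paired_bias_datasets(
    reference: SingleCellReference,
    n_samples: int = 50,
    n_cells: int = 10_000,
    depth: float = 1e7,
    seed: int = 0,
    scenario: str = "random",
    level: str = "fine",
) -> tuple[PseudoBulkDataset, PseudoBulkDataset]:
    """(with-bias, without-bias) datasets drawn from identical cells.

    Both arms use the same per-sample seeds; only the mRNA-content scaling
    differs, so their ground truths are element-wise equal.
    """
    common = dict(
        scenario=scenario, n_cells=n_cells, depth=depth, seed=seed,
        n_samples=n_samples, n_replicates=1, level=level,
    )
    with_bias = simulate_dataset(reference, SimulationConfig(bias_mode="expressed_genes", **common))
    without = simulate_dataset(reference, SimulationConfig(bias_mode="none", **common))
    return with_bias, without


def delta_rmse_bias(
    report_with_bias: EvaluationReport, report_without: EvaluationReport
) -> pd.Series:
    """Per-type RMSE(with bias) - RMSE(without bias) from paired-seed runs.

    Positive values mean the solver does not correct the mRNA bias for that
    type. Raises if the reports carry provenance from different seeds.
    """
    sa = report_with_bias.provenance.get("seed")
    sb = report_without.provenance.get("seed")
    if sa is not None and sb is not None and sa != sb:
        raise ConfigurationError(f"unpaired reports: seeds {sa} vs {sb}")
    a, b = report_with_bias.rmse_c, report_without.rmse_c
    if set(a.index) != set(b.index):
        raise ConfigurationError(
            f"type sets differ: {sorted(set(a.index) ^ set(b.index))}"
        )
    out = a - b.loc[a.index]
    out.name = "delta_rmse"
    return out


def mrna_bias_compendium(
    references: list[SingleCellReference],
    solver="nnls",
    n_samples: int = 50,
    n_cells: int = 10_000,
    depth: float = 1e7,
    seed: int = 0,
    signature_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Paired bias/no-bias protocol over several references.

    For each reference, simulates ``n_samples`` random-composition samples in
    both arms (identical cell draws), deconvolves each arm with a signature
    built from the same reference, and records per-type Delta-RMSE. Returns a
    tidy frame with one row per (reference, cell type) plus the total sample
    count in ``.attrs['n_samples_total']``.
    """
    solve = get_solver(solver)
    rows = []
    total = 0
    for r, ref in enumerate(references):
        with_bias, without = paired_bias_datasets(
            ref, n_samples=n_samples, n_cells=n_cells, depth=depth, seed=seed + 1000 * r
        )
        total += with_bias.n_samples + without.n_samples
        sig = make_signature(ref, **(signature_kwargs or {}))
        rep_b = evaluate_fractions(
            with_bias.ground_truth, solve(sig, with_bias.expression).values,
            provenance={"seed": seed + 1000 * r},
        )
        rep_n = evaluate_fractions(
            without.ground_truth, solve(sig, without.expression).values,
            provenance={"seed": seed + 1000 * r},
        )
        delta = delta_rmse_bias(rep_b, rep_n)
        for t, d in delta.items():
            rows.append((f"ref{r + 1}", t, d, rep_b.rmse_c[t], rep_n.rmse_c[t]))
    out = pd.DataFrame(
        rows, columns=["reference", "cell_type", "delta_rmse", "rmse_bias", "rmse_nobias"]
    )
    out.attrs["n_samples_total"] = total
    return out


# ---------------------------------------------------------------------------
# spillover


@dataclass
class SpilloverReport:
    """Mean predicted fractions (%) for pure pseudo-bulks of every type."""

    matrix: pd.DataFrame  # simulated type x predicted type, percentages
    correct: pd.Series  # % on the true type
    total_spillover: float  # mean over types of (100 - correct)

    def spill(self, simulated_type: str) -> pd.Series:
        row = self.matrix.loc[simulated_type].drop(simulated_type)
        return row.sort_values(ascending=False)


def spillover_experiment(
    reference_sim: SingleCellReference,
    reference_train: SingleCellReference | None = None,
    solver="nnls",
    n_reps: int = 50,
    n_cells: int = 1000,
    seed: int = 0,
    level: str = "fine",
    signature_kwargs: dict | None = None,
) -> SpilloverReport:
    """Pure-type pseudo-bulk deconvolution, the spillover stress test.

    For each cell type, ``n_reps`` pure pseudo-bulks of ``n_cells`` cells are
    simulated from ``reference_sim`` and deconvolved with a signature built
    from ``reference_train`` (defaults to the simulation reference). The
    report row of a type gives the mean estimated percentage on every type;
    the diagonal is the correct-assignment percentage, ideally 100.
    """
    reference_train = reference_train or reference_sim
    sim_types = reference_sim.cell_types(level)
    train_types = reference_train.cell_types(level)
    missing = sorted(set(sim_types) - set(train_types))
    if missing:
        raise ConfigurationError(f"simulated types missing from training reference: {missing}")
    solve = get_solver(solver)
    sig = make_signature(reference_train, level=level, **(signature_kwargs or {}))
    rows = {}
    for t in sim_types:
        config = SimulationConfig(
            scenario="pure", pure_type=t, n_replicates=n_reps, n_cells=n_cells,
            seed=seed, level=level, bias_mode="none",
        )
        ds = simulate_dataset(reference_sim, config)
        est = solve(sig, ds.expression).values
        rows[t] = est.mean(axis=0) * 100.0
    matrix = pd.DataFrame(rows).T
    matrix = matrix.loc[sim_types, sorted(matrix.columns)]
    correct = pd.Series(
        {t: matrix.loc[t, t] if t in matrix.columns else 0.0 for t in sim_types},
        name="correct_pct",
    )
    total = float((100.0 - correct).mean())
    return SpilloverReport(matrix=matrix, correct=correct, total_spillover=total)


# ---------------------------------------------------------------------------
# unknown content


def unknown_content_experiment(
    reference: SingleCellReference,
    solver="nnls",
    known_types: list[str] | None = None,
    spike_type: str | None = None,
    levels=UNKNOWN_CONTENT_LEVELS,
    n_replicates: int = 5,
    n_samples: int = 10,
    n_cells: int = 10_000,
    depth: float = 1e7,
    seed: int = 0,
    level: str = "fine",
    train_cap: int = 500,
    signature_kwargs: dict | None = None,
) -> dict:
    """Spike an untrained type at increasing levels; evaluate known types.

    The training signature is built only from ``known_types``, downsampled to
    ``train_cap`` cells per type. Ground truth for the known types sums to
    ``1 - level`` (unnormalized; the primary comparison — estimate inflation
    *is* the effect under study), with a renormalized secondary report.
    Returns ``{"per_level": {level: {"raw": report, "renormalized": report,
    "estimates": FractionMatrix, "truth": DataFrame}},
    "n_samples_total": int}``.
    """
    if spike_type is None or known_types is None:
        raise ConfigurationError("known_types and spike_type are required")
    if spike_type in known_types:
        raise ConfigurationError(f"spike_type {spike_type!r} must not be a known type")
    bad = [lv for lv in levels if not (0 <= lv < 1)]
    if bad:
        raise ConfigurationError(f"levels must be in [0, 1): {bad}")
    solve = get_solver(solver)

    train = reference.drop_cell_types(
        set(reference.cell_types(level)) - set(known_types), level=level
    )
    train = subsample_reference(train, "cap_per_type", train_cap, seed=seed, level=level)
    sig = make_signature(train, level=level, **(signature_kwargs or {}))

    per_level = {}
    total = 0
    for li, lv in enumerate(levels):
        config = SimulationConfig(
            scenario="weighted_spike", spike_type=spike_type, spike_level=lv,
            cell_types=list(known_types) + [spike_type],
            n_samples=n_samples, n_replicates=n_replicates,
            n_cells=n_cells, depth=depth, seed=seed + 10_000 * li, level=level,
            bias_mode="none",
        )
        ds = simulate_dataset(reference, config)
        total += ds.n_samples
        fractions = solve(sig, ds.expression)
        truth_known = ds.ground_truth[list(known_types)]
        est = fractions.values[truth_known.columns]
        raw_report = evaluate_fractions(truth_known, est)
        if lv < 1 and truth_known.to_numpy().sum() > 0:
            renorm = truth_known.div(truth_known.sum(axis=1), axis=0)
            renorm_report = evaluate_fractions(renorm, est)
        else:  # pragma: no cover - guarded by level < 1 precondition
            renorm_report = raw_report
        per_level[lv] = {
            "raw": raw_report,
            "renormalized": renorm_report,
            "estimates": fractions,
            "truth": truth_known,
        }
    return {"per_level": per_level, "n_samples_total": total}


# ---------------------------------------------------------------------------
# annotation granularity


def granularity_experiment(
    reference: SingleCellReference,
    solver="nnls",
    n_replicates: int = 5,
    n_samples: int = 10,
    n_cells: int = 10_000,
    depth: float = 1e7,
    seed: int = 0,
    train_cap: int = 500,
    signature_kwargs: dict | None = None,
) -> dict:
    """Deconvolve mirror-composition pseudo-bulks at every annotation level.

    Pseudo-bulks are simulated at *fine* resolution; signatures are built and
    deconvolution run independently at fine, normal and coarse resolution
    (training capped at ``train_cap`` cells per fine type). Additionally the
    fine estimates are aggregated to coarse and compared against the direct
    coarse run — the aggregation strategy. Returns
    ``{"reports": {level: report}, "aggregated_coarse": report, "datasets": ...}``.
    """
    for col in ("fine", "normal", "coarse"):
        if col not in reference.obs.columns:
            raise ConfigurationError(f"missing annotation level column {col!r}")
    solve = get_solver(solver)
    config = SimulationConfig(
        scenario="mirror_db", n_samples=n_samples, n_replicates=n_replicates,
        n_cells=n_cells, depth=depth, seed=seed, level="fine", bias_mode="none",
    )
    ds = simulate_dataset(reference, config)
    train = subsample_reference(reference, "cap_per_type", train_cap, seed=seed, level="fine")

    reports, estimates = {}, {}
    for lvl in ("fine", "normal", "coarse"):
        sig = make_signature(train, level=lvl, **(signature_kwargs or {}))
        est = solve(sig, ds.expression)
        mapping = AggregationMap(reference.hierarchy_map("fine", lvl))
        truth_lvl = aggregate_fractions(
            FractionMatrix(ds.ground_truth), mapping
        ).values
        estimates[lvl] = est
        reports[lvl] = evaluate_fractions(truth_lvl, est.values)

    coarse_map = AggregationMap(reference.hierarchy_map("fine", "coarse"))
    agg = aggregate_fractions(estimates["fine"], coarse_map)
    truth_coarse = aggregate_fractions(FractionMatrix(ds.ground_truth), coarse_map).values
    aggregated_report = evaluate_fractions(truth_coarse, agg.values)
    return {
        "reports": reports,
        "aggregated_coarse": aggregated_report,
        "dataset": ds,
        "estimates": estimates,
    }


# ---------------------------------------------------------------------------
# leave-one-cell-type-out


def leave_one_out_experiment(
    reference: SingleCellReference,
    solver,
    bulk: PseudoBulkDataset,
    seed: int = 0,
    level: str = "fine",
    signature_kwargs: dict | None = None,
) -> pd.DataFrame:
    """Per-removed-type Delta-RMSE matrix for an incomplete training reference.

    Row *r*, column *t*: RMSE of type *t* when the signature is rebuilt
    without type *r*, minus the RMSE with the full reference. The removed
    type's truth mass is necessarily redistributed over the remaining types.
    """
    types = reference.cell_types(level)
    if len(types) < 3:
        raise ConfigurationError("leave-one-out needs at least 3 cell types")
    extra = sorted(set(bulk.ground_truth.columns) - set(types))
    if extra:
        raise ConfigurationError(f"bulk truth types missing from reference: {extra}")
    solve = get_solver(solver)
    kwargs = signature_kwargs or {}

    sig_full = make_signature(reference, level=level, **kwargs)
    est_full = solve(sig_full, bulk.expression).values
    truth = bulk.ground_truth
    full_rmse = {
        t: rmse_per_type(truth[t], est_full[t]) for t in truth.columns
    }

    rows = {}
    for removed in types:
        ref_r = reference.drop_cell_types([removed], level=level)
        sig_r = make_signature(ref_r, level=level, **kwargs)
        est_r = solve(sig_r, bulk.expression).values
        deltas = {}
        for t in truth.columns:
            if t == removed:
                continue
            deltas[t] = rmse_per_type(truth[t], est_r[t]) - full_rmse[t]
        rows[removed] = deltas
    out = pd.DataFrame(rows).T
    out.index.name = "removed_type"
    return out
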