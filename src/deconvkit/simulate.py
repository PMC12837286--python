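"""Scenario-driven pseudo-bulk simulation with optional mRNA-content bias.

A pseudo-bulk sample is the weighted sum of single-cell count vectors drawn
with replacement from an annotated reference, rescaled to a fixed sequencing
depth. Cell-type composition is controlled by a *scenario*:

``mirror_fractions``  user-supplied target fraction rows
``mirror_db``         every sample mirrors the reference's own proportions
``random``            per-sample fractions from a flat Dirichlet
``pure``              all mass on a single type (spillover protocol)
``weighted_spike``    one type fixed at a spike level, rest flat Dirichlet
                      (unknown-content protocol)

mRNA-content bias is modeled by per-cell scaling factors proportional to the
number of expressed genes per cell, normalized to mean one. Crucially the
ground truth is always recorded as *cell-count* fractions while the
expression aggregates *mRNA mass*: with bias enabled the two differ, which is
exactly the discrepancy that deconvolution methods must correct for. Paired
bias / no-bias datasets built with the same seed draw identical cells — the
scaling factor is applied after the draw — so any downstream difference is
attributable to the bias alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DomainError
from .reference import SingleCellReference
from .util import largest_remainder

__all__ = [
    "ScalingFactors",
    "SimulationConfig",
    "PseudoBulkDataset",
    "compute_scaling_factors",
    "draw_cell_counts",
    "simulate_sample",
    "simulate_dataset",
]

SCENARIOS = ("mirror_fractions", "mirror_db", "random", "pure", "weighted_spike")
BIAS_MODES = ("expressed_genes", "none")


@dataclass
class ScalingFactors:
    """Per-cell mRNA-content scaling factors, normalized to mean one."""

    per_cell: np.ndarray
    mode: str

    def __post_init__(self) -> None:
        self.per_cell = np.asarray(self.per_cell, dtype=float)
        if self.mode not in BIAS_MODES:
            raise ConfigurationError(f"unknown scaling mode {self.mode!r}")
        if (self.per_cell <= 0).any():
            raise DomainError("scaling factors must be positive")


def compute_scaling_factors(reference: SingleCellReference, mode: str = "expressed_genes") -> ScalingFactors:
    """Scaling factor of cell c = (its expressed-gene count) / (mean over cells).

    ``mode='none'`` disables the bias: all factors are one.
    """
    if mode not in BIAS_MODES:
        raise ConfigurationError(f"unknown bias mode {mode!r}; choose from {BIAS_MODES}")
    if mode == "none":
        return ScalingFactors(np.ones(reference.n_cells), "none")
    genes = reference.genes_per_cell().astype(float)
    if (genes == 0).any():
        bad = [reference.cell_ids[i] for i in np.flatnonzero(genes == 0)[:5]]
        raise DomainError(f"cells with zero expressed genes: {bad}")
    return ScalingFactors(genes / genes.mean(), "expressed_genes")


def draw_cell_counts(fractions, n_cells: int, seed: int = 0) -> np.ndarray:
    """Per-type integer cell counts summing exactly to ``n_cells``.

    Deterministic largest-remainder rounding of ``fractions * n_cells``; the
    seed argument is accepted for interface uniformity but unused (rounding
    is deterministic by design so paired runs agree exactly).
    """
    f = np.asarray(fractions, dtype=float)
    if (f < 0).any():
        raise DomainError("fractions must be non-negative")
    if n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if abs(f.sum() - 1.0) > 1e-6:
        raise DomainError(f"fractions must sum to 1, got {f.sum():.6g}")
    return largest_remainder(f, n_cells)


@dataclass
class SimulationConfig:
    """Settings for one pseudo-bulk simulation run.

    ``n_samples * n_replicates`` samples are generated for the composition
    scenarios (``n_replicates`` only for ``pure``; rows x ``n_replicates``
    for ``mirror_fractions``). Sample *i* uses RNG seed ``seed + i`` so that
    bias and no-bias arms pair exactly.
    """

    scenario: str = "random"
    n_cells: int = 10_000
    depth: float = 10_000_000.0
    bias_mode: str = "none"
    seed: int = 0
    n_samples: int = 10
    n_replicates: int = 5
    level: str = "fine"
    cell_types: list[str] | None = None  # restrict the sampled type universe
    target_fractions: pd.DataFrame | None = None  # mirror_fractions rows
    pure_type: str | None = None
    spike_type: str | None = None
    spike_level: float = 0.0

    def __post_init__(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}; choose from {SCENARIOS}")
        if self.bias_mode not in BIAS_MODES:
            raise ConfigurationError(f"unknown bias mode {self.bias_mode!r}")
        if self.n_cells < 1 or self.depth <= 0:
            raise ConfigurationError("n_cells and depth must be positive")
        if self.scenario == "pure" and self.pure_type is None:
            raise ConfigurationError("pure scenario requires pure_type")
        if self.scenario == "weighted_spike":
            if self.spike_type is None:
                raise ConfigurationError("weighted_spike requires spike_type")
            if not (0 <= self.spike_level < 1):
                raise ConfigurationError(
                    f"spike_level must be in [0, 1), got {self.spike_level}"
                )
        if self.scenario == "mirror_fractions" and self.target_fractions is None:
            raise ConfigurationError("mirror_fractions requires target_fractions")

    def provenance(self) -> dict:
        d = asdict(self)
        if isinstance(d.get("target_fractions"), pd.DataFrame):  # pragma: no cover
            d["target_fractions"] = "user-supplied"
        if self.target_fractions is not None:
            d["target_fractions"] = "user-supplied"
        return d


@dataclass
class PseudoBulkDataset:
    """Simulated genes x samples expression plus ground-truth fractions.

    ``expression`` columns each sum to the configured depth; ``ground_truth``
    rows (samples x types, cell-count fractions) each sum to one.
    """

    expression: pd.DataFrame
    ground_truth: pd.DataFrame
    config: SimulationConfig
    sample_seeds: list[int] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def validate(self) -> None:
        sums = self.ground_truth.sum(axis=1).to_numpy()
        if not np.allclose(sums, 1.0, atol=1e-9):
            raise DomainError("ground-truth rows must sum to 1")


def simulate_sample(
    reference: SingleCellReference,
    fractions: pd.Series,
    n_cells: int,
    depth: float,
    factors: ScalingFactors,
    seed: int,
    level: str = "fine",
) -> tuple[np.ndarray, pd.Series]:
    """One pseudo-bulk sample: expression vector and its ground-truth row.

    Cells are drawn uniformly with replacement within each type, at per-type
    counts from :func:`draw_cell_counts`; each drawn cell contributes its
    library-normalized count vector times its scaling factor (so that with
    all factors one, every cell carries equal mRNA mass and the expression
    shares match the cell-count fractions); the aggregate is rescaled to sum
    to ``depth``. The cell draw depends only on (seed, fractions, n_cells) —
    not on the factors — so paired bias/no-bias samples use identical cells.
    Ground truth is the realized *cell-count* fraction per type.
    """
    types = list(fractions.index)
    labels = reference.obs[level].to_numpy()
    missing = [t for t in types if t not in set(labels)]
    if missing:
        raise ConfigurationError(f"cell types absent from reference at level {level!r}: {missing}")
    per_type = draw_cell_counts(fractions.to_numpy(), n_cells)
    rng = np.random.default_rng(seed)

    weight = np.zeros(reference.n_cells)
    for t, k in zip(types, per_type):
        if k == 0:
            continue
        pool = np.flatnonzero(labels == t)
        drawn = rng.integers(0, len(pool), size=int(k))
        mult = np.bincount(drawn, minlength=len(pool)).astype(float)
        weight[pool] += mult
    lib = reference.counts_per_cell().astype(float)
    if (lib[weight > 0] <= 0).any():
        raise DomainError("drawn cell with zero total counts")
    expr = np.asarray(reference.counts @ (weight * factors.per_cell / lib)).ravel()
    total = expr.sum()
    if total <= 0:
        raise DomainError("simulated sample has zero total expression")
    expr *= depth / total
    truth = pd.Series(per_type / n_cells, index=types)
    return expr, truth


def _scenario_fraction_rows(
    reference: SingleCellReference, config: SimulationConfig
) -> list[tuple[pd.Series, int]]:
    """Target fraction row and RNG seed for every sample of the run."""
    level = config.level
    all_types = reference.cell_types(level)
    types = config.cell_types if config.cell_types is not None else all_types
    unknown = sorted(set(types) - set(all_types))
    if unknown:
        raise ConfigurationError(f"cell types not in the reference: {unknown}")

    rows: list[tuple[pd.Series, int]] = []
    if config.scenario == "pure":
        if config.pure_type not in types:
            raise ConfigurationError(f"pure_type {config.pure_type!r} not in the sampled types")
        one_hot = pd.Series(0.0, index=types)
        one_hot[config.pure_type] = 1.0
        for i in range(config.n_replicates):
            rows.append((one_hot.copy(), config.seed + i))
    elif config.scenario == "mirror_fractions":
        tf = config.target_fractions
        if isinstance(tf, pd.Series):
            tf = tf.to_frame().T
        extra = sorted(set(tf.columns) - set(all_types))
        if extra:
            raise ConfigurationError(f"mirror_fractions columns not in the reference: {extra}")
        i = 0
        for _, row in tf.iterrows():
            for _ in range(config.n_replicates):
                rows.append((row.astype(float), config.seed + i))
                i += 1
    elif config.scenario == "mirror_db":
        props = reference.proportions(level)
        props = props[props.index.isin(types)]
        props = props / props.sum()
        for i in range(config.n_samples * config.n_replicates):
            rows.append((props.copy(), config.seed + i))
    elif config.scenario == "random":
        for i in range(config.n_samples * config.n_replicates):
            rng = np.random.default_rng(config.seed + i)
            f = rng.dirichlet(np.ones(len(types)))
            rows.append((pd.Series(f, index=types), config.seed + i))
    else:  # weighted_spike
        if config.spike_type not in types:
            raise ConfigurationError(f"spike_type {config.spike_type!r} not in the sampled types")
        others = [t for t in types if t != config.spike_type]
        if not others:
            raise ConfigurationError("weighted_spike needs at least one non-spike type")
        for i in range(config.n_samples * config.n_replicates):
            rng = np.random.default_rng(config.seed + i)
            rest = rng.dirichlet(np.ones(len(others))) * (1.0 - config.spike_level)
            row = pd.Series(rest, index=others)
            row[config.spike_type] = config.spike_level
            rows.append((row[types], config.seed + i))
    return rows


def simulate_dataset(reference: SingleCellReference, config: SimulationConfig) -> PseudoBulkDataset:
    """Simulate a full pseudo-bulk dataset under the configured scenario.

    The fraction draw for sample *i* uses RNG seed ``config.seed + i``, and
    the cell draw re-derives from the same seed, so two runs differing only
    in ``bias_mode`` pair sample-by-sample: identical ground truths, and
    identical expression whenever all scaling factors are one.
    """
    factors = compute_scaling_factors(reference, config.bias_mode)
    rows = _scenario_fraction_rows(reference, config)
    exprs, truths, seeds = [], [], []
    for fractions, sample_seed in rows:
        # weighted_spike at level 0 can carry an exactly-zero spike column;
        # keep the column in the truth but drop nothing from the draw
        expr, truth = simulate_sample(
            reference, fractions, config.n_cells, config.depth, factors,
            seed=sample_seed, level=config.level,
        )
        exprs.append(expr)
        truths.append(truth)
        seeds.append(sample_seed)
    sample_ids = [f"S{i + 1:04d}" for i in range(len(exprs))]
    expression = pd.DataFrame(
        np.column_stack(exprs), index=reference.gene_ids, columns=sample_ids
    )
    ground_truth = pd.DataFrame(truths, index=sample_ids)
    ds = PseudoBulkDataset(expression, ground_truth, config, seeds)
    ds.validate()
    return ds
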