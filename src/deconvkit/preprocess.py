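"""Quality control, CPM normalization, and reference subsampling.

QC follows the MAD-outlier convention for single-cell data: a cell is an
outlier when one of its metrics deviates from the metric's median by more
than *k* MADs, with MAD = median(|x - median(x)|) and no consistency-constant
rescaling. Following standard practice for this filter, total counts and
expressed-gene numbers are tested on the log1p scale (their raw distributions
are log-normal-like, so a raw-scale rule would flag whole high-content cell
types rather than genuine outliers) and two-sided; the mitochondrial fraction
is tested on its raw scale and only upward (a low mito fraction is not a
quality problem).

Three subsampling rules are provided: a per-type fraction (keep ceil(f*n_t)
of each type), a proportional total (largest-remainder apportionment to a
target cell count), and a per-type cap. Types smaller than ``min_guard``
cells are exempt from downsampling so rare populations are never thinned.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, DomainError
from .reference import SingleCellReference, iter_type_blocks
from .util import largest_remainder

logger = logging.getLogger(__name__)

__all__ = [
    "QCThresholds",
    "mad",
    "mad_outlier_filter",
    "cpm_normalize",
    "subsample_reference",
]


class QCThresholds:
    """MAD multipliers for the three QC metrics (counts, genes two-sided; mito upper)."""

    def __init__(self, n_counts_mads: float = 5.0, n_genes_mads: float = 5.0,
                 mito_mads: float = 3.0):
        if min(n_counts_mads, n_genes_mads, mito_mads) <= 0:
            raise ConfigurationError("all MAD thresholds must be > 0")
        self.n_counts_mads = float(n_counts_mads)
        self.n_genes_mads = float(n_genes_mads)
        self.mito_mads = float(mito_mads)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"QCThresholds(n_counts_mads={self.n_counts_mads}, "
                f"n_genes_mads={self.n_genes_mads}, mito_mads={self.mito_mads})")


def mad(values) -> float:
    """Median absolute deviation, median(|x_i - median(x)|), unscaled."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("mad() of an empty vector is undefined")
    return float(np.median(np.abs(x - np.median(x))))


def mad_outlier_filter(
    reference: SingleCellReference,
    thresholds: QCThresholds | None = None,
) -> SingleCellReference:
    """Remove outlier cells by the MAD rule; retained cells keep their order.

    Removed cell ids are reported through the module logger. Raises
    :class:`DomainError` if every cell would be removed.
    """
    thresholds = thresholds or QCThresholds()
    counts = np.log1p(reference.counts_per_cell().astype(float))
    genes = np.log1p(reference.genes_per_cell().astype(float))
    mito = reference.obs["mito_fraction"].to_numpy(dtype=float)

    def _two_sided(x: np.ndarray, k: float) -> np.ndarray:
        med = np.median(x)
        return np.abs(x - med) > k * mad(x)

    def _upper(x: np.ndarray, k: float) -> np.ndarray:
        med = np.median(x)
        return (x - med) > k * mad(x)

    outlier = (
        _two_sided(counts, thresholds.n_counts_mads)
        | _two_sided(genes, thresholds.n_genes_mads)
        | _upper(mito, thresholds.mito_mads)
    )
    if outlier.all():
        raise DomainError("QC filter removed every cell (empty reference)")
    removed = [cid for cid, o in zip(reference.cell_ids, outlier) if o]
    logger.info("QC removed %d/%d cells: %s", len(removed), reference.n_cells,
                ", ".join(removed[:20]) + ("..." if len(removed) > 20 else ""))
    return reference.subset_cells(~outlier)


def cpm_normalize(matrix):
    """Scale every column to sum to one million (counts per million).

    Accepts a dense array, sparse matrix, or DataFrame (genes in rows,
    cells/samples in columns); returns the same container type with float
    values. A zero-sum column raises :class:`DomainError` naming the column.
    """
    if isinstance(matrix, pd.DataFrame):
        sums = matrix.sum(axis=0)
        zero = sums[sums <= 0]
        if len(zero):
            raise DomainError(f"zero-sum column(s): {list(zero.index)}")
        return matrix / sums * 1e6
    if sp.issparse(matrix):
        sums = np.asarray(matrix.sum(axis=0)).ravel()
        _check_zero_columns(sums)
        scale = sp.diags(1e6 / sums)
        return (matrix @ scale).tocsc()
    x = np.asarray(matrix, dtype=float)
    sums = x.sum(axis=0)
    _check_zero_columns(np.atleast_1d(sums))
    return x / sums * 1e6


def _check_zero_columns(sums: np.ndarray) -> None:
    zero = np.flatnonzero(sums <= 0)
    if zero.size:
        raise DomainError(f"zero-sum column(s) at positions: {zero.tolist()}")


_SUBSAMPLE_MODES = ("fraction_per_type", "total_proportional", "cap_per_type")


def subsample_reference(
    reference: SingleCellReference,
    mode: str,
    param: float,
    min_guard: int = 20,
    seed: int = 0,
    level: str = "fine",
) -> SingleCellReference:
    """Downsample cells without replacement under one of three rules.

    ``fraction_per_type``
        keep ``ceil(param * n_t)`` cells of every type *t*; types with
        ``n_t < min_guard`` cells are kept whole.
    ``total_proportional``
        target ``param`` total cells, apportioned across types by the
        largest-remainder rule on the observed proportions; guarded types
        kept whole.
    ``cap_per_type``
        keep ``min(n_t, param)`` cells per type.

    Sampling is seed-deterministic and preserves the original cell order.
    """
    if mode not in _SUBSAMPLE_MODES:
        raise ConfigurationError(f"unknown subsample mode {mode!r}; choose from {_SUBSAMPLE_MODES}")
    blocks = list(iter_type_blocks(reference.obs, level))
    sizes = np.array([len(ix) for _, ix in blocks])

    if mode == "fraction_per_type":
        if not (0 < param <= 1):
            raise ConfigurationError(f"fraction_per_type needs param in (0, 1], got {param}")
        take = np.ceil(param * sizes).astype(int)
        take = np.where(sizes < min_guard, sizes, take)
    elif mode == "cap_per_type":
        if param < 1:
            raise ConfigurationError(f"cap_per_type needs param >= 1, got {param}")
        take = np.minimum(sizes, int(param))
    else:  # total_proportional
        total = int(param)
        if total < len(blocks):
            raise ConfigurationError(
                f"total_proportional target {total} below the number of types {len(blocks)}"
            )
        guarded = sizes < min_guard
        budget = total - int(sizes[guarded].sum())
        if budget < 0:
            raise ConfigurationError("guarded types alone exceed the requested total")
        free_sizes = sizes[~guarded]
        quota = largest_remainder(free_sizes / free_sizes.sum(), budget)
        quota = np.minimum(quota, free_sizes)  # a quota can never exceed the type size
        take = sizes.copy()
        take[~guarded] = quota

    rng = np.random.default_rng(seed)
    keep: list[np.ndarray] = []
    for (label, ix), n_keep in zip(blocks, take):
        if n_keep >= len(ix):
            keep.append(ix)
        else:
            keep.append(rng.choice(ix, size=int(n_keep), replace=False))
    order = np.sort(np.concatenate(keep))
    return reference.subset_cells(order)
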