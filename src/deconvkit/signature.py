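"""Signature matrix construction and quality scores.

A signature matrix is the genes x cell-types matrix of mean CPM expression
over a marker gene set. Markers are selected per type by a one-vs-rest
Wilcoxon rank-sum test on CPM values, gated on a Benjamini-Hochberg adjusted
p-value and a positive log2 fold-change, ranked by fold-change and capped per
type.

Three signature quality scores are provided:

* entropy specificity — 1 minus the normalized Shannon entropy of a gene's
  expression distribution across types; 1 for a perfectly type-specific
  (one-hot) gene, 0 for a uniformly expressed one;
* Gini index — dispersion of a gene's across-type expression, 0 when all
  values are equal, approaching 1 when maximally concentrated;
* condition number kappa — ratio of the largest to smallest singular value of
  the signature; values near 1 indicate that estimated fractions are stable
  under perturbations of the bulk input.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DomainError
from .preprocess import cpm_normalize
from .reference import SingleCellReference, iter_type_blocks

logger = logging.getLogger(__name__)

__all__ = [
    "SignatureMatrix",
    "SignatureQC",
    "select_marker_genes",
    "build_signature",
    "entropy_specificity",
    "gini_index",
    "condition_number",
    "signature_qc",
]


@dataclass
class SignatureMatrix:
    """Genes x cell-types mean-CPM profile over a selected marker set."""

    values: pd.DataFrame  # genes x types
    build_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ConfigurationError("a signature needs at least 2 cell types")
        if self.values.shape[0] < 1:
            raise ConfigurationError("a signature needs at least 1 gene")
        if (self.values.to_numpy() < 0).any():
            raise DomainError("signature entries must be non-negative")
        zero_rows = self.values.index[(self.values.sum(axis=1) == 0)]
        if len(zero_rows):
            raise DomainError(f"all-zero signature rows: {list(zero_rows[:5])}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_types(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]


@dataclass
class SignatureQC:
    """Per-gene specificity scores plus the matrix condition number."""

    entropy: pd.Series
    gini: pd.Series
    condition_number: float
    n_genes: int

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"entropy_specificity": self.entropy, "gini": self.gini})
        out.attrs["condition_number"] = self.condition_number
        out.attrs["n_genes"] = self.n_genes
        return out


def select_marker_genes(
    reference: SingleCellReference,
    level: str = "fine",
    pval_cutoff: float = 0.05,
    max_genes_per_type: int = 200,
) -> list[str]:
    """Marker genes by one-vs-rest rank-sum test on CPM values.

    Per type, genes with BH-adjusted p below ``pval_cutoff`` *and* positive
    log2 fold-change (type mean vs rest mean, 1-count pseudo) are ranked by
    fold-change and capped at ``max_genes_per_type``; the union over types is
    returned in the reference's gene order.
    """
    blocks = list(iter_type_blocks(reference.obs, level))
    if len(blocks) < 2:
        raise ConfigurationError(f"need >= 2 cell types at level {level!r}")
    small = [t for t, ix in blocks if len(ix) < 3]
    if small:
        raise ConfigurationError(f"cell types with < 3 cells: {small}")

    cpm = np.asarray(cpm_normalize(reference.counts).todense(), dtype=float)
    # rank once per gene over all cells; the rank-sum of the in-group columns
    # is the Wilcoxon statistic for every one-vs-rest contrast
    ranks = stats.rankdata(cpm, axis=1)
    n = reference.n_cells
    # tie correction term per gene for the normal approximation
    tie_term = np.array([(np.bincount(row.astype(np.int64)) ** 3).sum() for row in ranks * 2])
    tie_correction = 1.0 - (tie_term - n) / (n**3 - n)
    selected: set[int] = set()
    for t, ix in blocks:
        n1 = len(ix)
        n2 = n - n1
        rank_sum = ranks[:, ix].sum(axis=1)
        u = rank_sum - n1 * (n1 + 1) / 2.0
        mu = n1 * n2 / 2.0
        sigma = np.sqrt(n1 * n2 / 12.0 * (n + 1) * tie_correction)
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (u - mu - np.sign(u - mu) * 0.5) / sigma  # continuity-corrected
        z = np.nan_to_num(z, nan=0.0)  # constant genes: no evidence
        pvals = 2.0 * stats.norm.sf(np.abs(z))
        padj = multipletests(pvals, method="fdr_bh")[1]
        mask = np.zeros(n, dtype=bool)
        mask[ix] = True
        lfc = np.log2(cpm[:, mask].mean(axis=1) + 1.0) - np.log2(
            cpm[:, ~mask].mean(axis=1) + 1.0
        )
        hit = np.flatnonzero((padj < pval_cutoff) & (lfc > 0))
        hit = hit[np.argsort(-lfc[hit], kind="stable")][:max_genes_per_type]
        selected.update(hit.tolist())
        logger.debug("markers for %s: %d", t, len(hit))
    if not selected:
        raise DomainError(
            f"no marker genes pass pval_cutoff={pval_cutoff}; loosen the cutoff"
        )
    order = sorted(selected)
    return [reference.gene_ids[i] for i in order]


def build_signature(
    reference: SingleCellReference,
    genes: list[str],
    level: str = "fine",
    pval_cutoff: float | None = None,
) -> SignatureMatrix:
    """Mean CPM per cell type over the given genes (columns in sorted type order)."""
    index = {g: i for i, g in enumerate(reference.gene_ids)}
    unknown = [g for g in genes if g not in index]
    if unknown:
        raise ConfigurationError(f"genes not in the reference: {unknown[:10]}")
    rows = [index[g] for g in genes]
    cpm = cpm_normalize(reference.counts)
    cols = {}
    for t, ix in iter_type_blocks(reference.obs, level):
        cols[t] = np.asarray(cpm[rows][:, ix].mean(axis=1)).ravel()
    values = pd.DataFrame(cols, index=list(genes))
    values = values.loc[values.sum(axis=1) > 0]
    meta = {
        "level": level,
        "pval_cutoff": pval_cutoff,
        "n_cells": reference.n_cells,
        "n_genes_requested": len(genes),
    }
    return SignatureMatrix(values=values, build_meta=meta)


def make_signature(
    reference: SingleCellReference,
    level: str = "fine",
    pval_cutoff: float = 0.05,
    max_genes_per_type: int = 200,
) -> SignatureMatrix:
    """Convenience: marker selection followed by signature construction."""
    genes = select_marker_genes(reference, level, pval_cutoff, max_genes_per_type)
    sig = build_signature(reference, genes, level, pval_cutoff=pval_cutoff)
    sig.build_meta["max_genes_per_type"] = max_genes_per_type
    return sig


def entropy_specificity(signature: SignatureMatrix | pd.DataFrame) -> pd.Series:
    """Per-gene specificity 1 - H(p)/log2(C), p the gene's across-type profile.

    1 for a one-hot gene (expressed in a single type), 0 for uniform
    expression across all C types; 0*log(0) is taken as 0.
    """
    values = signature.values if isinstance(signature, SignatureMatrix) else signature
    x = values.to_numpy(dtype=float)
    row_sums = x.sum(axis=1)
    if (row_sums <= 0).any():
        bad = values.index[row_sums <= 0]
        raise DomainError(f"all-zero gene rows: {list(bad[:5])}")
    p = x / row_sums[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    h = -plogp.sum(axis=1)
    score = 1.0 - h / np.log2(x.shape[1])
    return pd.Series(score, index=values.index, name="entropy_specificity")


def gini_index(values) -> float:
    """Gini index G = sum_ij |x_i - x_j| / (2 n^2 mean(x)) of a non-negative vector.

    0 when all values are equal; 1 in the limit of all mass on one of many
    entries. An all-zero vector is defined as 0 (with a warning).
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("gini_index of an empty vector is undefined")
    if (x < 0).any():
        raise DomainError("gini_index requires non-negative values")
    total = x.sum()
    if total == 0:
        warnings.warn("gini_index of an all-zero vector defined as 0", stacklevel=2)
        return 0.0
    # sorted-identity form of the pairwise double sum
    xs = np.sort(x)
    n = x.size
    i = np.arange(1, n + 1)
    return float(np.sum((2 * i - n - 1) * xs) / (n * total))


def gene_gini(signature: SignatureMatrix | pd.DataFrame) -> pd.Series:
    """Gini index of every gene's across-type expression profile."""
    values = signature.values if isinstance(signature, SignatureMatrix) else signature
    out = values.apply(lambda row: gini_index(row.to_numpy()), axis=1)
    out.name = "gini"
    return out


def condition_number(signature: SignatureMatrix | pd.DataFrame, rcond: float = 1e-12) -> float:
    """Condition number kappa = sigma_max / sigma_min of the signature matrix.

    Equivalent to ||M|| * ||M^-1|| in the 2-norm for square invertible M; the
    singular-value ratio generalizes this to the rectangular genes x types
    case. A rank-deficient signature returns infinity, with a warning naming
    the collinear columns.
    """
    values = signature.values if isinstance(signature, SignatureMatrix) else signature
    x = values.to_numpy(dtype=float)
    s = np.linalg.svd(x, compute_uv=False)
    if s[-1] <= rcond * s[0]:
        cols = _collinear_columns(values)
        warnings.warn(
            f"signature is rank-deficient (collinear columns: {cols}); kappa = inf",
            stacklevel=2,
        )
        return float("inf")
    return float(s[0] / s[-1])


def _collinear_columns(values: pd.DataFrame) -> list[tuple[str, str]]:
    """Pairs of columns with near-unit cosine similarity (diagnostic only)."""
    x = values.to_numpy(dtype=float)
    norms = np.linalg.norm(x, axis=0)
    norms[norms == 0] = 1.0
    u = x / norms
    cos = u.T @ u
    pairs = []
    cols = list(values.columns)
    for i in range(len(cols)):
        for j in range(i + 1, len(cols)):
            if cos[i, j] > 1 - 1e-10:
                pairs.append((cols[i], cols[j]))
    return pairs


def signature_qc(signature: SignatureMatrix) -> SignatureQC:
    """All quality scores of a signature in one report."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        kappa = condition_number(signature)
    return SignatureQC(
        entropy=entropy_specificity(signature),
        gini=gene_gini(signature),
        condition_number=kappa,
        n_genes=signature.n_genes,
    )
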