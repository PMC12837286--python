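"""Shared fixtures: small synthetic references built once per session."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

import deconvkit as dk


@pytest.fixture(scope="session")
def stock_reference() -> dk.SingleCellReference:
    """The 2,500-cell / 2,000-gene blood-like fixture (seed 1)."""
    return dk.example_reference(seed=1)


@pytest.fixture(scope="session")
def stock_signature(stock_reference) -> dk.SignatureMatrix:
    return dk.make_signature(stock_reference)


@pytest.fixture(scope="session")
def uniform_content_reference() -> dk.SingleCellReference:
    """Three types sharing one background profile; only markers differ.

    Built directly from a shared gamma-Poisson background with 20 strongly
    elevated marker genes per type, so the only truly differential genes are
    the planted markers and selection precision is interpretable.
    """
    rng = np.random.default_rng(1)
    n_genes, per_type = 2000, 150
    types = ("alpha", "beta", "gamma")
    base = rng.lognormal(0.0, 1.0, n_genes)
    base = base / base.sum() * 4000.0  # shared background, library 4000
    blocks, fine, markers = [], [], {}
    for t, name in enumerate(types):
        idx = np.arange(t * 20, (t + 1) * 20)
        markers[name] = [f"G{i:04d}" for i in idx]
        mu = base.copy()
        mu[idx] *= 8.0
        mu = mu / mu.sum() * 4000.0  # same library for every type: background
        # genes keep identical CPM levels and only markers are differential
        lam = rng.gamma(2.0, np.tile(mu[:, None] / 2.0, (1, per_type)))
        blocks.append(rng.poisson(lam))
        fine += [name] * per_type
    ref = tiny_reference(np.hstack(blocks).astype(np.int64), fine)
    ref.gene_ids = [f"G{i:04d}" for i in range(n_genes)]
    ref.marker_genes = markers
    ref, _ = ref.drop_zero_genes()
    return ref


def make_orthogonal_reference(
    n_types: int = 3, genes_per_type: int = 12, cells_per_type: int = 60, seed: int = 0
) -> dk.SingleCellReference:
    """Types with disjoint expressed gene blocks and zero background.

    The resulting signature is block-diagonal, the fully separable regime.
    """
    rng = np.random.default_rng(seed)
    n_genes = n_types * genes_per_type
    n_cells = n_types * cells_per_type
    counts = np.zeros((n_genes, n_cells), dtype=np.int64)
    fine = []
    for t in range(n_types):
        rows = slice(t * genes_per_type, (t + 1) * genes_per_type)
        cols = slice(t * cells_per_type, (t + 1) * cells_per_type)
        counts[rows, cols] = rng.poisson(50.0, size=(genes_per_type, cells_per_type)) + 1
        fine += [f"type{t + 1}"] * cells_per_type
    cell_ids = [f"C{i:04d}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {
            "fine": fine,
            "normal": fine,
            "coarse": fine,
            "donor_id": ["d1"] * n_cells,
            "mito_fraction": rng.beta(2, 40, n_cells),
        },
        index=cell_ids,
    )
    return dk.SingleCellReference(
        counts=sp.csc_matrix(counts),
        gene_ids=[f"G{i:04d}" for i in range(n_genes)],
        cell_ids=cell_ids,
        obs=obs,
    )


@pytest.fixture(scope="session")
def orthogonal_reference() -> dk.SingleCellReference:
    return make_orthogonal_reference()


@pytest.fixture(scope="session")
def similar_pair_reference() -> dk.SingleCellReference:
    """Two nearly identical types (weak, few markers) plus one distinct type.

    Spillover should concentrate between the similar pair, not toward the
    distinct third type.
    """
    specs = [
        dk.CellTypeSpec("twinA", 150, 600, 4000.0, n_markers=2, marker_fold=2.5),
        dk.CellTypeSpec("twinB", 150, 600, 4000.0, n_markers=2, marker_fold=2.5),
        dk.CellTypeSpec("distinct", 150, 600, 4000.0, n_markers=25, marker_fold=16.0),
    ]
    return dk.generate_reference(specs, n_genes=1500, seed=1)


def tiny_reference(counts: np.ndarray, fine: list[str], seed: int = 0) -> dk.SingleCellReference:
    """Wrap a dense counts array into a minimal annotated reference."""
    rng = np.random.default_rng(seed)
    n_genes, n_cells = counts.shape
    cell_ids = [f"C{i:03d}" for i in range(n_cells)]
    obs = pd.DataFrame(
        {
            "fine": fine,
            "normal": fine,
            "coarse": fine,
            "donor_id": ["d1"] * n_cells,
            "mito_fraction": rng.beta(2, 40, n_cells),
        },
        index=cell_ids,
    )
    return dk.SingleCellReference(
        counts=sp.csc_matrix(np.asarray(counts)),
        gene_ids=[f"G{i:03d}" for i in range(n_genes)],
        cell_ids=cell_ids,
        obs=obs,
    )
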