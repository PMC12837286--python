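"""Annotated single-cell reference container and synthetic reference generator.

A :class:`SingleCellReference` holds a sparse genes x cells count matrix plus
per-cell metadata: a three-level cell-type label hierarchy (fine -> normal ->
coarse), a donor label, and a mitochondrial-read fraction. The synthetic
generator :func:`generate_reference` produces references with controlled
marker structure and controlled per-type mRNA content — proxied, as is common
for pseudo-bulk simulation, by the number of expressed (nonzero) genes per
cell — so that every downstream benchmarking experiment can run without any
real dataset.

Count model
-----------
Counts are gamma-Poisson (negative binomial): for a cell of type *t* the mean
of gene *g* is ``lib_factor_cell * profile_t[g]`` where ``profile_t`` sums to
the type's mean library size, and the NB dispersion is shared. Each type
expresses a contiguous-by-rank *support* of genes: markers of the type first,
then the most abundant background genes. The support size is solved by
bisection on the analytic NB zero-probability so that the expected number of
nonzero genes per cell matches ``expressed_gene_target``; this leaves the
library size and the expressed-gene count independently controllable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import ConfigurationError, DomainError

__all__ = [
    "CellTypeSpec",
    "SingleCellReference",
    "generate_reference",
    "example_specs",
    "example_reference",
]

#: per-cell annotation columns every reference must carry
ANNOTATION_COLUMNS = ("fine", "normal", "coarse", "donor_id", "mito_fraction")


@dataclass(frozen=True)
class CellTypeSpec:
    """Generative parameters for one (fine-level) cell type.

    Parameters
    ----------
    name
        Fine-level label, unique within a reference.
    parent_normal, parent_coarse
        Labels at the intermediate and coarse annotation level; default to
        ``name`` (a type that is its own lineage).
    n_cells
        Number of cells to generate.
    n_markers
        Number of genes reserved as markers of this type (disjoint across
        types).
    expressed_gene_target
        Expected number of nonzero genes per cell — the mRNA-content proxy.
    mean_library_size
        Expected total counts per cell.
    marker_fold
        Fold elevation of marker-gene means inside the own type.
    marker_background
        Relative abundance of *other* types' markers in this type
        (0 = fully orthogonal marker structure).
    """

    name: str
    n_cells: int
    expressed_gene_target: int
    mean_library_size: float = 5000.0
    n_markers: int = 20
    parent_normal: str | None = None
    parent_coarse: str | None = None
    marker_fold: float = 16.0
    marker_background: float = 0.02

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ConfigurationError(f"{self.name}: n_cells must be >= 1, got {self.n_cells}")
        if self.n_markers < 0:
            raise ConfigurationError(f"{self.name}: n_markers must be >= 0")
        if self.expressed_gene_target < 1:
            raise ConfigurationError(f"{self.name}: expressed_gene_target must be positive")
        if self.mean_library_size <= 0:
            raise ConfigurationError(f"{self.name}: mean_library_size must be positive")

    @property
    def normal(self) -> str:
        return self.parent_normal if self.parent_normal is not None else self.name

    @property
    def coarse(self) -> str:
        return self.parent_coarse if self.parent_coarse is not None else self.normal


@dataclass
class SingleCellReference:
    """Annotated genes x cells count matrix with a label hierarchy.

    ``counts`` is sparse CSC (genes in rows, cells in columns); ``obs`` is a
    cell-indexed frame with columns ``fine``, ``normal``, ``coarse``,
    ``donor_id`` and ``mito_fraction``. Every fine label maps to exactly one
    normal and one coarse label.
    """

    counts: sp.csc_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    obs: pd.DataFrame
    marker_genes: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = sp.csc_matrix(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise ConfigurationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        missing = [c for c in ANNOTATION_COLUMNS if c not in self.obs.columns]
        if missing:
            raise ConfigurationError(f"missing annotation columns: {missing}")
        if list(self.obs.index) != list(self.cell_ids):
            self.obs = self.obs.loc[self.cell_ids]
        self.validate_hierarchy()

    # -- structure ---------------------------------------------------------

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def validate_hierarchy(self) -> None:
        """Every fine label must map to exactly one (normal, coarse) pair."""
        per_fine = self.obs.groupby("fine", observed=True)[["normal", "coarse"]].nunique()
        bad = per_fine[(per_fine["normal"] != 1) | (per_fine["coarse"] != 1)]
        if len(bad):
            raise ConfigurationError(
                "fine labels with ambiguous parents: " + ", ".join(map(str, bad.index))
            )

    def cell_types(self, level: str = "fine") -> list[str]:
        if level not in ("fine", "normal", "coarse"):
            raise ConfigurationError(f"unknown annotation level {level!r}")
        return sorted(self.obs[level].unique())

    def proportions(self, level: str = "fine") -> pd.Series:
        """Observed cell-type proportions at a resolution level."""
        p = self.obs[level].value_counts(normalize=True).sort_index()
        p.name = "proportion"
        return p

    def hierarchy_map(self, frm: str = "fine", to: str = "coarse") -> dict[str, str]:
        """Total fine-to-coarse (or fine-to-normal) label map."""
        if frm == to:
            return {t: t for t in self.obs[frm].unique()}
        pairs = self.obs[[frm, to]].drop_duplicates()
        return dict(zip(pairs[frm], pairs[to]))

    # -- per-cell metrics --------------------------------------------------

    def counts_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        """Number of expressed (nonzero) genes per cell, the mRNA-content proxy."""
        return self.counts.getnnz(axis=0)

    # -- derived references ------------------------------------------------

    def subset_cells(self, index: np.ndarray) -> "SingleCellReference":
        """New reference restricted to the given cell positions (order kept)."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return SingleCellReference(
            counts=self.counts[:, index],
            gene_ids=list(self.gene_ids),
            cell_ids=[self.cell_ids[i] for i in index],
            obs=self.obs.iloc[index].copy(),
            marker_genes={t: list(g) for t, g in self.marker_genes.items()},
        )

    def drop_cell_types(self, names, level: str = "fine") -> "SingleCellReference":
        keep = ~self.obs[level].isin(list(names)).to_numpy()
        if not keep.any():
            raise DomainError("dropping these cell types would empty the reference")
        return self.subset_cells(keep)

    def drop_zero_genes(self) -> tuple["SingleCellReference", int]:
        """Remove all-zero gene rows; returns (reference, number removed)."""
        nnz = self.counts.getnnz(axis=1)
        keep = nnz > 0
        n_removed = int((~keep).sum())
        if n_removed == 0:
            return self, 0
        kept_genes = [g for g, k in zip(self.gene_ids, keep) if k]
        kept_set = set(kept_genes)
        ref = SingleCellReference(
            counts=self.counts[keep, :],
            gene_ids=kept_genes,
            cell_ids=list(self.cell_ids),
            obs=self.obs.copy(),
            marker_genes={
                t: [g for g in genes if g in kept_set] for t, genes in self.marker_genes.items()
            },
        )
        return ref, n_removed

    def equals(self, other: "SingleCellReference") -> bool:
        return (
            self.gene_ids == other.gene_ids
            and self.cell_ids == other.cell_ids
            and (self.counts != other.counts).nnz == 0
            and self.obs[list(ANNOTATION_COLUMNS[:4])].equals(
                other.obs[list(ANNOTATION_COLUMNS[:4])]
            )
            and np.allclose(self.obs["mito_fraction"], other.obs["mito_fraction"], atol=1e-12)
        )


# ---------------------------------------------------------------------------
# generator internals


def _nb_zero_prob(mean: np.ndarray, dispersion: float) -> np.ndarray:
    """P(X = 0) for NB with given mean and shape (size) parameter."""
    return np.power(dispersion / (dispersion + mean), dispersion)


def _expected_nonzero(unnormalized: np.ndarray, k: int, library: float, dispersion: float) -> float:
    """Expected nonzero genes per cell if the first ``k`` genes form the support."""
    u = unnormalized[:k]
    means = u * (library / u.sum())
    return float(np.sum(1.0 - _nb_zero_prob(means, dispersion)))


def _solve_support_size(
    unnormalized: np.ndarray, target: int, library: float, dispersion: float
) -> int:
    """Smallest support size whose expected nonzero count reaches ``target``.

    The expected count is monotone non-decreasing in the support size over the
    relevant range, so plain bisection suffices.
    """
    n = len(unnormalized)
    lo, hi = 1, n
    if _expected_nonzero(unnormalized, n, library, dispersion) < 0.9 * target:
        raise ConfigurationError(
            f"expressed_gene_target={target} unreachable: even expressing all {n} "
            f"candidate genes at library size {library:.0f} yields fewer nonzero genes; "
            "increase mean_library_size or lower the target"
        )
    while lo < hi:
        mid = (lo + hi) // 2
        if _expected_nonzero(unnormalized, mid, library, dispersion) < target:
            lo = mid + 1
        else:
            hi = mid
    return lo


def generate_reference(
    specs: list[CellTypeSpec],
    n_genes: int,
    n_donors: int = 3,
    seed: int = 0,
    dispersion: float = 2.0,
    library_sigma: float = 0.45,
) -> SingleCellReference:
    """Generate an annotated single-cell reference from type specs.

    Deterministic given ``seed``: identical arguments yield bit-identical
    references. Marker genes of distinct types are disjoint; each type's
    markers have ``marker_fold``-elevated means inside the type and are
    suppressed to ``marker_background`` of baseline elsewhere. Per-type
    expressed-gene counts land within 10% of ``expressed_gene_target`` in
    expectation (see module docstring for the mechanism). Donor labels are
    assigned round-robin over ``n_donors`` donors; mitochondrial fractions are
    Beta(2, 40) per cell, the typical healthy-cell range.

    All-zero gene rows (genes outside every type's support) are removed before
    returning, so the reference satisfies the no-empty-gene invariant.
    """
    if not specs:
        raise ConfigurationError("need at least one CellTypeSpec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ConfigurationError(f"duplicate cell-type names in specs: {names}")
    total_markers = sum(s.n_markers for s in specs)
    if total_markers > n_genes:
        raise ConfigurationError(
            f"marker budget {total_markers} exceeds n_genes={n_genes}"
        )
    for s in specs:
        if s.expressed_gene_target > n_genes:
            raise ConfigurationError(
                f"{s.name}: expressed_gene_target {s.expressed_gene_target} > n_genes {n_genes}"
            )
    if n_donors < 1:
        raise ConfigurationError("n_donors must be >= 1")

    rng = np.random.default_rng(seed)
    gene_ids = [f"G{i + 1:05d}" for i in range(n_genes)]

    # baseline relative abundances shared by all types (log-normal tail)
    base = rng.lognormal(mean=0.0, sigma=1.0, size=n_genes)

    # disjoint marker blocks, assigned in spec order from the front
    marker_idx: dict[str, np.ndarray] = {}
    cursor = 0
    for s in specs:
        marker_idx[s.name] = np.arange(cursor, cursor + s.n_markers)
        cursor += s.n_markers
    all_marker_idx = np.arange(cursor)

    # per-type mean profiles
    profiles: dict[str, np.ndarray] = {}
    supports: dict[str, np.ndarray] = {}
    for s in specs:
        m = base.copy()
        own = marker_idx[s.name]
        others = np.setdiff1d(all_marker_idx, own)
        # floor marker baseline at the distribution median so every marker
        # lands in the top decile of its own type's expression
        m[own] = np.maximum(m[own], 1.0) * s.marker_fold
        m[others] *= s.marker_background
        # support: own markers first, then remaining genes by abundance rank
        rest = np.setdiff1d(np.arange(n_genes), own)
        rest = rest[np.argsort(-m[rest], kind="stable")]
        order = np.concatenate([own, rest])
        u = m[order]
        positive = u > 0
        order, u = order[positive], u[positive]
        k = _solve_support_size(u, s.expressed_gene_target, s.mean_library_size, dispersion)
        sup = order[:k]
        prof = np.zeros(n_genes)
        prof[sup] = m[sup] * (s.mean_library_size / m[sup].sum())
        profiles[s.name] = prof
        supports[s.name] = sup

    # draw counts type by type (cells stay grouped by spec order)
    blocks: list[sp.csc_matrix] = []
    fine, normal, coarse = [], [], []
    for s in specs:
        sup = supports[s.name]
        mu_sup = profiles[s.name][sup]
        lib = rng.lognormal(mean=-0.5 * library_sigma**2, sigma=library_sigma, size=s.n_cells)
        # gamma-Poisson draw restricted to the support
        lam = rng.gamma(shape=dispersion, scale=np.outer(mu_sup, lib) / dispersion)
        x = sp.coo_matrix(rng.poisson(lam))
        block = sp.coo_matrix(
            (x.data, (sup[x.row], x.col)), shape=(n_genes, s.n_cells), dtype=np.int64
        )
        blocks.append(block.tocsc())
        fine += [s.name] * s.n_cells
        normal += [s.normal] * s.n_cells
        coarse += [s.coarse] * s.n_cells

    counts = sp.hstack(blocks, format="csc").astype(np.int64)
    n_cells = counts.shape[1]
    cell_ids = [f"C{i + 1:06d}" for i in range(n_cells)]
    donors = [f"donor{(i % n_donors) + 1}" for i in range(n_cells)]
    mito = rng.beta(2.0, 40.0, size=n_cells)

    obs = pd.DataFrame(
        {
            "fine": fine,
            "normal": normal,
            "coarse": coarse,
            "donor_id": donors,
            "mito_fraction": mito,
        },
        index=cell_ids,
    )
    markers = {s.name: [gene_ids[i] for i in marker_idx[s.name]] for s in specs}
    ref = SingleCellReference(
        counts=counts, gene_ids=gene_ids, cell_ids=cell_ids, obs=obs, marker_genes=markers
    )
    ref, _ = ref.drop_zero_genes()
    return ref


# ---------------------------------------------------------------------------
# stock fixture: a small blood-like reference with a 3-level hierarchy


def example_specs(
    scale: float = 1.0,
    content_spread: float = 2.0,
) -> list[CellTypeSpec]:
    """Blood-like spec set: six fine types under a lymphoid/myeloid hierarchy.

    ``scale`` multiplies per-type cell numbers (1.0 -> 2,500 cells total);
    ``content_spread`` is the ratio of expressed-gene targets between
    monocytes (high mRNA content) and T cells (low), around a geometric
    middle of ~1,000 genes.
    """
    mid = 1000.0
    t_lo = int(round(mid / np.sqrt(content_spread)))
    t_hi = int(round(mid * np.sqrt(content_spread)))
    mk = dict(n_markers=25, marker_fold=16.0)
    lymph = dict(parent_coarse="Lymphoid")
    return [
        CellTypeSpec("T CD4", int(600 * scale), t_lo, 4000, parent_normal="T cells", **lymph, **mk),
        CellTypeSpec("T CD8", int(500 * scale), t_lo, 4000, parent_normal="T cells", **lymph, **mk),
        CellTypeSpec("Tregs", int(200 * scale), t_lo, 4000, parent_normal="T cells", **lymph, **mk),
        CellTypeSpec("B cells", int(400 * scale), 900, 5000, parent_normal="B cells", **lymph, **mk),
        CellTypeSpec("NK cells", int(300 * scale), 850, 5000, parent_normal="NK cells", **lymph, **mk),
        CellTypeSpec(
            "Monocytes", int(500 * scale), t_hi, 8000,
            parent_normal="Monocytes", parent_coarse="Myeloid", **mk,
        ),
    ]


def example_reference(
    seed: int = 1,
    n_genes: int = 2000,
    scale: float = 1.0,
    content_spread: float = 2.0,
    n_donors: int = 3,
) -> SingleCellReference:
    """The stock 2,500-cell / 2,000-gene fixture reference used in examples."""
    return generate_reference(
        example_specs(scale=scale, content_spread=content_spread),
        n_genes=n_genes,
        n_donors=n_donors,
        seed=seed,
    )


def specs_from_config(config: dict) -> tuple[list[CellTypeSpec], dict]:
    """Build specs from a YAML-style mapping (used by the fixtures CLI).

    Expected layout::

        n_genes: 2000
        n_donors: 3
        cell_types:
          - name: T CD4
            n_cells: 600
            expressed_gene_target: 700
            ...
    """
    try:
        raw = config["cell_types"]
        specs = [CellTypeSpec(**entry) for entry in raw]
        meta = {
            "n_genes": int(config["n_genes"]),
            "n_donors": int(config.get("n_donors", 3)),
        }
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"bad fixture config: {exc}") from exc
    return specs, meta


def _iter_type_blocks(obs: pd.DataFrame, level: str):
    """Yield (label, positional index array) per type, in sorted label order."""
    labels = obs[level].to_numpy()
    for label in sorted(pd.unique(labels)):
        yield label, np.flatnonzero(labels == label)


# re-exported helper used by preprocess and simulator
iter_type_blocks = _iter_type_blocks
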