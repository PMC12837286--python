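"""On-disk formats: Matrix Market references, CSV matrices, JSON reports.

A reference is a directory with ``matrix.mtx`` (genes x cells counts),
``genes.tsv`` (one gene id per line, with header) and ``cells.tsv`` (columns
``cell_id``, ``fine``, ``normal``, ``coarse``, ``donor_id``,
``mito_fraction``). Expression and fraction matrices travel as labeled CSV;
genes are always rows and cells/samples columns for expression, samples rows
and types columns for fractions. Numeric output keeps >= 10 significant
digits so tables round-trip within 1e-10.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

from .deconv import FractionMatrix
from .errors import ValidationError
from .reference import ANNOTATION_COLUMNS, SingleCellReference

logger = logging.getLogger(__name__)

__all__ = [
    "write_reference",
    "read_reference",
    "read_matrix_csv",
    "write_matrix_csv",
    "read_fractions",
    "write_fractions",
    "write_report",
]

_FLOAT_FORMAT = "%.12g"


# ---------------------------------------------------------------------------
# reference directories


def write_reference(reference: SingleCellReference, out_dir) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    mmwrite(out / "matrix.mtx", sp.coo_matrix(reference.counts))
    pd.Series(reference.gene_ids, name="gene_id").to_csv(
        out / "genes.tsv", sep="\t", index=False
    )
    cells = reference.obs.copy()
    cells.insert(0, "cell_id", reference.cell_ids)
    cells.to_csv(out / "cells.tsv", sep="\t", index=False, float_format=_FLOAT_FORMAT)
    if reference.marker_genes:
        (out / "markers.json").write_text(json.dumps(reference.marker_genes, indent=1))
    return out


def read_reference(in_dir) -> SingleCellReference:
    """Load and validate a reference directory; all-zero genes are stripped."""
    d = Path(in_dir)
    for name in ("matrix.mtx", "genes.tsv", "cells.tsv"):
        if not (d / name).exists():
            raise ValidationError(f"missing {name} in {d}")
    counts = sp.csc_matrix(mmread(d / "matrix.mtx"))
    genes = pd.read_csv(d / "genes.tsv", sep="\t")["gene_id"].astype(str).tolist()
    cells = pd.read_csv(d / "cells.tsv", sep="\t")
    missing = [c for c in ("cell_id",) + ANNOTATION_COLUMNS if c not in cells.columns]
    if missing:
        raise ValidationError(f"cells.tsv missing column(s): {missing}")
    if counts.shape != (len(genes), len(cells)):
        raise ValidationError(
            f"matrix.mtx shape {counts.shape} does not match "
            f"genes.tsv x cells.tsv ({len(genes)} x {len(cells)})"
        )
    obs = cells.set_index("cell_id")[list(ANNOTATION_COLUMNS)]
    markers = {}
    if (d / "markers.json").exists():
        markers = json.loads((d / "markers.json").read_text())
    ref = SingleCellReference(
        counts=counts,
        gene_ids=genes,
        cell_ids=cells["cell_id"].astype(str).tolist(),
        obs=obs,
        marker_genes=markers,
    )
    ref, n_removed = ref.drop_zero_genes()
    if n_removed:
        logger.info("removed %d all-zero gene rows while reading %s", n_removed, d)
    return ref


# ---------------------------------------------------------------------------
# labeled CSV matrices


def read_matrix_csv(path, orientation: str = "genes_by_samples") -> pd.DataFrame:
    """Read a labeled numeric CSV matrix; validates rectangular numeric body."""
    try:
        df = pd.read_csv(path, index_col=0)
    except pd.errors.ParserError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    body = df.apply(pd.to_numeric, errors="coerce")
    bad = body.isna() & df.notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-numeric cell at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    if body.isna().to_numpy().any():
        raise ValidationError(f"{path}: missing values in matrix body")
    if orientation == "samples_by_types":
        if (body.to_numpy() < 0).any():
            raise ValidationError(f"{path}: negative entries in a fraction table")
    elif orientation != "genes_by_samples":
        raise ValidationError(f"unknown orientation {orientation!r}")
    body.index = body.index.astype(str)
    body.columns = body.columns.astype(str)
    return body


def write_matrix_csv(matrix: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(path, float_format=_FLOAT_FORMAT)


def write_fractions(fractions: FractionMatrix | pd.DataFrame, path) -> None:
    frame = fractions.values if isinstance(fractions, FractionMatrix) else fractions
    write_matrix_csv(frame, path)


def read_fractions(path, sum_constrained: bool | None = None) -> FractionMatrix:
    frame = read_matrix_csv(path, orientation="samples_by_types")
    if sum_constrained is None:
        sums = frame.sum(axis=1).to_numpy()
        sum_constrained = bool(np.allclose(sums, 1.0, atol=1e-9))
    return FractionMatrix(frame, sum_constrained=sum_constrained)


# ---------------------------------------------------------------------------
# reports


def _jsonable(obj):
    if isinstance(obj, pd.Series):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, pd.DataFrame):
        return json.loads(obj.to_json(orient="index"))
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return None if np.isnan(v) else v
    if isinstance(obj, (np.integer, int)):
        return int(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(report, path) -> None:
    """Serialize a report (dataclass with Series/DataFrame fields) to JSON."""
    if hasattr(report, "__dataclass_fields__"):
        payload = {k: _jsonable(getattr(report, k)) for k in report.__dataclass_fields__}
    else:
        payload = _jsonable(report)
    p = Path(path)
    p.parent.mkdir(parents=True, exist_ok=True)
    p.write_text(json.dumps(payload, indent=1, allow_nan=False))
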