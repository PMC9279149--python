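"""Readers and writers for the plain-text interchange formats.

Counts travel as matrix-market triplets plus one-column feature / barcode
tables (the 10x-style trio), intervals as BED, metadata as TSV, motif
membership as a two-column (motif_id, peak_id) TSV.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .core import (
    CellMetadata,
    CountsMatrix,
    GenomicIntervalSet,
    MotifAnnotation,
    SampleTable,
    ValidationError,
)


def read_counts(
    matrix_path,
    features_path,
    barcodes_path,
    *,
    feature_kind: str = "peak",
    sample_of: pd.Series | None = None,
) -> CountsMatrix:
    """Read a matrix-market counts matrix with feature/barcode sidecars.

    The barcode file may carry a second tab-separated column holding the
    sample id of each cell; otherwise ``sample_of`` must be given.
    """
    mat = scipy.io.mmread(str(matrix_path))
    features = _read_one_col(features_path)
    bc_table = pd.read_csv(barcodes_path, sep="\t", header=None, dtype=str)
    barcodes = bc_table[0].to_numpy(dtype=object) if len(bc_table) else np.array([], dtype=object)
    nf, nc = mat.shape
    if nf != len(features) or nc != len(barcodes):
        raise ValidationError(
            f"dimension mismatch: matrix {matrix_path} is {nf}x{nc} but "
            f"{features_path} has {len(features)} features and "
            f"{barcodes_path} has {len(barcodes)} barcodes"
        )
    if sample_of is None:
        if bc_table.shape[1] >= 2:
            sample_of = pd.Series(bc_table[1].to_numpy(), index=barcodes)
        else:
            sample_of = pd.Series("sample0", index=barcodes)
    data = sp.csr_matrix(mat)
    if data.nnz and not np.allclose(data.data, np.round(data.data)):
        raise ValidationError(f"non-integer entries in {matrix_path}")
    data = data.astype(np.int64)
    return CountsMatrix(
        values=data,
        feature_ids=features,
        feature_kind=feature_kind,
        barcodes=barcodes,
        sample_of=sample_of,
    )


def write_counts(counts: CountsMatrix, matrix_path, features_path, barcodes_path) -> None:
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(counts.values))
    _write_one_col(features_path, counts.feature_ids)
    bc = pd.DataFrame({0: counts.barcodes, 1: counts.sample_of.to_numpy()})
    bc.to_csv(barcodes_path, sep="\t", header=False, index=False)


def _read_one_col(path) -> np.ndarray:
    text = Path(path).read_text()
    lines = [ln.split("\t")[0] for ln in text.splitlines() if ln.strip()]
    return np.array(lines, dtype=object)


def _write_one_col(path, values) -> None:
    Path(path).write_text("".join(f"{v}\n" for v in values))


def read_intervals(bed_path) -> GenomicIntervalSet:
    """Read a 3+ column BED file (0-based half-open) into an interval set.

    A fourth column becomes the interval id; otherwise ids are synthesised
    as ``chrom:start-end``.
    """
    rows = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(f"{bed_path}:{lineno}: fewer than 3 BED columns")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValidationError(
                    f"{bed_path}:{lineno}: start >= end ({start} >= {end})"
                )
            iid = parts[3] if len(parts) >= 4 and parts[3] else f"{chrom}:{start}-{end}"
            rows.append((chrom, start, end, iid))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "id"])
    return GenomicIntervalSet(df)


def write_intervals(intervals: GenomicIntervalSet, bed_path) -> None:
    intervals.df.to_csv(bed_path, sep="\t", header=False, index=False)


def read_sample_table(path) -> SampleTable:
    return SampleTable(pd.read_csv(path, sep="\t", dtype={"sample_id": str, "donor_id": str}))


def write_sample_table(samples: SampleTable, path) -> None:
    samples.df.to_csv(path, sep="\t", index=False)


def read_cell_metadata(path) -> CellMetadata:
    return CellMetadata(pd.read_csv(path, sep="\t"))


def write_cell_metadata(cells: CellMetadata, path) -> None:
    cells.df.to_csv(path, sep="\t", index=False)


def read_motif_annotation(path, peak_ids: Sequence[str]) -> MotifAnnotation:
    """Read a (motif_id, peak_id) pair TSV into a binary membership matrix."""
    pairs = pd.read_csv(path, sep="\t", dtype=str)
    if not {"motif_id", "peak_id"} <= set(pairs.columns):
        raise ValidationError("motif table needs 'motif_id' and 'peak_id' columns")
    peak_ids = np.asarray(peak_ids, dtype=object)
    motif_ids = np.array(sorted(pairs["motif_id"].unique()), dtype=object)
    peak_lookup = pd.Index(peak_ids)
    motif_lookup = pd.Index(motif_ids)
    cols = peak_lookup.get_indexer(pairs["peak_id"])
    if (cols < 0).any():
        bad = pairs.loc[cols < 0, "peak_id"].unique()[:5]
        raise ValidationError(f"motif table references unknown peaks: {list(bad)}")
    rows = motif_lookup.get_indexer(pairs["motif_id"])
    mat = sp.coo_matrix(
        (np.ones(len(pairs)), (rows, cols)), shape=(len(motif_ids), len(peak_ids))
    ).tocsr()
    mat.data = np.minimum(mat.data, 1.0)
    return MotifAnnotation(membership=mat, motif_ids=motif_ids, peak_ids=peak_ids)


def write_motif_annotation(annotation: MotifAnnotation, path) -> None:
    coo = sp.coo_matrix(annotation.membership)
    pd.DataFrame(
        {
            "motif_id": annotation.motif_ids[coo.row],
            "peak_id": annotation.peak_ids[coo.col],
        }
    ).to_csv(path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
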