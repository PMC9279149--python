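"""Shared domain types for the polyp-to-CRC single-cell analysis pipeline.

All genomic coordinates are 0-based half-open (BED convention) throughout
the package; readers for 1-based dialects must convert at the boundary.
Raw counts are immutable value objects: normalised or transformed matrices
are always produced as new arrays, never written back into a
:class:`CountsMatrix`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

DISEASE_STATES = ("normal", "unaffected", "polyp", "CRC")
FEATURE_KINDS = ("peak", "gene", "tile")


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


def _check_unique(values, what: str) -> None:
    arr = np.asarray(values)
    if len(np.unique(arr)) != len(arr):
        series = pd.Series(arr)
        dups = series[series.duplicated()].unique()[:5]
        raise ValidationError(f"duplicate {what}: {list(dups)}")


@dataclass
class CountsMatrix:
    """Sparse non-negative integer feature-by-cell counts.

    Parameters
    ----------
    values
        ``(n_features, n_cells)`` sparse matrix of non-negative integers.
    feature_ids
        Unique feature identifiers (peaks, tiles or genes).
    feature_kind
        One of ``{"peak", "gene", "tile"}``.
    barcodes
        Unique cell identifiers.
    sample_of
        Mapping cell barcode -> sample id for every cell.
    """

    values: sp.csr_matrix
    feature_ids: np.ndarray
    feature_kind: str
    barcodes: np.ndarray
    sample_of: pd.Series

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values)
        self.feature_ids = np.asarray(self.feature_ids, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if not isinstance(self.sample_of, pd.Series):
            self.sample_of = pd.Series(self.sample_of)
        if self.feature_kind not in FEATURE_KINDS:
            raise ValidationError(
                f"feature_kind must be one of {FEATURE_KINDS}, got {self.feature_kind!r}"
            )
        nf, nc = self.values.shape
        if nf != len(self.feature_ids):
            raise ValidationError(
                f"matrix has {nf} rows but {len(self.feature_ids)} feature ids"
            )
        if nc != len(self.barcodes):
            raise ValidationError(
                f"matrix has {nc} columns but {len(self.barcodes)} barcodes"
            )
        if self.values.nnz and self.values.data.min() < 0:
            raise ValidationError("counts matrix contains negative entries")
        _check_unique(self.feature_ids, "feature ids")
        _check_unique(self.barcodes, "barcodes")
        missing = set(self.barcodes) - set(self.sample_of.index)
        if missing:
            raise ValidationError(
                f"{len(missing)} cells missing a sample assignment, e.g. {sorted(missing)[:3]}"
            )
        # align sample_of to the barcode order
        self.sample_of = self.sample_of.loc[self.barcodes]

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=0)).ravel()

    def feature_totals(self) -> np.ndarray:
        return np.asarray(self.values.sum(axis=1)).ravel()

    def feature_index(self, feature_ids: Sequence[str]) -> np.ndarray:
        """Positions of ``feature_ids`` in this matrix (error on unknown ids)."""
        lookup = pd.Index(self.feature_ids)
        idx = lookup.get_indexer(np.asarray(feature_ids, dtype=object))
        if (idx < 0).any():
            bad = np.asarray(feature_ids, dtype=object)[idx < 0][:5]
            raise ValidationError(f"unknown feature ids: {list(bad)}")
        return idx

    def subset_cells(self, mask_or_barcodes) -> "CountsMatrix":
        arr = np.asarray(mask_or_barcodes)
        if arr.dtype == bool:
            idx = np.flatnonzero(arr)
        else:
            lookup = pd.Index(self.barcodes)
            idx = lookup.get_indexer(arr)
            if (idx < 0).any():
                raise ValidationError("unknown barcodes in subset request")
        return CountsMatrix(
            values=self.values[:, idx],
            feature_ids=self.feature_ids,
            feature_kind=self.feature_kind,
            barcodes=self.barcodes[idx],
            sample_of=self.sample_of.iloc[idx],
        )

    def subset_features(self, feature_ids: Sequence[str]) -> "CountsMatrix":
        idx = self.feature_index(feature_ids)
        return CountsMatrix(
            values=self.values[idx],
            feature_ids=self.feature_ids[idx],
            feature_kind=self.feature_kind,
            barcodes=self.barcodes,
            sample_of=self.sample_of,
        )


@dataclass
class GenomicIntervalSet:
    """A set of named genomic intervals, 0-based half-open."""

    df: pd.DataFrame  # columns: chrom, start, end, id

    def __post_init__(self) -> None:
        required = ["chrom", "start", "end", "id"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"interval table missing columns {missing}")
        self.df = self.df[required].reset_index(drop=True)
        bad = self.df["start"] >= self.df["end"]
        if bad.any():
            row = self.df[bad].iloc[0]
            raise ValidationError(
                f"interval {row['id']} has start >= end ({row['start']} >= {row['end']})"
            )
        if (self.df["start"] < 0).any():
            raise ValidationError("negative interval start")
        _check_unique(self.df["id"].to_numpy(), "interval ids")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["id"].to_numpy(dtype=object)

    def sorted(self) -> "GenomicIntervalSet":
        out = self.df.sort_values(["chrom", "start"], kind="mergesort")
        return GenomicIntervalSet(out.reset_index(drop=True))


@dataclass
class SampleTable:
    """Per-sample metadata: donor, disease state and colon region."""

    df: pd.DataFrame  # columns: sample_id, donor_id, disease_state, region

    def __post_init__(self) -> None:
        required = ["sample_id", "donor_id", "disease_state", "region"]
        missing = [c for c in required if c not in self.df.columns]
        if missing:
            raise ValidationError(f"sample table missing columns {missing}")
        self.df = self.df[required].reset_index(drop=True)
        _check_unique(self.df["sample_id"].to_numpy(), "sample ids")
        bad = ~self.df["disease_state"].isin(DISEASE_STATES)
        if bad.any():
            raise ValidationError(
                f"unknown disease states: {sorted(self.df.loc[bad, 'disease_state'].unique())}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def sample_ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy(dtype=object)

    def state_of(self) -> pd.Series:
        return self.df.set_index("sample_id")["disease_state"]

    def samples_in_state(self, *states: str) -> list[str]:
        return list(self.df.loc[self.df["disease_state"].isin(states), "sample_id"])


@dataclass
class CellMetadata:
    """Per-cell QC covariates, sample assignment and (optional) labels."""

    df: pd.DataFrame

    REQUIRED = ["barcode", "sample_id"]
    NUMERIC = ["tss_enrichment", "n_fragments", "n_genes", "total_counts", "pct_mito"]

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.df.columns]
        if missing:
            raise ValidationError(f"cell metadata missing columns {missing}")
        self.df = self.df.reset_index(drop=True)
        _check_unique(self.df["barcode"].to_numpy(), "barcodes")
        if "pct_mito" in self.df.columns:
            pm = self.df["pct_mito"].dropna()
            if ((pm < 0) | (pm > 100)).any():
                raise ValidationError("pct_mito outside [0, 100]")
        for col in ("n_fragments", "n_genes", "total_counts"):
            if col in self.df.columns and (self.df[col].dropna() < 0).any():
                raise ValidationError(f"negative values in {col}")

    def __len__(self) -> int:
        return len(self.df)

    def labels(self) -> pd.Series:
        if "label" not in self.df.columns:
            raise ValidationError("cell metadata has no 'label' column")
        return self.df.set_index("barcode")["label"]


@dataclass
class MotifAnnotation:
    """Binary motif-by-peak membership matrix."""

    membership: sp.csr_matrix  # motifs x peaks, entries in {0, 1}
    motif_ids: np.ndarray
    peak_ids: np.ndarray

    def __post_init__(self) -> None:
        self.membership = sp.csr_matrix(self.membership)
        self.motif_ids = np.asarray(self.motif_ids, dtype=object)
        self.peak_ids = np.asarray(self.peak_ids, dtype=object)
        nm, npk = self.membership.shape
        if nm != len(self.motif_ids) or npk != len(self.peak_ids):
            raise ValidationError("motif membership dimensions do not match id lists")
        if self.membership.nnz:
            data = self.membership.data
            if not np.isin(data, [0, 1]).all():
                raise ValidationError("motif membership entries must be 0/1")
        _check_unique(self.motif_ids, "motif ids")
        _check_unique(self.peak_ids, "peak ids")

    def peaks_with_motif(self, motif_id: str) -> np.ndarray:
        i = int(np.flatnonzero(self.motif_ids == motif_id)[0])
        row = self.membership.getrow(i)
        return self.peak_ids[row.indices]
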