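"""Per-cell quality filters for ATAC-like and RNA-like cells.

Boundary semantics follow the published rules literally: "less than" /
"greater than" are strict, so kept sets use >= / <= at the printed values
(a cell with TSS enrichment exactly 4 or 5.0% mitochondrial RNA is kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .core import CellMetadata

logger = logging.getLogger(__name__)


@dataclass
class QCThresholds:
    """Cutoffs for the per-cell filters.

    ``tss_min`` and ``frag_min`` apply to ATAC cells, the rest to RNA
    cells.  ``frag_min`` is a per-sample map (sequencing depth differs
    between samples); samples absent from the map fall back to
    ``frag_min_default``.
    """

    tss_min: float = 4.0
    frag_min: Mapping[str, int] = field(default_factory=dict)
    frag_min_default: int = 3000
    genes_min: int = 400
    genes_max: int = 4000
    counts_max: int = 10_000
    mito_max: float = 5.0

    def __post_init__(self) -> None:
        if self.genes_min >= self.genes_max:
            raise ValueError("genes_min must be below genes_max")
        for name in ("tss_min", "frag_min_default", "genes_min", "counts_max", "mito_max"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def frag_cutoff(self, sample_id: str) -> int:
        if sample_id in self.frag_min:
            return int(self.frag_min[sample_id])
        if self.frag_min:  # map provided but sample missing
            logger.warning(
                "sample %s missing from fragment-cutoff map; using default %d",
                sample_id,
                self.frag_min_default,
            )
        return self.frag_min_default


@dataclass
class QCReport:
    """Per-sample breakdown of cells removed by each rule.

    ``per_rule`` counts cells failing each rule (a cell can fail several),
    ``removed`` counts unique removed cells, so per-rule counts sum to at
    least ``removed``.
    """

    per_rule: pd.DataFrame  # index sample_id, one column per rule
    removed: pd.Series
    kept: pd.Series

    def to_dict(self) -> dict:
        return {
            "per_rule": self.per_rule.to_dict(orient="index"),
            "removed": self.removed.to_dict(),
            "kept": self.kept.to_dict(),
        }


def exclude_clusters(
    cluster_of: pd.Series, exclude: "set[object] | list"
) -> np.ndarray:
    """Manual removal of suspect (e.g. incoherent-marker doublet) clusters.

    Cluster-level doublet judgement is not automated; callers pass the
    cluster ids to drop and get back the surviving barcodes.
    """
    cluster_of = pd.Series(cluster_of)
    exclude = set(exclude)
    unknown = exclude - set(cluster_of.unique())
    if unknown:
        logger.warning("exclude list names unknown clusters: %s", sorted(unknown))
    keep = ~cluster_of.isin(exclude)
    return cluster_of.index[keep].to_numpy(dtype=object)


def _build_report(df: pd.DataFrame, fail_cols: dict[str, pd.Series]) -> QCReport:
    fails = pd.DataFrame(fail_cols)
    fails["sample_id"] = df["sample_id"].to_numpy()
    grouped = fails.groupby("sample_id")
    per_rule = grouped[[c for c in fail_cols]].sum().astype(int)
    any_fail = fails[[c for c in fail_cols]].any(axis=1)
    removed = any_fail.groupby(fails["sample_id"]).sum().astype(int)
    kept = (~any_fail).groupby(fails["sample_id"]).sum().astype(int)
    return QCReport(per_rule=per_rule, removed=removed, kept=kept)


def filter_atac_cells(
    meta: CellMetadata, thresholds: QCThresholds | None = None
) -> tuple[np.ndarray, QCReport]:
    """Keep ATAC cells with TSS enrichment >= tss_min and enough fragments.

    Returns the kept barcodes (input order preserved) and a per-sample
    report of removals per rule.
    """
    thresholds = thresholds or QCThresholds()
    df = meta.df
    for col in ("tss_enrichment", "n_fragments"):
        if col not in df.columns:
            raise ValueError(f"ATAC QC requires the '{col}' column")
    cutoffs = df["sample_id"].map(lambda s: thresholds.frag_cutoff(s))
    fail_tss = df["tss_enrichment"] < thresholds.tss_min
    fail_frag = df["n_fragments"] < cutoffs
    report = _build_report(df, {"tss": fail_tss, "fragments": fail_frag})
    kept = df.loc[~(fail_tss | fail_frag), "barcode"].to_numpy(dtype=object)
    return kept, report


def filter_rna_cells(
    meta: CellMetadata, thresholds: QCThresholds | None = None
) -> tuple[np.ndarray, QCReport]:
    """Keep RNA cells inside the gene-count, depth and mito-fraction bounds."""
    thresholds = thresholds or QCThresholds()
    df = meta.df
    for col in ("n_genes", "total_counts", "pct_mito"):
        if col not in df.columns:
            raise ValueError(f"RNA QC requires the '{col}' column")
    fail_genes_low = df["n_genes"] < thresholds.genes_min
    fail_genes_high = df["n_genes"] > thresholds.genes_max
    fail_counts = df["total_counts"] > thresholds.counts_max
    fail_mito = df["pct_mito"] > thresholds.mito_max
    report = _build_report(
        df,
        {
            "genes_low": fail_genes_low,
            "genes_high": fail_genes_high,
            "counts": fail_counts,
            "mito": fail_mito,
        },
    )
    keep = ~(fail_genes_low | fail_genes_high | fail_counts | fail_mito)
    return df.loc[keep, "barcode"].to_numpy(dtype=object), report
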