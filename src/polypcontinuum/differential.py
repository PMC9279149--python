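"""Per-sample differential features of stem-like cells against a background.

Each diseased sample's target cells (stem-like by default) are compared
with a pooled background population (normal or unaffected stem cells) one
feature at a time: depth-normalised values enter a rank-sum test (peaks)
or a two-part hurdle test (genes), fold changes are computed on
pseudocounted mean normalised values, and Benjamini-Hochberg adjustment is
applied within each sample's table.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import CountsMatrix, SampleTable, ValidationError
from .stats import bh_fdr, hurdle_test, log2_fold_change, rank_sum_rows

logger = logging.getLogger(__name__)

TABLE_COLUMNS = ["sample_id", "feature_id", "log2fc", "p", "fdr", "n_target", "n_background"]


@dataclass
class DifferentialParams:
    """Shared knobs for per-sample differential testing.

    ``min_cells`` mirrors the published inclusion rules (250 stem cells
    for ATAC, 100 cells for RNA); ``max_cells_per_group`` caps each group
    by seeded subsampling (300 for RNA in the original analysis).
    """

    min_cells: int = 250
    max_cells_per_group: int | None = None
    test: str = "wilcoxon"  # or "hurdle"
    pseudocount: float = 1.0
    binarize: bool = False
    seed: int = 0


def depth_normalize(values: sp.spmatrix, target: float | None = None) -> sp.csr_matrix:
    """Scale each cell (column) to the median cell depth (or ``target``)."""
    X = sp.csr_matrix(values, dtype=float)
    totals = np.asarray(X.sum(axis=0)).ravel()
    if target is None:
        positive = totals[totals > 0]
        target = float(np.median(positive)) if positive.size else 1.0
    scale = np.divide(target, totals, out=np.zeros_like(totals), where=totals > 0)
    return sp.csr_matrix(X @ sp.diags(scale))


def _group_matrix(
    counts: CountsMatrix, barcodes: np.ndarray, max_cells: int | None, rng: np.random.Generator
) -> np.ndarray:
    idx = pd.Index(counts.barcodes).get_indexer(barcodes)
    if max_cells is not None and len(idx) > max_cells:
        idx = rng.choice(idx, size=max_cells, replace=False)
        idx = np.sort(idx)
    return idx


def differential_features(
    target: np.ndarray,
    background: np.ndarray,
    feature_ids: np.ndarray,
    *,
    test: str = "wilcoxon",
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Feature-wise test of two dense (features x cells) value matrices."""
    if test == "wilcoxon":
        p = rank_sum_rows(target, background)
    elif test == "hurdle":
        p = np.array([hurdle_test(target[i], background[i]) for i in range(target.shape[0])])
    else:
        raise ValueError(f"unknown test {test!r}")
    lfc = log2_fold_change(target.mean(axis=1), background.mean(axis=1), pseudocount)
    return pd.DataFrame(
        {
            "feature_id": feature_ids,
            "log2fc": lfc,
            "p": p,
            "fdr": bh_fdr(p),
            "n_target": target.shape[1],
            "n_background": background.shape[1],
        }
    )


def merge_unaffected_samples(samples: SampleTable) -> pd.Series:
    """Map sample id -> differential unit, merging unaffected samples that
    share donor and colon region (pooling their scarce stem cells)."""
    df = samples.df
    unit = df["sample_id"].copy()
    unaffected = df["disease_state"] == "unaffected"
    unit[unaffected] = (
        df.loc[unaffected, "donor_id"].astype(str)
        + "_"
        + df.loc[unaffected, "region"].astype(str)
    )
    return pd.Series(unit.to_numpy(), index=df["sample_id"].to_numpy())


def per_sample_differentials(
    counts: CountsMatrix,
    labels: pd.Series,
    samples: SampleTable,
    *,
    target_type: str = "stem",
    background_states: Sequence[str] = ("normal",),
    params: DifferentialParams | None = None,
    merge_unaffected: bool = True,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Per-sample differential table of target-type cells vs. the background.

    The background pools ``target_type`` cells from all samples in
    ``background_states``.  Unaffected samples sharing donor and region are
    merged into one unit before the minimum-cell rule is applied.  Returns
    ``(tables, excluded_units)`` where tables map unit id -> DataFrame with
    columns {feature_id, log2fc, p, fdr, n_target, n_background} covering
    every feature.
    """
    params = params or DifferentialParams()
    rng = np.random.default_rng(params.seed)
    labels = pd.Series(labels)
    state_of = samples.state_of()

    cell_samples = counts.sample_of
    cell_labels = labels.loc[counts.barcodes].to_numpy()
    is_target_type = cell_labels == target_type

    bg_samples = set(samples.samples_in_state(*background_states))
    if not bg_samples:
        raise ValidationError(f"no samples in background states {background_states}")
    bg_mask = is_target_type & cell_samples.isin(bg_samples).to_numpy()
    if bg_mask.sum() == 0:
        raise ValidationError("background population is empty")

    units = (
        merge_unaffected_samples(samples)
        if merge_unaffected
        else pd.Series(samples.sample_ids, index=samples.sample_ids)
    )
    cell_units = cell_samples.map(units)

    X = counts.values
    if params.binarize:
        X = X.copy().astype(float)
        X.data = np.ones_like(X.data)
    norm = depth_normalize(X)

    bg_idx = np.flatnonzero(bg_mask)
    if params.max_cells_per_group is not None and len(bg_idx) > params.max_cells_per_group:
        bg_idx = np.sort(rng.choice(bg_idx, size=params.max_cells_per_group, replace=False))
    B = np.asarray(norm[:, bg_idx].todense())

    tables: dict[str, pd.DataFrame] = {}
    excluded: list[str] = []
    fg_units = sorted(
        units[~samples.df.set_index("sample_id")["disease_state"].isin(background_states)].unique()
    )
    for unit in fg_units:
        tgt_mask = is_target_type & (cell_units == unit).to_numpy()
        n_cells = int(tgt_mask.sum())
        if n_cells < params.min_cells:
            logger.info(
                "excluding %s: %d %s cells < min_cells=%d",
                unit,
                n_cells,
                target_type,
                params.min_cells,
            )
            excluded.append(unit)
            continue
        tgt_idx = np.flatnonzero(tgt_mask)
        if params.max_cells_per_group is not None and len(tgt_idx) > params.max_cells_per_group:
            tgt_idx = np.sort(
                rng.choice(tgt_idx, size=params.max_cells_per_group, replace=False)
            )
        T = np.asarray(norm[:, tgt_idx].todense())
        table = differential_features(
            T, B, counts.feature_ids, test=params.test, pseudocount=params.pseudocount
        )
        table.insert(0, "sample_id", unit)
        tables[unit] = table
    return tables, excluded


def select_recurrent_features(
    tables: Mapping[str, pd.DataFrame],
    fdr_max: float = 0.05,
    lfc_min: float = 1.5,
    min_samples: int = 2,
) -> np.ndarray:
    """Features significant (fdr <= fdr_max, |log2FC| >= lfc_min) in at
    least ``min_samples`` distinct samples."""
    if not tables:
        raise ValidationError("no differential tables provided")
    hits: dict = {}
    for sample_id, table in tables.items():
        sig = table[(table["fdr"] <= fdr_max) & (table["log2fc"].abs() >= lfc_min)]
        for f in sig["feature_id"]:
            hits.setdefault(f, set()).add(sample_id)
    selected = [f for f, s in hits.items() if len(s) >= min_samples]
    # preserve the feature order of the first table
    first = next(iter(tables.values()))
    order = {f: i for i, f in enumerate(first["feature_id"])}
    return np.array(sorted(selected, key=lambda f: order.get(f, len(order))), dtype=object)


def marker_features(
    counts: CountsMatrix,
    labels: pd.Series,
    target_type: str,
    *,
    fdr_max: float = 0.1,
    lfc_min: float = 0.5,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """One-vs-rest markers of ``target_type`` (up-regulated only)."""
    labels = pd.Series(labels).loc[counts.barcodes].to_numpy()
    if target_type not in labels:
        raise ValidationError(f"no cells labelled {target_type!r}")
    if len(np.unique(labels)) < 2:
        raise ValidationError("need at least two cell types for markers")
    norm = depth_normalize(counts.values)
    tgt = np.asarray(norm[:, labels == target_type].todense())
    rest = np.asarray(norm[:, labels != target_type].todense())
    table = differential_features(
        tgt, rest, counts.feature_ids, test="wilcoxon", pseudocount=pseudocount
    )
    markers = table[(table["fdr"] <= fdr_max) & (table["log2fc"] >= lfc_min)]
    return markers.reset_index(drop=True)
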