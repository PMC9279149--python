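"""Methylation-accessibility concordance analysis.

Differentially methylated array probes (rank-sum p and mean beta-value
difference against printed cutoffs) are overlapped with the accessibility
peak set; probe-bearing peaks are cross-tabulated by the direction of
their accessibility program (up / down / non-differential) against probe
class (hypo / hyper / none), and a sign test quantifies the residual
directional shift among non-differential peaks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .core import GenomicIntervalSet, ValidationError
from .programs import ProgramClusters
from .stats import rank_sum_rows, rank_sum_test, sign_test

logger = logging.getLogger(__name__)

PROBE_CLASSES = ("hypo", "hyper", "none")


def differential_probes(
    beta_normal: pd.DataFrame,
    beta_tumor: pd.DataFrame,
    p_cut: float = 1e-5,
    delta_cut: float = 0.25,
) -> pd.DataFrame:
    """Call differentially methylated probes between two sample groups.

    Probes (rows) are tested across samples (columns) with the two-sided
    rank-sum test; class ``hyper`` requires p <= p_cut and a tumor-minus-
    normal mean beta difference >= +delta_cut, ``hypo`` the mirror image.
    Probes with a group entirely missing are classed ``none`` and flagged.
    """
    if not beta_normal.index.equals(beta_tumor.index):
        raise ValidationError("normal and tumor beta tables must share probes in order")
    for name, df in (("normal", beta_normal), ("tumor", beta_tumor)):
        vals = df.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < 0 or finite.max() > 1):
            raise ValidationError(f"{name} beta values outside [0, 1]")
    if beta_normal.shape[1] < 2 or beta_tumor.shape[1] < 2:
        raise ValidationError("need at least 2 samples per group")

    N = beta_normal.to_numpy(dtype=float)
    T = beta_tumor.to_numpy(dtype=float)
    n_probes = N.shape[0]
    p = np.ones(n_probes)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN group rows
        mean_n = np.nanmean(np.where(np.isfinite(N), N, np.nan), axis=1)
        mean_t = np.nanmean(np.where(np.isfinite(T), T, np.nan), axis=1)
    complete = np.isfinite(N).all(axis=1) & np.isfinite(T).all(axis=1)
    if complete.any():
        p[complete] = rank_sum_rows(T[complete], N[complete])
    flagged = np.zeros(n_probes, dtype=bool)
    for i in np.flatnonzero(~complete):
        ti, ni = T[i][np.isfinite(T[i])], N[i][np.isfinite(N[i])]
        if ti.size == 0 or ni.size == 0:
            flagged[i] = True
            p[i] = np.nan
        else:
            p[i] = rank_sum_test(ti, ni)
    delta = mean_t - mean_n
    cls = np.full(n_probes, "none", dtype=object)
    sig = ~flagged & np.isfinite(p) & (p <= p_cut)
    cls[sig & (delta >= delta_cut)] = "hyper"
    cls[sig & (delta <= -delta_cut)] = "hypo"
    return pd.DataFrame(
        {
            "probe_id": beta_normal.index.to_numpy(dtype=object),
            "beta_normal": mean_n,
            "beta_tumor": mean_t,
            "delta_beta": delta,
            "p": p,
            "class": cls,
            "missing_group": flagged,
        }
    )


def overlap_probes_peaks(
    probes: pd.DataFrame,  # columns: probe_id, chrom, position (+ class optional)
    peaks: GenomicIntervalSet,
) -> pd.DataFrame:
    """Map probes to the peaks containing them (half-open intervals).

    A probe at position p overlaps peak [s, e) iff s <= p < e.  Returns a
    long table (peak_id, probe_id[, class]); a peak may appear once per
    overlapping probe.
    """
    required = {"probe_id", "chrom", "position"}
    if not required <= set(probes.columns):
        raise ValidationError(f"probe table needs columns {sorted(required)}")
    trees: dict[str, IntervalTree] = {}
    for chrom, sub in peaks.df.groupby("chrom"):
        trees[chrom] = IntervalTree.from_tuples(
            zip(sub["start"], sub["end"], sub["id"])
        )
    rows = []
    has_class = "class" in probes.columns
    classes = probes["class"].to_numpy() if has_class else None
    for i, (chrom, pos, pid) in enumerate(
        zip(probes["chrom"], probes["position"], probes["probe_id"])
    ):
        tree = trees.get(chrom)
        if tree is None:
            continue
        for iv in tree.at(pos):
            rows.append((iv.data, pid, classes[i]) if has_class else (iv.data, pid))
    cols = ["peak_id", "probe_id"] + (["class"] if has_class else [])
    return pd.DataFrame(rows, columns=cols)


@dataclass
class ConcordanceTable:
    """3x3 cross-tabulation of peak accessibility direction vs probe class.

    A peak overlapping both hyper and hypo probes is counted in both probe
    columns and listed in ``mixed_peaks``; ``counts`` rows are peak
    directions (up/down/nondiff), columns probe classes (hypo/hyper/none).
    """

    counts: pd.DataFrame
    mixed_peaks: np.ndarray
    peak_direction: pd.Series  # peak -> up/down/nondiff for probe-bearing peaks

    def concordant_fraction(self) -> float:
        """Fraction of differential probe-overlapping peaks in concordant
        cells (up x hypo, down x hyper), among differential-class cells."""
        c = self.counts
        concord = c.loc["up", "hypo"] + c.loc["down", "hyper"]
        discord = c.loc["up", "hyper"] + c.loc["down", "hypo"]
        total = concord + discord
        return float(concord / total) if total else float("nan")


def concordance_table(
    overlaps: pd.DataFrame,  # columns: peak_id, probe_id, class
    programs: ProgramClusters | None,
    up_clusters: Sequence[int],
    down_clusters: Sequence[int],
) -> ConcordanceTable:
    """Cross-tabulate probe-bearing peaks by program direction and probe class."""
    up_clusters, down_clusters = set(up_clusters), set(down_clusters)
    if up_clusters & down_clusters:
        raise ValidationError("up and down cluster sets overlap")
    if programs is not None:
        up_feats = {
            f for f, c in programs.assignment.items() if c in up_clusters
        }
        down_feats = {
            f for f, c in programs.assignment.items() if c in down_clusters
        }
    else:
        up_feats, down_feats = set(), set()
    table = pd.DataFrame(
        0, index=["up", "down", "nondiff"], columns=["hypo", "hyper", "none"]
    )
    mixed = []
    directions = {}
    for peak_id, sub in overlaps.groupby("peak_id"):
        direction = (
            "up" if peak_id in up_feats else "down" if peak_id in down_feats else "nondiff"
        )
        directions[peak_id] = direction
        classes = set(sub["class"])
        has_hyper = "hyper" in classes
        has_hypo = "hypo" in classes
        if has_hyper and has_hypo:
            mixed.append(peak_id)
        if has_hypo:
            table.loc[direction, "hypo"] += 1
        if has_hyper:
            table.loc[direction, "hyper"] += 1
        if not has_hyper and not has_hypo:
            table.loc[direction, "none"] += 1
    return ConcordanceTable(
        counts=table,
        mixed_peaks=np.array(mixed, dtype=object),
        peak_direction=pd.Series(directions, dtype=object),
    )


def nondiff_sign_test(
    mean_lfc: pd.Series, concordance: ConcordanceTable, overlaps: pd.DataFrame, probe_class: str
) -> tuple[float, float]:
    """Sign test on mean log2FC of non-differential peaks overlapping
    probes of ``probe_class``.  Returns (p, fraction_negative)."""
    peaks_with_class = set(overlaps.loc[overlaps["class"] == probe_class, "peak_id"])
    nondiff = [
        pk
        for pk, d in concordance.peak_direction.items()
        if d == "nondiff" and pk in peaks_with_class and pk in mean_lfc.index
    ]
    if not nondiff:
        return 1.0, float("nan")
    return sign_test(mean_lfc.loc[nondiff].to_numpy())


def accumulation_along_continuum(
    tables: Mapping[str, pd.DataFrame],
    overlaps: pd.DataFrame,
    positions: pd.Series,
    *,
    fdr_max: float = 0.05,
    lfc_min: float = 1.5,
) -> pd.DataFrame:
    """Per-sample counts of significant peaks overlapping hyper/hypo probes,
    ordered by continuum position."""
    hyper_peaks = set(overlaps.loc[overlaps["class"] == "hyper", "peak_id"])
    hypo_peaks = set(overlaps.loc[overlaps["class"] == "hypo", "peak_id"])
    rows = []
    for sample_id, table in tables.items():
        if sample_id not in positions.index:
            logger.warning("sample %s has no continuum position; skipped", sample_id)
            continue
        sig = table[(table["fdr"] <= fdr_max) & (table["log2fc"].abs() >= lfc_min)]
        sig_feats = set(sig["feature_id"])
        rows.append(
            (
                sample_id,
                float(positions[sample_id]),
                len(sig_feats & hyper_peaks),
                len(sig_feats & hypo_peaks),
            )
        )
    out = pd.DataFrame(rows, columns=["sample_id", "position", "n_hyper", "n_hypo"])
    return out.sort_values("position").reset_index(drop=True)
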