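"""Stage-specific feature programs, motif enrichment and activity scores.

Differential features are k-means clustered (by their per-sample log2FC
profiles) into programs that switch at distinct stages of transformation;
each program's peaks are tested for transcription-factor motif enrichment
with an upper-tail hypergeometric test.  Per-cell motif deviation z-scores
follow the chromVAR idea — excess accessibility in a motif's peaks over a
depth x peak-popularity expectation, z-scored against accessibility-matched
background peak sets — and module scores quantify stemness (or any gene
set) against abundance-matched control features.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import t as t_dist

from .core import CountsMatrix, GenomicIntervalSet, MotifAnnotation, ValidationError
from .stats import bh_fdr, hypergeometric_upper_tail

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------- k-means


@dataclass
class ProgramClusters:
    assignment: pd.Series  # feature -> cluster id in 1..k
    k: int
    centroids: np.ndarray
    seed: int
    inertia_history: np.ndarray

    def members(self, cluster_id: int) -> np.ndarray:
        return self.assignment.index[self.assignment == cluster_id].to_numpy(dtype=object)


def _kmeanspp_init(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    n = X.shape[0]
    centers = np.empty((k, X.shape[1]))
    centers[0] = X[rng.integers(n)]
    d2 = ((X - centers[0]) ** 2).sum(axis=1)
    for j in range(1, k):
        probs = d2 / d2.sum() if d2.sum() > 0 else np.full(n, 1.0 / n)
        centers[j] = X[rng.choice(n, p=probs)]
        d2 = np.minimum(d2, ((X - centers[j]) ** 2).sum(axis=1))
    return centers


def kmeans_cluster(
    lfc_matrix: pd.DataFrame,
    k: int = 10,
    max_iter: int = 500,
    seed: int = 0,
    n_init: int = 10,
) -> ProgramClusters:
    """Lloyd's k-means with k-means++ init on feature log2FC profiles.

    Rows are features, columns samples.  Empty clusters are re-seeded from
    the point farthest from its centroid; ``n_init`` restarts are run and
    the solution with the lowest within-cluster sum of squares kept.
    Deterministic given ``seed``.
    """
    X = np.asarray(lfc_matrix, dtype=float)
    n = X.shape[0]
    if k > n:
        raise ValidationError(f"k={k} exceeds the {n} features")
    best = None
    for restart in range(max(n_init, 1)):
        result = _kmeans_once(X, k, max_iter, np.random.default_rng((seed, restart)))
        if best is None or result[2][-1] < best[2][-1]:
            best = result
    assign, centers, history = best
    index = (
        lfc_matrix.index if isinstance(lfc_matrix, pd.DataFrame) else pd.RangeIndex(n)
    )
    return ProgramClusters(
        assignment=pd.Series(assign + 1, index=index, name="cluster"),
        k=k,
        centroids=centers,
        seed=seed,
        inertia_history=np.asarray(history),
    )


def _kmeans_once(X: np.ndarray, k: int, max_iter: int, rng: np.random.Generator):
    n = X.shape[0]
    centers = _kmeanspp_init(X, k, rng)
    assign = np.zeros(n, dtype=int)
    history = []
    for _ in range(max_iter):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_assign = d2.argmin(axis=1)
        point_d2 = d2[np.arange(n), new_assign]
        for j in range(k):  # re-seed empty clusters from the farthest point
            if not (new_assign == j).any():
                far = point_d2.argmax()
                centers[j] = X[far]
                new_assign[far] = j
                point_d2[far] = 0.0
        history.append(float(point_d2.sum()))
        if (new_assign == assign).all() and len(history) > 1:
            break
        assign = new_assign
        for j in range(k):
            centers[j] = X[assign == j].mean(axis=0)
    return assign, centers, history


# ------------------------------------------------------------------- enrichment


def hypergeometric_enrichment(
    cluster_features: Sequence[str],
    annotation: MotifAnnotation,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Upper-tail hypergeometric motif enrichment within one peak cluster.

    Universe size N = peaks entering the clustering, K = universe peaks
    carrying the motif, n = cluster size, overlap = cluster peaks carrying
    the motif; p = P(X >= overlap).  BH adjustment across motifs.
    """
    cluster_features = np.asarray(cluster_features, dtype=object)
    universe = np.asarray(universe, dtype=object)
    if len(cluster_features) == 0:
        return pd.DataFrame(
            columns=["motif_id", "overlap", "cluster_size", "motif_total", "universe", "p", "fdr"]
        )
    if not set(cluster_features) <= set(universe):
        raise ValidationError("cluster features must be a subset of the universe")
    peak_lookup = pd.Index(annotation.peak_ids)
    uni_idx = peak_lookup.get_indexer(universe)
    if (uni_idx < 0).any():
        raise ValidationError("annotation does not cover the universe")
    clu_idx = peak_lookup.get_indexer(cluster_features)
    M = sp.csc_matrix(annotation.membership)
    in_universe = np.asarray(M[:, uni_idx].sum(axis=1)).ravel().astype(int)
    in_cluster = np.asarray(M[:, clu_idx].sum(axis=1)).ravel().astype(int)
    N, n = len(universe), len(cluster_features)
    pvals = np.array(
        [
            hypergeometric_upper_tail(int(o), N, int(K), n)
            for o, K in zip(in_cluster, in_universe)
        ]
    )
    out = pd.DataFrame(
        {
            "motif_id": annotation.motif_ids,
            "overlap": in_cluster,
            "cluster_size": n,
            "motif_total": in_universe,
            "universe": N,
            "p": pvals,
            "fdr": bh_fdr(pvals),
        }
    )
    return out.sort_values("p", kind="mergesort").reset_index(drop=True)


def enrichment_by_cluster(
    clusters: ProgramClusters, annotation: MotifAnnotation
) -> dict[int, pd.DataFrame]:
    """Motif enrichment for every program cluster; the universe is the set
    of clustered features."""
    universe = clusters.assignment.index.to_numpy(dtype=object)
    return {
        cid: hypergeometric_enrichment(clusters.members(cid), annotation, universe)
        for cid in range(1, clusters.k + 1)
    }


# ------------------------------------------------------------ motif deviations


@dataclass
class DeviationScores:
    z: pd.DataFrame  # motifs x cells
    raw: pd.DataFrame
    n_background: int
    seed: int


def motif_deviation(
    counts: CountsMatrix,
    annotation: MotifAnnotation,
    n_background: int = 50,
    n_bins: int = 50,
    seed: int = 0,
) -> DeviationScores:
    """chromVAR-style motif deviation z-scores.

    Raw deviation per motif and cell = (observed counts in motif peaks −
    expected under a cell-depth x peak-popularity model) / expected.  The
    z-score standardises against ``n_background`` random peak sets matched
    on total accessibility (equal-frequency bins).  Motifs with no peaks
    get NaN.
    """
    if not np.array_equal(counts.feature_ids, annotation.peak_ids):
        raise ValidationError("counts and annotation must cover the same peaks in order")
    X = sp.csr_matrix(counts.values, dtype=float)
    popularity = np.asarray(X.sum(axis=1)).ravel()
    total = popularity.sum()
    if total == 0:
        raise ValidationError("empty counts matrix")
    p = popularity / total
    depth = np.asarray(X.sum(axis=0)).ravel()
    M = sp.csr_matrix(annotation.membership, dtype=float)

    def _raw_dev(member: sp.csr_matrix) -> np.ndarray:
        observed = (member @ X).toarray()  # motifs x cells
        expected = np.outer(np.asarray(member @ p).ravel(), depth)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(expected > 0, (observed - expected) / expected, np.nan)

    raw = _raw_dev(M)

    # accessibility-matched background peak sets
    order = np.argsort(popularity, kind="mergesort")
    n_peaks = len(popularity)
    bin_of = np.empty(n_peaks, dtype=int)
    bin_of[order] = np.minimum(np.arange(n_peaks) * n_bins // n_peaks, n_bins - 1)
    peaks_in_bin = [np.flatnonzero(bin_of == b) for b in range(n_bins)]
    rng = np.random.default_rng(seed)
    Mcsr = M.tocsr()
    bg_mean = np.zeros_like(raw)
    bg_m2 = np.zeros_like(raw)
    for _ in range(n_background):
        rows, cols = [], []
        for mi in range(M.shape[0]):
            motif_peaks = Mcsr.indices[Mcsr.indptr[mi] : Mcsr.indptr[mi + 1]]
            for pk in motif_peaks:
                pool = peaks_in_bin[bin_of[pk]]
                cols.append(pool[rng.integers(len(pool))])
                rows.append(mi)
        B = sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=M.shape
        )
        B.data = np.minimum(B.data, 1.0)
        dev_b = _raw_dev(B)
        bg_mean += dev_b
        bg_m2 += dev_b**2
    bg_mean /= n_background
    bg_sd = np.sqrt(np.maximum(bg_m2 / n_background - bg_mean**2, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(bg_sd > 0, (raw - bg_mean) / bg_sd, np.nan)
    empty_motifs = np.asarray(M.sum(axis=1)).ravel() == 0
    z[empty_motifs] = np.nan
    raw[empty_motifs] = np.nan
    return DeviationScores(
        z=pd.DataFrame(z, index=annotation.motif_ids, columns=counts.barcodes),
        raw=pd.DataFrame(raw, index=annotation.motif_ids, columns=counts.barcodes),
        n_background=n_background,
        seed=seed,
    )


def motif_expression_correlation(
    deviations: DeviationScores,
    expression: np.ndarray | sp.spmatrix,
    gene_ids: Sequence[str],
    motif_to_gene: Mapping[str, str],
) -> pd.DataFrame:
    """Pearson correlation between each motif's deviation z-scores and its
    transcription factor's expression across cells.

    ``expression`` is a (genes x cells) matrix aligned with the deviation
    columns; ``motif_to_gene`` maps motif id -> TF gene id.  Motifs whose
    TF is absent, or with constant values, get NaN.
    """
    gene_lookup = pd.Index(np.asarray(gene_ids, dtype=object))
    E = np.asarray(expression.todense() if sp.issparse(expression) else expression)
    rows = []
    for motif_id, gene_id in motif_to_gene.items():
        if motif_id not in deviations.z.index:
            continue
        z = deviations.z.loc[motif_id].to_numpy(dtype=float)
        gi = gene_lookup.get_indexer([gene_id])[0]
        if gi < 0:
            rows.append((motif_id, gene_id, np.nan))
            continue
        expr = E[gi]
        ok = np.isfinite(z)
        if ok.sum() < 3 or z[ok].std() == 0 or expr[ok].std() == 0:
            rows.append((motif_id, gene_id, np.nan))
            continue
        rows.append((motif_id, gene_id, float(np.corrcoef(z[ok], expr[ok])[0, 1])))
    return pd.DataFrame(rows, columns=["motif_id", "gene_id", "r"])


# ------------------------------------------------------------ peak-gene links


def peak_gene_links(
    peak_counts: CountsMatrix,
    gene_counts: CountsMatrix,
    peaks: GenomicIntervalSet,
    gene_positions: pd.DataFrame,  # columns: gene_id, chrom, tss
    *,
    window: int = 250_000,
    corr_min: float = 0.45,
    fdr_max: float = 0.05,
    n_aggregates: int = 100,
    embedding: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlate peak accessibility with proximal gene expression.

    Cells (matched between assays) are grouped into ``n_aggregates``
    pseudo-bulk neighbourhoods (k-means on ``embedding``, or on a PCA of
    log-normalised expression when none is given); peak-gene pairs with
    TSS within ``window`` of the peak are tested by Pearson correlation of
    the log-normalised aggregate profiles, with BH adjustment over all
    tested pairs.

    Returns ``(links, tested)``: the pairs passing |r| >= corr_min and
    fdr <= fdr_max, and the full table of tested pairs.
    """
    if not np.array_equal(peak_counts.barcodes, gene_counts.barcodes):
        raise ValidationError("peak and gene matrices must share cells in order")
    n_cells = peak_counts.n_cells
    n_aggregates = min(n_aggregates, n_cells)

    if embedding is None:
        from sklearn.decomposition import PCA

        expr = _log_norm_dense(gene_counts.values)
        n_comp = min(20, min(expr.shape) - 1)
        embedding = PCA(n_components=n_comp, random_state=seed).fit_transform(expr.T)
    from sklearn.cluster import KMeans

    groups = KMeans(n_clusters=n_aggregates, n_init=3, random_state=seed).fit_predict(
        embedding
    )

    def _aggregate(values: sp.spmatrix) -> np.ndarray:
        X = sp.csr_matrix(values, dtype=float)
        agg = np.column_stack(
            [np.asarray(X[:, groups == g].sum(axis=1)).ravel() for g in np.unique(groups)]
        )
        lib = agg.sum(axis=0)
        lib = np.where(lib > 0, lib, 1.0)
        return np.log1p(agg / lib * 1e4)

    peak_prof = _aggregate(peak_counts.values)
    gene_prof = _aggregate(gene_counts.values)

    # candidate pairs within the window, per chromosome
    pdf = peaks.df.set_index("id").loc[peak_counts.feature_ids].reset_index()
    gdf = gene_positions.copy()
    pairs: list[tuple[int, int, int]] = []
    gene_row = {g: i for i, g in enumerate(gene_counts.feature_ids)}
    for chrom, sub in pdf.groupby("chrom"):
        genes_here = gdf[gdf["chrom"] == chrom]
        if genes_here.empty:
            continue
        tss = genes_here["tss"].to_numpy()
        tss_order = np.argsort(tss)
        tss_sorted = tss[tss_order]
        gidx = genes_here["gene_id"].to_numpy()[tss_order]
        for pi, start, end in zip(sub.index, sub["start"], sub["end"]):
            lo = np.searchsorted(tss_sorted, start - window)
            hi = np.searchsorted(tss_sorted, end + window, side="right")
            for j in range(lo, hi):
                g = gidx[j]
                if g in gene_row:
                    dist = 0 if start <= tss_sorted[j] < end else int(
                        min(abs(tss_sorted[j] - start), abs(tss_sorted[j] - (end - 1)))
                    )
                    pairs.append((pi, gene_row[g], dist))
    if not pairs:
        empty = pd.DataFrame(columns=["peak_id", "gene_id", "distance", "r", "p", "fdr"])
        return empty, empty.drop(columns="fdr")

    n_agg = peak_prof.shape[1]
    rows = []
    for pi, gi, dist in pairs:
        x, y = peak_prof[pi], gene_prof[gi]
        if x.std() == 0 or y.std() == 0:
            r, p = 0.0, 1.0
        else:
            r = float(np.corrcoef(x, y)[0, 1])
            df = n_agg - 2
            if df <= 0 or abs(r) >= 1.0:
                p = 0.0 if abs(r) >= 1.0 and df > 0 else 1.0
            else:
                tstat = r * np.sqrt(df / (1 - r**2))
                p = float(2 * t_dist.sf(abs(tstat), df))
        rows.append((peak_counts.feature_ids[pi], gene_counts.feature_ids[gi], dist, r, p))
    out = pd.DataFrame(rows, columns=["peak_id", "gene_id", "distance", "r", "p"])
    out["fdr"] = bh_fdr(out["p"].to_numpy())
    links = out[(out["r"].abs() >= corr_min) & (out["fdr"] <= fdr_max)]
    return links.reset_index(drop=True), out


def _log_norm_dense(values: sp.spmatrix) -> np.ndarray:
    X = sp.csr_matrix(values, dtype=float)
    lib = np.asarray(X.sum(axis=0)).ravel()
    inv = np.divide(1e4, lib, out=np.zeros_like(lib), where=lib > 0)
    norm = X @ sp.diags(inv)
    return np.log1p(np.asarray(norm.todense()))


# --------------------------------------------------------------- module scores


def module_score(
    values: np.ndarray | sp.spmatrix,
    feature_ids: Sequence[str],
    feature_set: Sequence[str],
    *,
    n_bins: int = 25,
    n_ctrl: int = 100,
    seed: int = 0,
) -> np.ndarray:
    """Per-cell module score against abundance-matched controls.

    ``values`` is a normalised (features x cells) matrix.  The score is
    the mean over the feature set minus the mean over control features
    drawn, for each set feature, from the same average-abundance bin
    (``n_ctrl`` controls per set feature).  Deterministic given ``seed``.
    """
    feature_ids = np.asarray(feature_ids, dtype=object)
    feature_set = np.asarray(feature_set, dtype=object)
    if feature_set.size == 0:
        raise ValidationError("empty feature set for module score")
    lookup = pd.Index(feature_ids)
    set_idx = lookup.get_indexer(feature_set)
    if (set_idx < 0).any():
        raise ValidationError("feature set contains unknown features")
    X = np.asarray(values.todense() if sp.issparse(values) else values, dtype=float)
    abundance = X.mean(axis=1)
    order = np.argsort(abundance, kind="mergesort")
    n = len(abundance)
    bin_of = np.empty(n, dtype=int)
    bin_of[order] = np.minimum(np.arange(n) * n_bins // n, n_bins - 1)
    in_set = np.zeros(n, dtype=bool)
    in_set[set_idx] = True
    rng = np.random.default_rng(seed)
    ctrl_rows: list[np.ndarray] = []
    for fi in set_idx:
        pool = np.flatnonzero((bin_of == bin_of[fi]) & ~in_set)
        if pool.size == 0:
            pool = np.flatnonzero(bin_of == bin_of[fi])
        ctrl_rows.append(pool[rng.integers(0, pool.size, size=n_ctrl)])
    ctrl = np.concatenate(ctrl_rows)
    return X[set_idx].mean(axis=0) - X[ctrl].mean(axis=0)


def bin_score_distribution(
    scores: pd.Series, sample_of: pd.Series, n_bins: int = 50
) -> pd.DataFrame:
    """Samples x bins matrix of score-distribution fractions.

    Bins are equal-width over the pooled score range (the published
    display convention uses 50 bins); each sample's row sums to 1.
    Samples with no cells are dropped with a warning.
    """
    scores = pd.Series(scores)
    sample_of = pd.Series(sample_of).loc[scores.index]
    lo, hi = float(scores.min()), float(scores.max())
    if lo == hi:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, n_bins + 1)
    which = np.clip(np.digitize(scores.to_numpy(), edges) - 1, 0, n_bins - 1)
    out = {}
    for sample in pd.unique(sample_of):
        mask = (sample_of == sample).to_numpy()
        if mask.sum() == 0:
            logger.warning("sample %s has no cells; dropped from binning", sample)
            continue
        counts = np.bincount(which[mask], minlength=n_bins)
        out[sample] = counts / counts.sum()
    return pd.DataFrame.from_dict(out, orient="index", columns=range(n_bins))
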