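"""Iterative LSI reference construction, frozen-subspace projection and
k-nearest-neighbour label transfer.

The normal-epithelium reference is built by repeated rounds of
variable-feature selection, TF-IDF weighting and truncated SVD, with
clustering between rounds so that variable features are re-chosen on
cluster-aggregated log-CPM profiles (which damps per-cell sampling noise
and batch structure).  The fitted transform is frozen — variable feature
list, row mask, IDF vector and right singular vectors — so that query
cells from diseased samples can be projected into exactly the reference
subspace and labelled by their 25 nearest reference neighbours.
"""

from __future__ import annotations

import dataclasses
import logging
import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD
from sklearn.neighbors import NearestNeighbors

from .core import CountsMatrix, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class IterativeLSIParams:
    """Knobs for iterative LSI.

    Defaults follow the epithelial-reference recipe: 4 iterations, shared
    nearest-neighbour clustering between rounds with rising resolution,
    log-CPM cluster aggregation with prior count 3.  For RNA use 1,600
    variable genes and 8 dimensions; for ATAC peaks/tiles 15,000 variable
    features and 30 dimensions are conventional.
    """

    n_iterations: int = 4
    n_var_features: int = 1600
    n_dims: int = 8
    resolutions: tuple = (0.1, 0.2, 0.4)
    cpm_prior: float = 3.0
    exclude_regex: str | None = None  # e.g. r"^(MT-|RPL|RPS|HLA-)" for RNA
    binarize: bool = False
    cluster_method: str = "leiden"  # or "kmeans"
    kmeans_clusters: int = 8
    knn_k: int = 15

    def __post_init__(self) -> None:
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.n_dims < 1:
            raise ValueError("n_dims must be >= 1")


@dataclass
class LSIModel:
    """Frozen reference transform plus the reference embedding and labels."""

    variable_features: np.ndarray  # ordered feature ids used by the transform
    row_mask: np.ndarray  # bool; False = feature zeroed at projection
    idf: np.ndarray  # per-variable-feature inverse document frequency
    svd_v: np.ndarray  # right singular vectors, (n_variable_features x n_dims)
    singular_values: np.ndarray
    retained_dims: np.ndarray  # indices of dims kept for downstream use
    ref_embedding_full: np.ndarray  # reference cells x all fitted dims
    ref_barcodes: np.ndarray
    ref_labels: np.ndarray | None = None
    binarize: bool = False

    @property
    def ref_embedding(self) -> np.ndarray:
        return self.ref_embedding_full[:, self.retained_dims]

    @property
    def n_dims(self) -> int:
        return self.svd_v.shape[1]

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            variable_features=self.variable_features.astype(str),
            row_mask=self.row_mask,
            idf=self.idf,
            svd_v=self.svd_v,
            singular_values=self.singular_values,
            retained_dims=self.retained_dims,
            ref_embedding_full=self.ref_embedding_full,
            ref_barcodes=self.ref_barcodes.astype(str),
            ref_labels=(
                self.ref_labels.astype(str)
                if self.ref_labels is not None
                else np.array([], dtype=str)
            ),
            binarize=np.array([self.binarize]),
        )

    @classmethod
    def load(cls, path) -> "LSIModel":
        z = np.load(path, allow_pickle=False)
        labels = z["ref_labels"]
        return cls(
            variable_features=z["variable_features"].astype(object),
            row_mask=z["row_mask"],
            idf=z["idf"],
            svd_v=z["svd_v"],
            singular_values=z["singular_values"],
            retained_dims=z["retained_dims"],
            ref_embedding_full=z["ref_embedding_full"],
            ref_barcodes=z["ref_barcodes"].astype(object),
            ref_labels=labels.astype(object) if labels.size else None,
            binarize=bool(z["binarize"][0]),
        )


def tfidf_transform(
    matrix: sp.spmatrix,
    *,
    idf: np.ndarray | None = None,
    row_mask: np.ndarray | None = None,
) -> tuple[sp.csr_matrix, np.ndarray, np.ndarray]:
    """TF-IDF weight a (features x cells) count matrix.

    ``tf`` is each count divided by its cell's total over the selected
    features; ``idf`` is ``ln(1 + N_cells / n_cells_with_feature)``.  When
    ``idf``/``row_mask`` are supplied (projection mode) they are applied
    instead of being fitted, and masked rows are zeroed.  Cells with zero
    total map to the origin.

    Returns ``(tfidf, idf, row_mask)``.
    """
    X = sp.csr_matrix(matrix, dtype=float)
    n_cells = X.shape[1]
    if idf is None:
        n_with = np.asarray((X > 0).sum(axis=1)).ravel()
        row_mask = n_with > 0
        # +1 smoothing keeps empty features finite; they are masked anyway
        idf = np.log(1.0 + n_cells / np.maximum(n_with, 1.0))
    else:
        idf = np.asarray(idf, dtype=float)
        if row_mask is None:
            row_mask = np.ones(X.shape[0], dtype=bool)
    totals = np.asarray(X.sum(axis=0)).ravel()
    inv_totals = np.divide(1.0, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0)
    tf = X @ sp.diags(inv_totals)
    weights = np.where(row_mask, idf, 0.0)
    tfidf = sp.diags(weights) @ tf
    return sp.csr_matrix(tfidf), idf, np.asarray(row_mask, dtype=bool)


def _log_cpm(counts: np.ndarray, prior: float) -> np.ndarray:
    """edgeR-style log2 counts-per-million with a depth-scaled prior count."""
    counts = np.asarray(counts, dtype=float)
    lib = counts.sum(axis=0)
    lib = np.where(lib > 0, lib, 1.0)
    adj_prior = prior * lib / lib.mean()
    return np.log2((counts + adj_prior[None, :]) / (lib + 2 * adj_prior)[None, :] * 1e6)


def _sparse_row_variance(X: sp.csr_matrix) -> np.ndarray:
    n = X.shape[1]
    mean = np.asarray(X.mean(axis=1)).ravel()
    sq = X.copy()
    sq.data = sq.data**2
    ex2 = np.asarray(sq.mean(axis=1)).ravel()
    return ex2 - mean**2


def _per_cell_variance_features(X: sp.csr_matrix) -> np.ndarray:
    """Feature variance of log1p depth-normalised counts (round-1 criterion)."""
    totals = np.asarray(X.sum(axis=0)).ravel()
    inv = np.divide(1e4, totals, out=np.zeros_like(totals, dtype=float), where=totals > 0)
    norm = sp.csr_matrix(X @ sp.diags(inv))
    norm.data = np.log1p(norm.data)
    return _sparse_row_variance(norm)


def _svd_embed(tfidf: sp.csr_matrix, n_dims: int, seed: int):
    """Truncated SVD of the cells-x-features TF-IDF; deterministic signs."""
    n_dims = min(n_dims, min(tfidf.shape) - 1)
    svd = TruncatedSVD(n_components=n_dims, algorithm="arpack", random_state=seed)
    emb = svd.fit_transform(tfidf.T)  # cells x dims, scaled by singular values
    v = svd.components_.T  # features x dims
    # sign convention: largest-magnitude loading of each component positive
    flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    return emb * flip, v * flip, svd.singular_values_


def _snn_leiden(embedding: np.ndarray, resolution: float, seed: int, k: int) -> np.ndarray:
    import igraph
    import leidenalg

    n = embedding.shape[0]
    k = min(k, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(embedding)
    _, idx = nn.kneighbors(embedding)
    edges = {(min(i, j), max(i, j)) for i in range(n) for j in idx[i, 1:]}
    g = igraph.Graph(n=n, edges=sorted(edges))
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=2,
    )
    return np.asarray(part.membership)


def _cluster(embedding: np.ndarray, resolution: float, params: IterativeLSIParams, seed: int) -> np.ndarray:
    if params.cluster_method == "kmeans":
        from sklearn.cluster import KMeans

        k = min(params.kmeans_clusters, embedding.shape[0])
        return KMeans(n_clusters=k, n_init=5, random_state=seed).fit_predict(embedding)
    return _snn_leiden(embedding, resolution, seed, params.knn_k)


def fit_iterative_lsi(
    counts: CountsMatrix,
    params: IterativeLSIParams | None = None,
    seed: int = 0,
    labels: Sequence[str] | None = None,
) -> LSIModel:
    """Fit the iterative LSI reference model on reference cells.

    Each round selects variable features (per-cell variance in round 1,
    variance of cluster-aggregated log-CPM profiles afterwards), TF-IDF
    weights them, embeds cells by truncated SVD and re-clusters.  The final
    round's transform constants are frozen into the returned model.
    """
    params = params or IterativeLSIParams()
    if counts.n_cells < 2:
        raise ValidationError("iterative LSI needs at least 2 cells")
    X = counts.values.astype(float)
    feature_ids = counts.feature_ids
    if params.exclude_regex:
        pattern = re.compile(params.exclude_regex)
        keep = np.array([not pattern.search(str(f)) for f in feature_ids])
        X, feature_ids = X[keep], feature_ids[keep]
    if params.binarize:
        X = X.copy()
        X.data = np.ones_like(X.data)

    n_var = params.n_var_features
    if n_var > X.shape[0]:
        logger.warning(
            "requested %d variable features but only %d available; using all",
            n_var,
            X.shape[0],
        )
        n_var = X.shape[0]

    clusters: np.ndarray | None = None
    var_idx = np.array([], dtype=int)
    emb = v = svals = idf = row_mask = None
    for it in range(params.n_iterations):
        if it == 0:
            variance = _per_cell_variance_features(sp.csr_matrix(X))
        else:
            agg = np.column_stack(
                [
                    np.asarray(X[:, clusters == c].sum(axis=1)).ravel()
                    for c in np.unique(clusters)
                ]
            )
            variance = _log_cpm(agg, params.cpm_prior).var(axis=1)
        var_idx = np.argsort(variance, kind="mergesort")[::-1][:n_var]
        var_idx = np.sort(var_idx)
        tfidf, idf, row_mask = tfidf_transform(X[var_idx])
        emb, v, svals = _svd_embed(tfidf, params.n_dims, seed)
        if it < params.n_iterations - 1:
            res_list = params.resolutions
            res = res_list[min(it, len(res_list) - 1)] if res_list else 0.2
            clusters = _cluster(emb, res, params, seed)

    model = LSIModel(
        variable_features=feature_ids[var_idx],
        row_mask=row_mask,
        idf=idf,
        svd_v=v,
        singular_values=svals,
        retained_dims=np.arange(v.shape[1]),
        ref_embedding_full=emb,
        ref_barcodes=counts.barcodes,
        ref_labels=np.asarray(labels, dtype=object) if labels is not None else None,
        binarize=params.binarize,
    )
    return model


def drop_sample_correlated_dims(
    model: LSIModel, sample_of: pd.Series, threshold: float = 0.8
) -> LSIModel:
    """Drop embedding dimensions tracking sample of origin.

    A dimension is dropped when the magnitude of its point-biserial
    correlation with any sample-indicator variable exceeds ``threshold``.
    """
    samples = pd.Series(sample_of).loc[model.ref_barcodes].to_numpy()
    uniq = np.unique(samples)
    if len(uniq) < 2:
        raise ValidationError("need at least two samples to test dimensions")
    emb = model.ref_embedding_full[:, model.retained_dims]
    keep = []
    for local, dim in enumerate(model.retained_dims):
        col = emb[:, local]
        max_corr = 0.0
        for s in uniq:
            indicator = (samples == s).astype(float)
            if indicator.std() == 0 or col.std() == 0:
                continue
            r = np.corrcoef(col, indicator)[0, 1]
            max_corr = max(max_corr, abs(r))
        if max_corr > threshold:
            logger.info("dropping LSI dimension %d (sample correlation %.3f)", dim, max_corr)
        else:
            keep.append(dim)
    if not keep:
        raise ValidationError("all LSI dimensions correlate with sample of origin")
    return dataclasses.replace(model, retained_dims=np.asarray(keep, dtype=int))


def _project_full(model: LSIModel, query: CountsMatrix) -> np.ndarray:
    lookup = pd.Index(query.feature_ids)
    idx = lookup.get_indexer(model.variable_features)
    if (idx >= 0).sum() == 0:
        raise ValidationError("query shares no features with the reference model")
    X = query.values.astype(float)
    if model.binarize:
        X = X.copy()
        X.data = np.ones_like(X.data)
    present = idx >= 0
    aligned = X[np.where(present, idx, 0)]
    aligned = sp.diags(present.astype(float)) @ aligned  # zero missing features
    tfidf, _, _ = tfidf_transform(aligned, idf=model.idf, row_mask=model.row_mask)
    return np.asarray(tfidf.T @ model.svd_v)


def project_cells(model: LSIModel, query: CountsMatrix) -> np.ndarray:
    """Project query cells into the frozen reference subspace.

    Query features absent from the model are treated as zero rows; the
    stored row mask, IDF vector and right singular vectors reproduce the
    reference transform exactly, so projecting the reference cells
    recovers ``ref_embedding``.
    """
    return _project_full(model, query)[:, model.retained_dims]


def knn_label_transfer(
    model: LSIModel, query_embedding: np.ndarray, k: int = 25
) -> tuple[np.ndarray, np.ndarray]:
    """Label query cells by majority vote of their k nearest reference cells.

    Ties in the modal vote are broken by summed inverse distance, then
    lexicographically.  Returns ``(labels, vote_fractions)``.
    """
    if model.ref_labels is None:
        raise ValidationError("model has no reference labels")
    ref = model.ref_embedding
    if k > ref.shape[0]:
        raise ValidationError(f"k={k} exceeds the {ref.shape[0]} reference cells")
    nn = NearestNeighbors(n_neighbors=k).fit(ref)
    dist, idx = nn.kneighbors(np.atleast_2d(query_embedding))
    labels = np.empty(idx.shape[0], dtype=object)
    fractions = np.empty(idx.shape[0], dtype=float)
    ref_labels = model.ref_labels
    for i in range(idx.shape[0]):
        votes = ref_labels[idx[i]]
        uniq, counts = np.unique(votes.astype(str), return_counts=True)
        top = counts.max()
        candidates = uniq[counts == top]
        if len(candidates) > 1:
            weights = {
                c: (1.0 / (dist[i][votes.astype(str) == c] + 1e-12)).sum()
                for c in candidates
            }
            best_w = max(weights.values())
            candidates = sorted(c for c, w in weights.items() if w == best_w)
        labels[i] = candidates[0]
        fractions[i] = top / k
    return labels, fractions
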