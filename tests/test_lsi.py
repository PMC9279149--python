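"""Iterative LSI fitting, frozen projection and k-NN label transfer."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from polypcontinuum.core import CountsMatrix, ValidationError
from polypcontinuum.lsi import (
    IterativeLSIParams,
    LSIModel,
    drop_sample_correlated_dims,
    fit_iterative_lsi,
    knn_label_transfer,
    project_cells,
    tfidf_transform,
)


def _two_population_counts(n_cells=120, n_features=60, seed=0):
    """Two well-separated populations with disjoint high-rate features."""
    rng = np.random.default_rng(seed)
    rates = np.full((n_features, 2), 0.2)
    rates[: n_features // 2, 0] = 4.0
    rates[n_features // 2 :, 1] = 4.0
    pop = np.repeat([0, 1], n_cells // 2)
    counts = rng.poisson(rates[:, pop])
    barcodes = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
    cm = CountsMatrix(
        values=sp.csr_matrix(counts),
        feature_ids=np.array([f"f{i}" for i in range(n_features)], dtype=object),
        feature_kind="peak",
        barcodes=barcodes,
        sample_of=pd.Series(np.where(pop == 0, "sA", "sB"), index=barcodes),
    )
    labels = np.where(pop == 0, "alpha", "beta")
    return cm, labels


class TestTFIDF:
    def test_single_cell_single_feature(self):
        t, idf, mask = tfidf_transform(sp.csr_matrix(np.array([[1.0]])))
        assert t[0, 0] == pytest.approx(np.log(2))
        assert idf[0] == pytest.approx(np.log(2))

    def test_depth_invariance_of_tf(self):
        X = sp.csr_matrix(np.array([[1.0, 2.0], [3.0, 6.0]]))
        t, _, _ = tfidf_transform(X)
        assert t[:, 0].toarray() == pytest.approx(t[:, 1].toarray())

    def test_stored_row_mask_zeroes_absent_features(self):
        # feature absent in the reference is zeroed at projection time
        ref = sp.csr_matrix(np.array([[2.0, 1.0], [0.0, 0.0]]))
        _, idf, mask = tfidf_transform(ref)
        assert not mask[1]
        query = sp.csr_matrix(np.array([[1.0], [5.0]]))
        tq, _, _ = tfidf_transform(query, idf=idf, row_mask=mask)
        assert tq[1, 0] == 0.0

    def test_zero_cell_maps_to_origin(self):
        X = sp.csr_matrix(np.array([[0.0, 1.0], [0.0, 2.0]]))
        t, _, _ = tfidf_transform(X)
        assert t[:, 0].toarray() == pytest.approx(np.zeros((2, 1)))


@pytest.fixture(scope="module")
def fitted():
    cm, labels = _two_population_counts()
    params = IterativeLSIParams(
        n_iterations=2, n_var_features=60, n_dims=5, resolutions=(0.4,)
    )
    model = fit_iterative_lsi(cm, params, seed=0, labels=labels)
    return cm, labels, model


class TestIterativeLSI:
    def test_projection_reproduces_reference_embedding(self, fitted):
        cm, _, model = fitted
        emb = project_cells(model, cm)
        scale = np.abs(model.ref_embedding).max()
        assert np.abs(emb - model.ref_embedding).max() / scale < 1e-8

    def test_two_populations_separate(self, fitted):
        cm, labels, model = fitted
        emb = model.ref_embedding
        # 1-NN classification in the embedding is perfect for separated pops
        from sklearn.neighbors import KNeighborsClassifier

        acc = (
            KNeighborsClassifier(n_neighbors=5)
            .fit(emb, labels)
            .score(emb, labels)
        )
        assert acc == 1.0

    def test_single_iteration_equals_global_tfidf_svd(self):
        cm, labels = _two_population_counts(seed=3)
        params = IterativeLSIParams(n_iterations=1, n_var_features=60, n_dims=4)
        model = fit_iterative_lsi(cm, params, seed=0)
        tfidf, _, _ = tfidf_transform(cm.values.astype(float))
        # embedding columns span the same subspace as a direct SVD
        from numpy.linalg import matrix_rank

        direct = np.asarray((tfidf.T @ model.svd_v))
        assert np.abs(direct - model.ref_embedding_full).max() < 1e-10

    def test_determinism(self):
        cm, labels = _two_population_counts(seed=5)
        params = IterativeLSIParams(n_iterations=2, n_var_features=40, n_dims=4, resolutions=(0.4,))
        m1 = fit_iterative_lsi(cm, params, seed=11)
        m2 = fit_iterative_lsi(cm, params, seed=11)
        assert list(m1.variable_features) == list(m2.variable_features)
        assert m1.ref_embedding_full == pytest.approx(m2.ref_embedding_full, abs=0.0)

    def test_cell_order_permutation_invariance(self):
        cm, _ = _two_population_counts(seed=8)
        params = IterativeLSIParams(n_iterations=1, n_var_features=60, n_dims=3)
        model = fit_iterative_lsi(cm, params, seed=0)
        perm = np.random.default_rng(0).permutation(cm.n_cells)
        cm_perm = cm.subset_cells(cm.barcodes[perm])
        model_p = fit_iterative_lsi(cm_perm, params, seed=0)
        assert model_p.ref_embedding_full == pytest.approx(
            model.ref_embedding_full[perm], abs=1e-8
        )

    def test_too_few_cells_rejected(self):
        cm, _ = _two_population_counts()
        single = cm.subset_cells(cm.barcodes[:1])
        with pytest.raises(ValidationError):
            fit_iterative_lsi(single, IterativeLSIParams(n_iterations=1, n_dims=2))

    def test_model_roundtrip(self, fitted, tmp_path):
        _, _, model = fitted
        model.save(tmp_path / "model.npz")
        back = LSIModel.load(tmp_path / "model.npz")
        assert back.ref_embedding_full == pytest.approx(model.ref_embedding_full)
        assert list(back.variable_features) == list(model.variable_features)
        assert list(back.ref_labels) == list(model.ref_labels)


class TestDropDims:
    def test_planted_batch_dimension_dropped(self, fitted):
        cm, _, model = fitted
        batch = (pd.Series(cm.sample_of).to_numpy() == "sA").astype(float)
        doctored = LSIModel(
            variable_features=model.variable_features,
            row_mask=model.row_mask,
            idf=model.idf,
            svd_v=model.svd_v,
            singular_values=model.singular_values,
            retained_dims=model.retained_dims,
            ref_embedding_full=np.column_stack(
                [model.ref_embedding_full[:, :4], batch]
            ),
            ref_barcodes=model.ref_barcodes,
        )
        # the planted one-hot dimension (index 4) correlates perfectly
        kept = drop_sample_correlated_dims(doctored, cm.sample_of, threshold=0.95)
        assert 4 not in kept.retained_dims

    def test_threshold_above_one_keeps_all(self, fitted):
        cm, _, model = fitted
        kept = drop_sample_correlated_dims(model, cm.sample_of, threshold=1.01)
        assert list(kept.retained_dims) == list(model.retained_dims)


class TestLabelTransfer:
    def test_identical_query_k1(self, fitted):
        _, labels, model = fitted
        lab, frac = knn_label_transfer(model, model.ref_embedding[:3], k=1)
        assert list(lab) == list(labels[:3])
        assert frac == pytest.approx(np.ones(3))

    def test_self_labeling_agreement(self, fitted):
        _, labels, model = fitted
        lab, _ = knn_label_transfer(model, model.ref_embedding, k=25)
        assert (lab == labels).mean() >= 0.99

    def test_majority_vote(self):
        # 13 votes beat 12: query at the centre of a 25-cell neighbourhood
        emb = np.linspace(0, 1, 25)[:, None]
        labels = np.array(["a"] * 12 + ["b"] * 13, dtype=object)
        model = LSIModel(
            variable_features=np.array(["f"], dtype=object),
            row_mask=np.array([True]),
            idf=np.array([1.0]),
            svd_v=np.ones((1, 1)),
            singular_values=np.array([1.0]),
            retained_dims=np.array([0]),
            ref_embedding_full=emb,
            ref_barcodes=np.array([f"c{i}" for i in range(25)], dtype=object),
            ref_labels=labels,
        )
        lab, frac = knn_label_transfer(model, np.array([[0.5]]), k=25)
        assert lab[0] == "b" and frac[0] == pytest.approx(13 / 25)

    def test_k_exceeding_reference_rejected(self, fitted):
        _, _, model = fitted
        with pytest.raises(ValidationError):
            knn_label_transfer(model, model.ref_embedding[:1], k=10_000)

    def test_rotation_invariance(self, fitted):
        _, labels, model = fitted
        theta = 0.7
        d = model.ref_embedding.shape[1]
        rot = np.eye(d)
        rot[:2, :2] = [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        rotated = LSIModel(
            variable_features=model.variable_features,
            row_mask=model.row_mask,
            idf=model.idf,
            svd_v=model.svd_v,
            singular_values=model.singular_values,
            retained_dims=np.arange(d),
            ref_embedding_full=model.ref_embedding @ rot,
            ref_barcodes=model.ref_barcodes,
            ref_labels=model.ref_labels,
        )
        lab0, _ = knn_label_transfer(model, model.ref_embedding, k=15)
        lab1, _ = knn_label_transfer(rotated, model.ref_embedding @ rot, k=15)
        assert list(lab0) == list(lab1)


def test_projection_linearity():
    """Projection is linear in the idf-weighted tf vectors."""
    rng = np.random.default_rng(0)
    v = rng.normal(size=(6, 3))
    model = LSIModel(
        variable_features=np.array([f"f{i}" for i in range(6)], dtype=object),
        row_mask=np.ones(6, bool),
        idf=np.ones(6),
        svd_v=v,
        singular_values=np.ones(3),
        retained_dims=np.arange(3),
        ref_embedding_full=np.zeros((1, 3)),
        ref_barcodes=np.array(["r"], dtype=object),
    )
    # two tf vectors (already normalised) and their midpoint
    a = np.array([0.5, 0.5, 0, 0, 0, 0])
    b = np.array([0, 0, 0, 0, 0.25, 0.75])
    mid = 0.5 * a + 0.5 * b
    pa, pb, pm = (x @ v for x in (a, b, mid))
    assert pm == pytest.approx(0.5 * pa + 0.5 * pb)
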