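"""Program clustering, motif enrichment, deviations, links and scores."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from sklearn.metrics import adjusted_rand_score

from polypcontinuum import programs as prog
from polypcontinuum.core import CountsMatrix, MotifAnnotation, ValidationError
from polypcontinuum.simulate import SimConfig, generate_cohort


class TestKMeans:
    def test_single_cluster(self):
        X = pd.DataFrame(np.random.default_rng(0).normal(size=(8, 3)))
        out = prog.kmeans_cluster(X, k=1, seed=0)
        assert (out.assignment == 1).all()

    def test_planted_groups_recovered_exactly(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        labels = np.repeat([0, 1, 2], 30)
        X = pd.DataFrame(centers[labels] + rng.normal(scale=0.3, size=(90, 2)))
        out = prog.kmeans_cluster(X, k=3, seed=0)
        assert adjusted_rand_score(labels, out.assignment) == 1.0

    def test_deterministic(self):
        X = pd.DataFrame(np.random.default_rng(2).normal(size=(40, 4)))
        a = prog.kmeans_cluster(X, k=5, seed=9).assignment
        b = prog.kmeans_cluster(X, k=5, seed=9).assignment
        assert (a == b).all()

    def test_objective_nonincreasing(self):
        X = pd.DataFrame(np.random.default_rng(3).normal(size=(60, 3)))
        out = prog.kmeans_cluster(X, k=4, seed=1, n_init=1)
        assert (np.diff(out.inertia_history) <= 1e-9).all()

    def test_final_assignment_is_fixed_point(self):
        X = pd.DataFrame(np.random.default_rng(4).normal(size=(50, 3)))
        out = prog.kmeans_cluster(X, k=4, seed=0)
        d2 = ((X.to_numpy()[:, None, :] - out.centroids[None]) ** 2).sum(axis=2)
        assert (d2.argmin(axis=1) + 1 == out.assignment.to_numpy()).all()

    def test_matches_sklearn_objective(self):
        from sklearn.cluster import KMeans

        X = np.random.default_rng(5).normal(size=(100, 4))
        ours = prog.kmeans_cluster(pd.DataFrame(X), k=5, seed=0)
        ref = KMeans(n_clusters=5, n_init=10, random_state=0).fit(X)
        assert ours.inertia_history[-1] == pytest.approx(ref.inertia_, rel=0.05)

    def test_k_exceeding_features_rejected(self):
        with pytest.raises(ValidationError):
            prog.kmeans_cluster(pd.DataFrame(np.zeros((3, 2))), k=5)


class TestEnrichment:
    def _annotation(self):
        # 10 peaks, motif A in peaks 0-3, motif B everywhere
        membership = np.zeros((2, 10))
        membership[0, :4] = 1
        membership[1, :] = 1
        return MotifAnnotation(
            membership=sp.csr_matrix(membership),
            motif_ids=np.array(["A", "B"], dtype=object),
            peak_ids=np.array([f"p{i}" for i in range(10)], dtype=object),
        )

    def test_worked_hypergeometric_example(self):
        ann = self._annotation()
        universe = [f"p{i}" for i in range(10)]
        cluster = ["p0", "p1", "p2", "p3", "p4"]  # overlap 4 of K=4, n=5
        out = prog.hypergeometric_enrichment(cluster, ann, universe).set_index("motif_id")
        assert out.loc["A", "p"] == pytest.approx(6 / 252, rel=1e-12)
        assert out.loc["B", "p"] == pytest.approx(1.0)

    def test_empty_cluster(self):
        out = prog.hypergeometric_enrichment([], self._annotation(), ["p0"])
        assert out.empty

    def test_cluster_outside_universe_rejected(self):
        with pytest.raises(ValidationError):
            prog.hypergeometric_enrichment(["p0"], self._annotation(), ["p1"])

    def test_planted_driver_motif_top_ranked(self, small_cohort, small_config):
        truth = small_cohort.truth
        members = truth.peak_program.index[truth.peak_program == 0].to_numpy()
        universe = truth.peak_program.index[truth.peak_program >= 0].to_numpy()
        out = prog.hypergeometric_enrichment(members, small_cohort.motifs, universe)
        assert out.iloc[0]["motif_id"] == truth.driver_motif[0]


class TestDeviations:
    def _counts_for(self, matrix):
        n_feat, n_cells = matrix.shape
        barcodes = np.array([f"c{i}" for i in range(n_cells)], dtype=object)
        return CountsMatrix(
            values=sp.csr_matrix(matrix),
            feature_ids=np.array([f"p{i}" for i in range(n_feat)], dtype=object),
            feature_kind="peak",
            barcodes=barcodes,
            sample_of=pd.Series(["s"] * n_cells, index=barcodes),
        )

    def _random_annotation(self, n_motifs, n_peaks, seed=0, density=0.2):
        rng = np.random.default_rng(seed)
        mem = (rng.random((n_motifs, n_peaks)) < density).astype(float)
        mem[:, 0] = 1  # no empty motifs
        return MotifAnnotation(
            membership=sp.csr_matrix(mem),
            motif_ids=np.array([f"m{i}" for i in range(n_motifs)], dtype=object),
            peak_ids=np.array([f"p{i}" for i in range(n_peaks)], dtype=object),
        )

    def test_expectation_model_exact_for_proportional_counts(self):
        # counts exactly depth x popularity -> raw deviations all zero
        pop = np.arange(1, 21, dtype=float)
        depth = np.array([1.0, 2.0, 4.0])
        counts = np.outer(pop, depth)
        cm = self._counts_for(counts)
        ann = self._random_annotation(4, 20)
        dev = prog.motif_deviation(cm, ann, n_background=5, seed=0)
        assert np.nanmax(np.abs(dev.raw.to_numpy())) < 1e-10

    def test_null_z_scores_standardised(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(2.0, size=(100, 150))
        cm = self._counts_for(counts)
        ann = self._random_annotation(6, 100, density=0.3)
        dev = prog.motif_deviation(cm, ann, n_background=50, seed=0)
        z = dev.z.to_numpy()
        assert abs(np.nanmean(z)) < 0.3
        sd = np.nanstd(z, axis=1)
        assert np.median(sd) == pytest.approx(1.0, abs=0.45)

    def test_cell_permutation_permutes_z(self):
        rng = np.random.default_rng(4)
        counts = rng.poisson(1.5, size=(30, 40))
        cm = self._counts_for(counts)
        ann = self._random_annotation(3, 30)
        dev = prog.motif_deviation(cm, ann, n_background=10, seed=1)
        perm = rng.permutation(40)
        dev_p = prog.motif_deviation(cm.subset_cells(cm.barcodes[perm]), ann, n_background=10, seed=1)
        assert dev_p.z.to_numpy() == pytest.approx(dev.z.to_numpy()[:, perm], nan_ok=True)

    def test_empty_motif_is_nan(self):
        counts = np.random.default_rng(5).poisson(2.0, size=(10, 8))
        cm = self._counts_for(counts)
        mem = np.zeros((2, 10))
        mem[0, :3] = 1  # motif m1 has no peaks
        ann = MotifAnnotation(
            membership=sp.csr_matrix(mem),
            motif_ids=np.array(["m0", "m1"], dtype=object),
            peak_ids=cm.feature_ids,
        )
        dev = prog.motif_deviation(cm, ann, n_background=5, seed=0)
        assert dev.z.loc["m1"].isna().all()

    def test_planted_motif_boost_highest_in_stem(self, small_cohort):
        c = small_cohort
        keep = np.isin(c.atac.sample_of.to_numpy(), ["CRC_0", "CRC_1"])
        sub = c.atac.subset_cells(keep)
        dev = prog.motif_deviation(sub, c.motifs, n_background=20, seed=0)
        labels = c.truth.cell_labels.loc[sub.barcodes].to_numpy()
        driver = c.truth.driver_motif[0]  # up-program, active in CRC stem cells
        z = dev.z.loc[driver].to_numpy()
        assert np.nanmean(z[labels == "stem"]) > np.nanmean(z[labels != "stem"])


class TestMotifExpressionCorrelation:
    def test_planted_driver_correlates_with_its_tf(self, small_cohort):
        """The driver motif's deviation tracks expression of a stem-specific
        TF gene, and anti-tracks an enterocyte gene."""
        c = small_cohort
        keep = np.isin(c.atac.sample_of.to_numpy(), ["CRC_0", "CRC_1"])
        sub_atac = c.atac.subset_cells(keep)
        sub_rna = c.rna.subset_cells(keep)
        dev = prog.motif_deviation(sub_atac, c.motifs, n_background=15, seed=0)
        labels = c.truth.cell_labels.loc[sub_atac.barcodes].to_numpy()
        # synthetic stand-in for the TF gene: a perfect stem indicator
        expr = np.vstack([(labels == "stem").astype(float),
                          (labels == "enterocyte").astype(float)])
        out = prog.motif_expression_correlation(
            dev,
            expr,
            ["stem_tf", "ent_tf"],
            {c.truth.driver_motif[0]: "stem_tf", c.truth.driver_motif[1]: "ent_tf"},
        )
        r = out.set_index("gene_id")["r"]
        assert r["stem_tf"] > 0.3
        assert r["ent_tf"] < 0.1  # down-program driver is not enterocyte-linked

    def test_missing_gene_is_nan(self, small_cohort):
        c = small_cohort
        sub = c.atac.subset_cells(np.arange(c.atac.n_cells) < 50)
        dev = prog.motif_deviation(sub, c.motifs, n_background=5, seed=0)
        out = prog.motif_expression_correlation(
            dev, np.zeros((1, 50)), ["g"], {c.truth.driver_motif[0]: "absent"}
        )
        assert np.isnan(out["r"]).all()


class TestPeakGeneLinks:
    def test_planted_links_recovered(self, small_cohort):
        links, tested = prog.peak_gene_links(
            small_cohort.atac,
            small_cohort.rna,
            small_cohort.peaks,
            small_cohort.gene_positions,
            seed=0,
        )
        truth_pairs = set(map(tuple, small_cohort.truth.links.to_numpy()))
        found = set(map(tuple, links[["peak_id", "gene_id"]].to_numpy()))
        tp = len(truth_pairs & found)
        assert tp / len(truth_pairs) >= 0.8
        assert tp / max(len(found), 1) >= 0.8

    def test_window_rule_excludes_distant_pairs(self, small_cohort):
        links, tested = prog.peak_gene_links(
            small_cohort.atac,
            small_cohort.rna,
            small_cohort.peaks,
            small_cohort.gene_positions,
            window=1000,
            n_aggregates=20,
            seed=0,
        )
        assert (tested["distance"] <= 1000).all()

    def test_no_pairs_in_window(self, small_cohort):
        gp = small_cohort.gene_positions.copy()
        gp["chrom"] = "chrX"  # no peaks there
        links, tested = prog.peak_gene_links(
            small_cohort.atac, small_cohort.rna, small_cohort.peaks, gp,
            n_aggregates=10, seed=0,
        )
        assert links.empty


class TestModuleScore:
    def test_zero_everywhere_scores_zero(self):
        X = np.zeros((10, 4))
        ids = [f"f{i}" for i in range(10)]
        s = prog.module_score(X, ids, ["f0", "f1"], n_bins=2, n_ctrl=5, seed=0)
        assert s == pytest.approx(np.zeros(4))

    def test_additive_shift_raises_one_cell(self):
        # widely separated feature abundances keep the control bins stable
        rng = np.random.default_rng(0)
        base = np.arange(50, dtype=float)[:, None] * 2.0
        X = base + rng.normal(scale=0.01, size=(50, 6))
        ids = [f"f{i}" for i in range(50)]
        feature_set = ["f3", "f7", "f11"]
        before = prog.module_score(X, ids, feature_set, seed=1)
        X2 = X.copy()
        for f in feature_set:
            X2[ids.index(f), 2] += 0.8
        shifted = prog.module_score(X2, ids, feature_set, seed=1)
        delta = shifted - before
        assert delta[2] == pytest.approx(0.8, abs=1e-9)
        assert np.abs(np.delete(delta, 2)).max() < 1e-9

    def test_empty_set_rejected(self):
        with pytest.raises(ValidationError):
            prog.module_score(np.zeros((3, 2)), ["a", "b", "c"], [])

    def test_stem_cells_outscore_enterocytes(self, small_cohort, small_config):
        from polypcontinuum.differential import depth_normalize

        c = small_cohort
        X = np.log1p(np.asarray(depth_normalize(c.rna.values).todense()))
        n_prog = small_config.n_programs * small_config.genes_per_program
        stem_markers = list(
            c.rna.feature_ids[n_prog : n_prog + small_config.gene_markers_per_type]
        )
        score = prog.module_score(X, c.rna.feature_ids, stem_markers, seed=0)
        lab = c.truth.cell_labels.loc[c.rna.barcodes].to_numpy()
        assert np.median(score[lab == "stem"]) > np.median(score[lab == "enterocyte"])


class TestScoreBinning:
    def test_single_value_sample_occupies_one_bin(self):
        scores = pd.Series([0.5, 0.5, 0.1, 0.9], index=list("abcd"))
        samples = pd.Series(["s1", "s1", "s2", "s2"], index=list("abcd"))
        out = prog.bin_score_distribution(scores, samples, n_bins=10)
        assert (out.loc["s1"] > 0).sum() == 1
        assert out.loc["s1"].max() == 1.0

    def test_rows_sum_to_one(self, small_cohort):
        rng = np.random.default_rng(0)
        scores = pd.Series(
            rng.normal(size=small_cohort.atac.n_cells), index=small_cohort.atac.barcodes
        )
        out = prog.bin_score_distribution(scores, small_cohort.atac.sample_of, n_bins=50)
        assert out.to_numpy().sum(axis=1) == pytest.approx(np.ones(len(out)))
        assert out.shape[1] == 50
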