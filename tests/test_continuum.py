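"""Sample embedding, principal-curve fitting and continuum ordering."""

import numpy as np
import pandas as pd
import pytest

from polypcontinuum import continuum as ct
from polypcontinuum.core import ValidationError
from polypcontinuum.stats import rank_sum_test


def _mock_table(sample, feature_ids, lfc):
    return pd.DataFrame(
        {
            "sample_id": sample,
            "feature_id": feature_ids,
            "log2fc": lfc,
            "p": 0.5,
            "fdr": 0.5,
            "n_target": 10,
            "n_background": 10,
        }
    )


class TestLfcMatrix:
    def test_declared_order(self):
        tables = {
            "s1": _mock_table("s1", ["a", "b", "c"], [1.0, 2.0, 3.0]),
            "s2": _mock_table("s2", ["a", "b", "c"], [4.0, 5.0, 6.0]),
        }
        m = ct.build_lfc_matrix(tables, ["c", "a"])
        assert m.shape == (2, 2)
        assert m.loc["s1"].tolist() == [3.0, 1.0]

    def test_empty_feature_list_rejected(self):
        tables = {"s1": _mock_table("s1", ["a"], [1.0])}
        with pytest.raises(ValidationError):
            ct.build_lfc_matrix(tables, [])

    def test_missing_feature_names_sample(self):
        tables = {"s1": _mock_table("s1", ["a"], [1.0])}
        with pytest.raises(ValidationError, match="s1"):
            ct.build_lfc_matrix(tables, ["zzz"])


class TestPCA:
    def test_collinear_samples_one_component(self):
        t = np.linspace(0, 1, 6)
        X = pd.DataFrame(np.outer(t, [1.0, 2.0, -1.0, 0.5]))
        res = ct.pca_samples(X, n_components=3)
        total = res.explained_variance.sum()
        assert res.explained_variance[0] / total == pytest.approx(1.0, abs=1e-10)

    def test_sample_permutation_permutes_scores(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(7, 5)), index=[f"s{i}" for i in range(7)])
        res = ct.pca_samples(X, 3)
        perm = rng.permutation(7)
        res_p = ct.pca_samples(X.iloc[perm], 3)
        assert res_p.scores == pytest.approx(res.scores[perm], abs=1e-9)

    def test_full_reconstruction_identity(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(5, 4)))
        res = ct.pca_samples(X, n_components=4)
        centered = X.to_numpy() - X.to_numpy().mean(axis=0)
        recon = res.scores @ res.loadings.T
        assert recon == pytest.approx(centered, abs=1e-10)

    def test_clipping_warns(self, caplog):
        X = pd.DataFrame(np.random.default_rng(2).normal(size=(3, 10)))
        res = ct.pca_samples(X, n_components=9)
        assert res.scores.shape[1] == 2


class TestPrincipalCurve:
    def test_straight_line_recovered(self):
        t = np.linspace(0, 1, 30)
        pts = np.column_stack([t, 2 * t])
        curve = ct.fit_trajectory_curve(pts)
        _, dist = ct._polyline_project(pts, curve)
        assert dist.max() < 1e-8

    def test_quarter_circle_arc_length(self):
        theta = np.linspace(0, np.pi / 2, 60)
        pts = np.column_stack([np.cos(theta), np.sin(theta)])
        curve = ct.fit_trajectory_curve(pts, smooth_frac=0.25)
        length = np.linalg.norm(np.diff(curve, axis=0), axis=1).sum()
        assert length == pytest.approx(np.pi / 2, rel=0.02)

    def test_deterministic_refit(self):
        rng = np.random.default_rng(4)
        pts = rng.normal(size=(25, 2)).cumsum(axis=0)
        c1 = ct.fit_trajectory_curve(pts)
        c2 = ct.fit_trajectory_curve(pts)
        assert c1 == pytest.approx(c2, abs=0.0)

    def test_degenerate_scatter_rejected(self):
        with pytest.raises(ValidationError):
            ct.fit_trajectory_curve(np.ones((10, 2)))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValidationError):
            ct.fit_trajectory_curve(np.random.default_rng(0).normal(size=(3, 2)))


class TestOrdering:
    def test_collinear_positions_equally_spaced(self):
        pts = np.column_stack([np.linspace(0, 10, 6), np.zeros(6)])
        curve = ct.fit_trajectory_curve(pts)
        ids = [f"s{i}" for i in range(6)]
        pos, order = ct.order_samples(curve, pts, ids, anchor_mask=np.eye(6, dtype=bool)[0])
        spacing = np.diff(pos.loc[ids].to_numpy())
        assert spacing == pytest.approx(np.full(5, spacing[0]), rel=1e-6)
        assert list(order) == ids

    def test_orientation_anchoring_flips_reversed_curve(self):
        pts = np.column_stack([np.linspace(0, 10, 8), np.zeros(8)])
        curve = ct.fit_trajectory_curve(pts)
        ids = [f"s{i}" for i in range(8)]
        anchor = np.zeros(8, dtype=bool)
        anchor[0] = True  # the normal-like sample sits at coordinate 0
        pos_fwd, order_fwd = ct.order_samples(curve, pts, ids, anchor)
        pos_rev, order_rev = ct.order_samples(curve[::-1], pts, ids, anchor)
        assert list(order_fwd) == list(order_rev)
        assert pos_fwd.loc[ids].to_numpy() == pytest.approx(
            pos_rev.loc[ids].to_numpy(), abs=1e-6
        )

    def test_centering_invariance_of_ordering(self):
        rng = np.random.default_rng(6)
        lfc = pd.DataFrame(
            rng.normal(size=(10, 20)), index=[f"s{i}" for i in range(10)]
        )
        shifted = lfc + 5.0  # constant offset to every sample's profile
        for frame in (lfc, shifted):
            res = ct.pca_samples(frame, 2)
            curve = ct.fit_trajectory_curve(res.scores[:, :2])
            pos, order = ct.order_samples(
                curve, res.scores, frame.index, np.eye(10, dtype=bool)[0]
            )
            if frame is lfc:
                base_order = list(order)
        assert list(order) == base_order


class TestCompositionAnalyses:
    def test_differential_counts_sorted_by_position(self):
        tables = {
            "s1": _mock_table("s1", ["a", "b"], [2.0, 0.0]),
            "s2": _mock_table("s2", ["a", "b"], [2.0, 2.0]),
        }
        tables["s1"].loc[0, "fdr"] = 0.01
        tables["s2"]["fdr"] = 0.01
        positions = pd.Series({"s1": 5.0, "s2": 1.0})
        out = ct.differential_counts_along_continuum(tables, positions)
        assert out["sample_id"].tolist() == ["s2", "s1"]
        assert out["n_significant"].tolist() == [2, 1]

    def test_missing_sample_skipped(self, caplog):
        tables = {"s1": _mock_table("s1", ["a"], [2.0])}
        out = ct.differential_counts_along_continuum(tables, pd.Series(dtype=float))
        assert out.empty

    def test_compare_fractions_identity_and_bonferroni(self):
        fr = pd.DataFrame(
            {"stem": [0.1, 0.1, 0.1, 0.1], "rest": [0.9, 0.9, 0.9, 0.9]},
            index=["n1", "n2", "p1", "p2"],
        )
        states = pd.Series({"n1": "normal", "n2": "normal", "p1": "polyp", "p2": "polyp"})
        out = ct.compare_fractions(fr, states)
        assert (out["p"] == 1.0).all()
        assert (out["p_bonferroni"] == 1.0).all()

    def test_compare_fractions_matches_manual_ranksum(self):
        rng = np.random.default_rng(7)
        fr = pd.DataFrame(
            {"stem": np.concatenate([rng.uniform(0, 0.2, 4), rng.uniform(0.5, 0.9, 4)])},
            index=[f"n{i}" for i in range(4)] + [f"p{i}" for i in range(4)],
        )
        states = pd.Series(
            ["normal"] * 4 + ["polyp"] * 4, index=fr.index
        )
        out = ct.compare_fractions(fr, states)
        manual = rank_sum_test(fr.iloc[4:, 0].to_numpy(), fr.iloc[:4, 0].to_numpy())
        row = out[(out["cell_type"] == "stem") & (out["state"] == "polyp")].iloc[0]
        assert row["p"] == pytest.approx(manual)
        assert row["p_bonferroni"] == pytest.approx(min(1.0, manual * len(out)))

    def test_small_group_reported_na(self):
        fr = pd.DataFrame({"stem": [0.1, 0.2, 0.3]}, index=["n1", "n2", "p1"])
        states = pd.Series({"n1": "normal", "n2": "normal", "p1": "polyp"})
        out = ct.compare_fractions(fr, states)
        assert out["p"].isna().all()

    def test_trend_perfect_correlation(self):
        pos = pd.Series({f"s{i}": float(i) for i in range(8)})
        fr = pd.DataFrame({"stem": pos.to_numpy()}, index=pos.index)
        out = ct.composition_trend(fr, pos)
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_trend_constant_fraction_is_na(self):
        pos = pd.Series({f"s{i}": float(i) for i in range(5)})
        fr = pd.DataFrame({"flat": np.full(5, 0.5)}, index=pos.index)
        out = ct.composition_trend(fr, pos)
        assert np.isnan(out.loc[0, "rho"])

    def test_fractions_rows_sum_to_one(self, small_cohort):
        fr = ct.cell_type_fractions(
            small_cohort.truth.cell_labels, small_cohort.atac.sample_of
        )
        assert fr.sum(axis=1).to_numpy() == pytest.approx(np.ones(len(fr)))
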