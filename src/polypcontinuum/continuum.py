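"""Ordering samples along the malignancy continuum.

Samples are embedded by PCA of their stem-like-cell log2 fold-change
profiles; a principal curve (Hastie-Stuetzle iterative projection and
smoothing) is fitted through the first two principal components, and each
sample receives the arc-length coordinate of its nearest point on the
curve.  Orientation is anchored so that normal-like (unaffected) samples
sit at the low end.  Downstream helpers relate cell-type composition and
differential-feature counts to the recovered positions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from statsmodels.nonparametric.smoothers_lowess import lowess

from .core import ValidationError
from .stats import bh_fdr, bonferroni, rank_sum_test

logger = logging.getLogger(__name__)


@dataclass
class PCAResult:
    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # features x components
    explained_variance: np.ndarray
    sample_ids: np.ndarray


@dataclass
class ContinuumResult:
    features_used: np.ndarray
    lfc_matrix: pd.DataFrame  # samples x features
    pca: PCAResult
    curve: np.ndarray  # ordered polyline in PC1-PC2, (n_points x 2)
    positions: pd.Series  # sample -> arc length
    order: np.ndarray  # sample ids sorted by position
    orientation_anchor: str = "unaffected-low"


def build_lfc_matrix(
    tables: Mapping[str, pd.DataFrame], features: Sequence[str]
) -> pd.DataFrame:
    """Samples x features matrix of log2 fold changes (no missing entries)."""
    features = np.asarray(features, dtype=object)
    if len(features) == 0:
        raise ValidationError("empty feature list for the fold-change matrix")
    rows = {}
    for sample_id, table in tables.items():
        series = table.set_index("feature_id")["log2fc"]
        missing = [f for f in features if f not in series.index]
        if missing:
            raise ValidationError(
                f"sample {sample_id} is missing log2FC for feature {missing[0]}"
            )
        rows[sample_id] = series.loc[features].to_numpy()
    return pd.DataFrame.from_dict(rows, orient="index", columns=features)


def pca_samples(matrix: pd.DataFrame, n_components: int = 10) -> PCAResult:
    """Column-centred SVD-based PCA with a deterministic sign convention."""
    values = np.asarray(matrix, dtype=float)
    n_samples, n_features = values.shape
    if n_samples < 2:
        raise ValidationError("PCA needs at least 2 samples")
    max_comp = min(n_samples - 1, n_features)
    if n_components > max_comp:
        logger.warning("n_components clipped from %d to %d", n_components, max_comp)
        n_components = max_comp
    centered = values - values.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt.T[:, :n_components]
    flip = np.sign(v[np.abs(v).argmax(axis=0), np.arange(v.shape[1])])
    flip[flip == 0] = 1.0
    scores = (u[:, :n_components] * s[:n_components]) * flip
    explained = (s**2 / max(n_samples - 1, 1))[:n_components]
    return PCAResult(
        scores=scores,
        loadings=v * flip,
        explained_variance=explained,
        sample_ids=np.asarray(matrix.index, dtype=object),
    )


# ---------------------------------------------------------------- principal curve


def _polyline_project(points: np.ndarray, curve: np.ndarray):
    """Arc-length coordinate and distance of each point's nearest location
    on the polyline ``curve``."""
    seg_start = curve[:-1]
    seg_vec = curve[1:] - curve[:-1]
    seg_len = np.linalg.norm(seg_vec, axis=1)
    keep = seg_len > 0
    seg_start, seg_vec, seg_len = seg_start[keep], seg_vec[keep], seg_len[keep]
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    diff = points[:, None, :] - seg_start[None, :, :]
    t = np.einsum("psd,sd->ps", diff, seg_vec) / (seg_len**2)
    t = np.clip(t, 0.0, 1.0)
    proj = seg_start[None] + t[..., None] * seg_vec[None]
    d2 = ((points[:, None, :] - proj) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    idx = np.arange(len(points))
    lam = cum[best] + t[idx, best] * seg_len[best]
    return lam, np.sqrt(d2[idx, best])


def fit_trajectory_curve(
    points: np.ndarray,
    *,
    smooth_frac: float = 0.35,
    max_iter: int = 15,
    n_polyline: int = 200,
    tol: float = 1e-4,
) -> np.ndarray:
    """Hastie-Stuetzle principal curve through a 2-D scatter.

    Starting from the first principal component, the curve is refined by
    alternately projecting points onto the current polyline (arc-length
    parameterisation) and LOWESS-smoothing each coordinate against arc
    length.  Returns a dense ordered polyline; the procedure is
    deterministic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValidationError("principal curve expects an (n x 2) scatter")
    if pts.shape[0] < 4:
        raise ValidationError("need at least 4 samples to fit the curve")
    if np.allclose(pts, pts[0]):
        raise ValidationError("degenerate scatter: all points identical")

    center = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - center, full_matrices=False)
    lam = (pts - center) @ vt[0]
    curve = None
    prev_dist = np.inf
    for _ in range(max_iter):
        order = np.argsort(lam, kind="mergesort")
        lam_sorted = lam[order]
        # jitter exactly-tied coordinates so lowess sees increasing x
        ties = np.diff(lam_sorted) == 0
        if ties.any():
            span = max(np.ptp(lam_sorted), 1.0)
            lam_sorted = lam_sorted + np.arange(len(lam_sorted)) * (1e-9 * span)
        smoothed = np.column_stack(
            [
                lowess(
                    pts[order, d],
                    lam_sorted,
                    frac=smooth_frac,
                    it=0,
                    return_sorted=False,
                )
                for d in range(2)
            ]
        )
        # densify to a regular polyline for stable projection
        seg = np.linalg.norm(np.diff(smoothed, axis=0), axis=1)
        cum = np.concatenate([[0.0], np.cumsum(seg)])
        if cum[-1] == 0:
            curve = smoothed[:1].repeat(2, axis=0)
            break
        grid = np.linspace(0.0, cum[-1], n_polyline)
        curve = np.column_stack(
            [np.interp(grid, cum, smoothed[:, d]) for d in range(2)]
        )
        lam_new, dist = _polyline_project(pts, curve)
        mean_dist = dist.mean()
        lam = lam_new
        if abs(prev_dist - mean_dist) <= tol * max(prev_dist, 1e-12):
            break
        prev_dist = mean_dist
    return curve


def order_samples(
    curve: np.ndarray,
    pc_scores: np.ndarray,
    sample_ids: Sequence[str],
    anchor_mask: np.ndarray | None = None,
) -> tuple[pd.Series, np.ndarray]:
    """Assign each sample the arc length of its nearest curve point.

    ``anchor_mask`` marks the normal-like (unaffected/normal) samples; the
    orientation is flipped if needed so their mean position is the low
    end, making the ordering invariant to the curve's internal direction.
    """
    pts = np.asarray(pc_scores, dtype=float)[:, :2]
    sample_ids = np.asarray(sample_ids, dtype=object)
    lam, _ = _polyline_project(pts, curve)
    total = float(np.linalg.norm(np.diff(curve, axis=0), axis=1).sum())
    if anchor_mask is not None and anchor_mask.any() and (~anchor_mask).any():
        if lam[anchor_mask].mean() > lam[~anchor_mask].mean():
            lam = total - lam
    positions = pd.Series(lam, index=sample_ids, name="position")
    order = sample_ids[np.argsort(lam, kind="mergesort")]
    return positions, order


# ------------------------------------------------------------------ composition


def cell_type_fractions(labels: pd.Series, sample_of: pd.Series) -> pd.DataFrame:
    """Samples x cell-type matrix of within-sample label fractions."""
    df = pd.DataFrame({"label": pd.Series(labels), "sample": pd.Series(sample_of)})
    counts = df.groupby(["sample", "label"]).size().unstack(fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


def differential_counts_along_continuum(
    tables: Mapping[str, pd.DataFrame],
    positions: pd.Series,
    *,
    fdr_max: float = 0.05,
    lfc_min: float = 1.5,
) -> pd.DataFrame:
    """Per-sample count of significant features, ordered by position."""
    rows = []
    for sample_id, table in tables.items():
        if sample_id not in positions.index:
            logger.warning("sample %s has no continuum position; skipped", sample_id)
            continue
        n_sig = int(
            ((table["fdr"] <= fdr_max) & (table["log2fc"].abs() >= lfc_min)).sum()
        )
        rows.append((sample_id, float(positions[sample_id]), n_sig))
    out = pd.DataFrame(rows, columns=["sample_id", "position", "n_significant"])
    return out.sort_values("position").reset_index(drop=True)


def compare_fractions(
    fractions: pd.DataFrame, state_of: pd.Series, reference_state: str = "normal"
) -> pd.DataFrame:
    """Rank-sum comparison of per-sample cell-type fractions vs. the
    reference state, Bonferroni-corrected over all comparisons made."""
    state_of = pd.Series(state_of)
    states = [s for s in state_of.unique() if s != reference_state]
    ref_samples = state_of.index[state_of == reference_state]
    ref_samples = [s for s in ref_samples if s in fractions.index]
    rows = []
    for cell_type in fractions.columns:
        for state in states:
            group = [
                s for s in state_of.index[state_of == state] if s in fractions.index
            ]
            if len(group) < 2 or len(ref_samples) < 2:
                logger.warning(
                    "group %s or reference too small for %s; reporting NA", state, cell_type
                )
                rows.append((cell_type, state, np.nan))
                continue
            p = rank_sum_test(
                fractions.loc[group, cell_type].to_numpy(),
                fractions.loc[ref_samples, cell_type].to_numpy(),
            )
            rows.append((cell_type, state, p))
    out = pd.DataFrame(rows, columns=["cell_type", "state", "p"])
    tested = out["p"].notna()
    adjusted = np.full(len(out), np.nan)
    adjusted[tested.to_numpy()] = bonferroni(out.loc[tested, "p"].to_numpy())
    out["p_bonferroni"] = adjusted
    return out


def composition_trend(fractions: pd.DataFrame, positions: pd.Series) -> pd.DataFrame:
    """Spearman correlation of each cell type's fraction with position."""
    shared = [s for s in fractions.index if s in positions.index]
    if not shared:
        raise ValidationError("no samples shared between fractions and positions")
    pos = positions.loc[shared].to_numpy()
    rows = []
    for cell_type in fractions.columns:
        frac = fractions.loc[shared, cell_type].to_numpy()
        if np.ptp(frac) == 0 or np.ptp(pos) == 0:
            rows.append((cell_type, np.nan, np.nan))
            continue
        rho, p = spearmanr(frac, pos)
        rows.append((cell_type, rho, p))
    out = pd.DataFrame(rows, columns=["cell_type", "rho", "p"])
    tested = out["p"].notna()
    adjusted = np.full(len(out), np.nan)
    adjusted[tested.to_numpy()] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["fdr"] = adjusted
    return out
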