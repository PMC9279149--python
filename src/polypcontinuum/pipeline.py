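"""End-to-end orchestration of the analysis stages on one cohort.

The full route mirrors the published workflow: QC filtering, normal
epithelial reference construction (iterative LSI), projection and 25-NN
labelling of diseased cells, per-sample stem-cell differentials against
the normal background, continuum ordering, program clustering with motif
enrichment, and methylation concordance.  Each stage is also callable on
its own; this module only wires them together with shared defaults scaled
to the synthetic cohort (min_cells=50 instead of the full-cohort 250,
matching the smaller per-sample cell counts of the generator).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import continuum as ct
from . import differential as diff
from . import methylation as meth
from . import programs as prog
from .core import CountsMatrix, SampleTable
from .lsi import (
    IterativeLSIParams,
    LSIModel,
    fit_iterative_lsi,
    knn_label_transfer,
    project_cells,
)
from .simulate import SimConfig, SimulatedCohort, generate_methylation

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    min_cells: int = 50
    max_cells_per_group: int | None = 300
    fdr_max: float = 0.05
    lfc_min: float = 1.5
    min_samples: int = 2
    n_program_clusters: int = 10
    background_states: tuple = ("normal",)
    label_source: str = "truth"  # or "projection"
    lsi: IterativeLSIParams = field(
        default_factory=lambda: IterativeLSIParams(
            n_var_features=5000, n_dims=15, resolutions=(0.1, 0.1, 0.2)
        )
    )
    knn_k: int = 25
    seed: int = 0


@dataclass
class PipelineResult:
    labels: pd.Series
    model: LSIModel | None
    tables: dict
    excluded: list
    features: np.ndarray
    continuum: ct.ContinuumResult
    clusters: prog.ProgramClusters | None
    enrichment: dict | None


def transfer_labels(
    counts: CountsMatrix,
    samples: SampleTable,
    truth_labels: pd.Series,
    lsi_params: IterativeLSIParams,
    k: int = 25,
    seed: int = 0,
) -> tuple[pd.Series, LSIModel]:
    """Fit the normal reference and label every cell by 25-NN transfer.

    Reference cells keep their annotations; all other cells get the modal
    label of their nearest reference neighbours in the frozen subspace.
    """
    normal_samples = set(samples.samples_in_state("normal"))
    is_ref = counts.sample_of.isin(normal_samples).to_numpy()
    ref = counts.subset_cells(is_ref)
    model = fit_iterative_lsi(
        ref,
        lsi_params,
        seed=seed,
        labels=pd.Series(truth_labels).loc[ref.barcodes].to_numpy(),
    )
    query = counts.subset_cells(~is_ref)
    emb = project_cells(model, query)
    q_labels, _ = knn_label_transfer(model, emb, k=k)
    labels = pd.Series(index=counts.barcodes, dtype=object)
    labels.loc[ref.barcodes] = pd.Series(truth_labels).loc[ref.barcodes].to_numpy()
    labels.loc[query.barcodes] = q_labels
    return labels, model


def run_continuum_pipeline(
    cohort: SimulatedCohort, params: PipelineParams | None = None
) -> PipelineResult:
    """Differentials -> recurrent features -> PCA -> principal curve -> order."""
    params = params or PipelineParams()
    if params.label_source == "projection":
        labels, model = transfer_labels(
            cohort.atac,
            cohort.samples,
            cohort.truth.cell_labels,
            params.lsi,
            k=params.knn_k,
            seed=params.seed,
        )
    else:
        labels, model = cohort.truth.cell_labels, None

    tables, excluded = diff.per_sample_differentials(
        cohort.atac,
        labels,
        cohort.samples,
        target_type="stem",
        background_states=params.background_states,
        params=diff.DifferentialParams(
            min_cells=params.min_cells,
            max_cells_per_group=params.max_cells_per_group,
            seed=params.seed,
        ),
    )
    features = diff.select_recurrent_features(
        tables, params.fdr_max, params.lfc_min, params.min_samples
    )
    used_fallback = len(features) < 2
    if used_fallback:
        logger.warning(
            "only %d recurrent differential features; using all features "
            "(no stable continuum expected)",
            len(features),
        )
        features = next(iter(tables.values()))["feature_id"].to_numpy(dtype=object)
    lfc = ct.build_lfc_matrix(tables, features)
    pca = ct.pca_samples(lfc, n_components=min(10, len(lfc) - 1))
    curve = ct.fit_trajectory_curve(pca.scores[:, :2])
    state_of = cohort.samples.state_of()
    unit_states = _unit_states(lfc.index, state_of, cohort.samples)
    anchor = np.asarray([unit_states[s] in ("normal", "unaffected") for s in lfc.index])
    positions, order = ct.order_samples(curve, pca.scores, lfc.index, anchor)

    result = ct.ContinuumResult(
        features_used=features,
        lfc_matrix=lfc,
        pca=pca,
        curve=curve,
        positions=positions,
        order=order,
    )
    clusters = enrichment = None
    if not used_fallback and len(features) >= params.n_program_clusters:
        clusters = prog.kmeans_cluster(
            lfc.T, k=params.n_program_clusters, seed=params.seed
        )
        if cohort.motifs.membership.shape[0]:
            enrichment = prog.enrichment_by_cluster(clusters, cohort.motifs)
    return PipelineResult(
        labels=labels,
        model=model,
        tables=tables,
        excluded=excluded,
        features=features,
        continuum=result,
        clusters=clusters,
        enrichment=enrichment,
    )


def _unit_states(units, state_of: pd.Series, samples: SampleTable) -> dict:
    """Disease state of each differential unit (merged unaffected units
    inherit 'unaffected')."""
    unit_map = diff.merge_unaffected_samples(samples)
    out = {}
    for sample_id, unit in unit_map.items():
        out[unit] = state_of[sample_id]
    return out


def unit_malignancy(truth_m: pd.Series, samples: SampleTable) -> pd.Series:
    """Latent malignancy per differential unit (merged unaffected units
    take the mean of their member samples)."""
    unit_of = diff.merge_unaffected_samples(samples)
    df = pd.DataFrame({"unit": unit_of, "m": pd.Series(truth_m).loc[unit_of.index]})
    return df.groupby("unit")["m"].mean()


def cluster_directions(clusters: prog.ProgramClusters, lfc_matrix: pd.DataFrame):
    """Split program clusters into up / down sets by mean log2FC sign."""
    up, down = [], []
    for cid in range(1, clusters.k + 1):
        members = clusters.members(cid)
        mean_lfc = lfc_matrix[members].to_numpy().mean()
        (up if mean_lfc >= 0 else down).append(cid)
    return up, down


def run_methylation_stage(
    cohort: SimulatedCohort,
    result: PipelineResult,
    config: SimConfig,
    seed: int | None = None,
):
    """Differential probes, peak overlap, concordance table and sign tests."""
    beta_normal, beta_tumor, coords = generate_methylation(cohort.truth, config, seed=seed)
    probe_table = meth.differential_probes(beta_normal, beta_tumor)
    probes = coords[["probe_id", "chrom", "position"]].merge(
        probe_table[["probe_id", "class"]], on="probe_id"
    )
    overlaps = meth.overlap_probes_peaks(probes, cohort.peaks)
    up, down = cluster_directions(result.clusters, result.continuum.lfc_matrix)
    table = meth.concordance_table(overlaps, result.clusters, up, down)
    mean_lfc = pd.concat(result.tables.values()).groupby("feature_id")["log2fc"].mean()
    sign_hyper = meth.nondiff_sign_test(mean_lfc, table, overlaps, "hyper")
    sign_hypo = meth.nondiff_sign_test(mean_lfc, table, overlaps, "hypo")
    return {
        "probe_table": probe_table,
        "overlaps": overlaps,
        "concordance": table,
        "sign_hyper": sign_hyper,
        "sign_hypo": sign_hypo,
    }
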