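"""Synthetic multi-sample cohort generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes: samples from four disease states carry a latent malignancy
position m in [0, 1] (0 for normal/unaffected tissue, polyps spread over
the interval, carcinomas near 1); epithelial cell types lie on a
differentiation axis whose stem-like fraction rises with m; groups of
peaks and genes ("programs") switch accessibility/expression in stem-like
cells at staggered points along m via a logistic ramp; each program has a
driver transcription-factor motif enriched in its member peaks; and
methylation probes planted in differential peaks are anti-correlated with
the accessibility change.  Counts follow a gamma-Poisson (negative
binomial) model with log-normal per-cell depth factors.  Everything is
deterministic given the seed, and the planted truth is returned for
parameter-recovery testing.

Up-programs start at the baseline rate in normal stem cells and gain
accessibility along m; down-programs start high (baseline x 2^effect) and
fall to baseline, so total depth stays roughly balanced along the
continuum, as in real libraries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .core import (
    CellMetadata,
    CountsMatrix,
    GenomicIntervalSet,
    MotifAnnotation,
    SampleTable,
    ValidationError,
)

logger = logging.getLogger(__name__)

CELL_TYPES = (
    "stem",
    "TA",
    "enterocyte_progenitor",
    "immature_enterocyte",
    "enterocyte",
    "goblet",
)

# baseline cell-type composition at m = 0
_BASE_COMPOSITION = {
    "stem": 0.15,
    "TA": 0.20,
    "enterocyte_progenitor": 0.15,
    "immature_enterocyte": 0.15,
    "enterocyte": 0.25,
    "goblet": 0.10,
}
# per-unit-m decay of the non-stem weights (mature cells are depleted most)
_DECAY = {
    "TA": 0.0,
    "enterocyte_progenitor": 0.1,
    "immature_enterocyte": 0.4,
    "enterocyte": 0.8,
    "goblet": 0.3,
}

PEAK_WIDTH = 500


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    The defaults describe the cohort used throughout the test suite:
    40 samples (6 normal / 8 unaffected / 20 polyp / 6 CRC) x 500 cells,
    5,000 peaks and 2,000 genes, with ten staggered programs of 25 peaks
    and 12 genes each.
    """

    n_samples: Mapping[str, int] = field(
        default_factory=lambda: {"normal": 6, "unaffected": 8, "polyp": 20, "CRC": 6}
    )
    n_cells: int = 500
    n_peaks: int = 5000
    n_genes: int = 2000
    n_programs: int = 10
    peaks_per_program: int = 25
    genes_per_program: int = 12
    switch_points: np.ndarray | None = None  # default: evenly spread in (0, 1)
    program_effect: float = 3.0  # log2 units, ATAC
    program_effect_rna: float = 2.0
    ramp_steepness: float = 25.0
    program_baseline: float = 2.0  # mean counts of a program peak in stem cells
    stem_fraction_base: float = 0.15
    stem_fraction_slope: float = 0.5
    markers_per_type: int = 150
    gene_markers_per_type: int = 60
    marker_rate: float = 3.0
    background_rate: float = 0.3
    background_rate_rna: float = 0.5
    n_motifs: int = 30
    motif_enrichment_prob: float = 0.8
    motif_background_prob: float = 0.05
    ballast_peaks_per_type: int = 50
    ballast_genes_per_type: int = 25
    n_probes: int = 1000
    probe_anticorr_prob: float = 0.99
    probe_null: bool = False  # classes independent of accessibility direction
    n_weak_peaks: int = 300
    weak_effect: float = 0.8
    n_meth_samples: int = 20
    beta_low: float = 0.25
    beta_high: float = 0.65
    beta_none: float = 0.45
    beta_kappa: float = 150.0  # Beta-noise concentration (sd ~ 0.04)
    n_links: int = 60
    link_window: int = 10_000  # TSS offset of a linked gene from its peak
    depth_sigma: float = 0.35
    nb_dispersion: float = 0.5
    doublet_frac: float = 0.0
    qc_fail: Mapping[str, float] = field(
        default_factory=lambda: {
            "tss": 0.05,
            "fragments": 0.05,
            "genes_low": 0.02,
            "genes_high": 0.02,
            "counts": 0.02,
            "mito": 0.04,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.switch_points is None:
            # programs alternate up/down; pairing each up-program with a
            # down-program at the same stage keeps total stem read mass
            # balanced at every point of the continuum
            if self.n_programs % 2 == 0 and self.n_programs > 0:
                stages = np.linspace(0.08, 0.92, self.n_programs // 2)
                self.switch_points = np.repeat(stages, 2)
            else:
                self.switch_points = np.linspace(0.08, 0.92, self.n_programs)
        self.switch_points = np.asarray(self.switch_points, dtype=float)
        if len(self.switch_points) != self.n_programs:
            raise ValidationError("need one switch point per program")
        if ((self.switch_points < 0) | (self.switch_points > 1)).any():
            raise ValidationError("switch points must lie in [0, 1]")
        for name in (
            "motif_enrichment_prob",
            "motif_background_prob",
            "probe_anticorr_prob",
            "doublet_frac",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValidationError(f"{name} must lie in [0, 1]")
        for name in ("n_cells", "n_peaks", "n_genes", "n_programs", "n_probes"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        layout = (
            self.n_programs * self.peaks_per_program
            + self.n_weak_peaks
            + (self.markers_per_type + self.ballast_peaks_per_type) * len(CELL_TYPES)
            + self.n_links
        )
        if self.n_peaks and self.n_peaks < layout:
            raise ValidationError(
                f"n_peaks={self.n_peaks} too small for the planted layout ({layout})"
            )
        gene_layout = (
            self.n_programs * self.genes_per_program
            + (self.gene_markers_per_type + self.ballast_genes_per_type) * len(CELL_TYPES)
            + self.n_links
        )
        if self.n_genes and self.n_genes < gene_layout:
            raise ValidationError(
                f"n_genes={self.n_genes} too small for the planted layout ({gene_layout})"
            )

    @classmethod
    def small(cls, **overrides) -> "SimConfig":
        """A reduced cohort for fast tests (same structure, smaller sizes)."""
        defaults = dict(
            n_samples={"normal": 3, "unaffected": 3, "polyp": 8, "CRC": 2},
            n_cells=200,
            n_peaks=1200,
            n_genes=600,
            n_programs=4,
            peaks_per_program=15,
            genes_per_program=8,
            markers_per_type=60,
            gene_markers_per_type=30,
            n_weak_peaks=100,
            n_probes=300,
            n_motifs=12,
            n_links=20,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class SimTruth:
    """Planted ground truth — the acceptance oracle."""

    malignancy: pd.Series  # sample -> m in [0, 1]
    cell_labels: pd.Series  # barcode -> cell type
    peak_program: pd.Series  # peak -> program id (-1 = none)
    gene_program: pd.Series
    program_direction: pd.Series  # program -> +1 (up) / -1 (down)
    switch_points: np.ndarray
    driver_motif: pd.Series  # program -> motif id
    weak_direction: pd.Series  # weak peak -> +1 / -1
    probes: pd.DataFrame  # probe_id, chrom, position, class, peak_id
    links: pd.DataFrame  # peak_id, gene_id
    expected_stem_fraction: pd.Series  # sample -> planted stem fraction

    def validate(self, peaks: GenomicIntervalSet) -> None:
        peak_ids = set(peaks.ids)
        targets = set(self.probes.loc[self.probes["peak_id"].notna(), "peak_id"])
        if not targets <= peak_ids:
            raise ValidationError("probe targets missing from the peak set")


@dataclass
class SimulatedCohort:
    atac: CountsMatrix
    rna: CountsMatrix
    samples: SampleTable
    cells: CellMetadata
    motifs: MotifAnnotation
    peaks: GenomicIntervalSet
    gene_positions: pd.DataFrame  # gene_id, chrom, tss
    truth: SimTruth


def expected_stem_fraction(config: SimConfig, m: float) -> float:
    return float(min(config.stem_fraction_base + config.stem_fraction_slope * m, 0.85))


def _composition(config: SimConfig, m: float) -> np.ndarray:
    stem = expected_stem_fraction(config, m)
    weights = np.array(
        [_BASE_COMPOSITION[t] * max(1.0 - _DECAY[t] * m, 0.02) for t in CELL_TYPES[1:]]
    )
    weights = weights / weights.sum() * (1.0 - stem)
    return np.concatenate([[stem], weights])


def _ramp(m: float, switch: float, steepness: float) -> float:
    """Logistic activation in m, re-anchored to exactly 0 at m = 0."""
    raw = 1.0 / (1.0 + np.exp(-steepness * (m - switch)))
    at0 = 1.0 / (1.0 + np.exp(steepness * switch))
    return float(np.clip((raw - at0) / (1.0 - at0), 0.0, 1.0))


def _assign_malignancy(config: SimConfig, rng: np.random.Generator) -> pd.Series:
    entries = {}
    for state in ("normal", "unaffected", "polyp", "CRC"):
        n = int(config.n_samples.get(state, 0))
        if n == 0:
            continue
        if state in ("normal", "unaffected"):
            ms = np.zeros(n)
        elif state == "polyp":
            ms = np.linspace(0.05, 0.92, n) if n > 1 else np.array([0.5])
        else:
            ms = np.linspace(0.93, 1.0, n) if n > 1 else np.array([0.97])
        for i, m in enumerate(ms):
            entries[f"{state}_{i}"] = float(m)
    return pd.Series(entries, name="malignancy")


def _build_peak_layout(config: SimConfig, rng: np.random.Generator):
    """Peak table with roles, coordinates and per-type baseline rates."""
    n_prog_peaks = config.n_programs * config.peaks_per_program
    n_marker = config.markers_per_type * len(CELL_TYPES)
    n_bg = (
        config.n_peaks
        - n_prog_peaks
        - config.n_weak_peaks
        - n_marker
        - config.n_links
        - config.ballast_peaks_per_type * len(CELL_TYPES)
    )

    rows = []
    rates = np.full((config.n_peaks, len(CELL_TYPES)), config.background_rate)
    i = 0
    for b in range(n_bg):
        rows.append((f"peak_{i:05d}", "chr1", 1000 + b * 5000, "background", -1, 0, ""))
        i += 1
    for pg in range(config.n_programs):
        direction = 1 if pg % 2 == 0 else -1
        for j in range(config.peaks_per_program):
            k = pg * config.peaks_per_program + j
            rows.append((f"peak_{i:05d}", "chr2", 1000 + k * 5000, "program", pg, direction, ""))
            base = config.program_baseline * (
                2.0**config.program_effect if direction < 0 else 1.0
            )
            rates[i, :] = config.background_rate
            rates[i, 0] = base  # stem column
            i += 1
    for w in range(config.n_weak_peaks):
        direction = 1 if w % 2 == 0 else -1
        pos = 1000 + (n_prog_peaks + w) * 5000
        rows.append((f"peak_{i:05d}", "chr2", pos, "weak", -1, direction, ""))
        base = config.program_baseline * (2.0**config.weak_effect if direction < 0 else 1.0)
        rates[i, :] = config.background_rate
        rates[i, 0] = base
        i += 1
    for ti, ctype in enumerate(CELL_TYPES):
        for j in range(config.markers_per_type):
            k = ti * config.markers_per_type + j
            rows.append((f"peak_{i:05d}", "chr3", 1000 + k * 5000, "marker", -1, 0, ctype))
            rates[i, :] = config.background_rate
            rates[i, ti] = config.marker_rate
            i += 1
    for li in range(config.n_links):
        ctype = CELL_TYPES[li % len(CELL_TYPES)]
        ti = CELL_TYPES.index(ctype)
        rows.append((f"peak_{i:05d}", "chr4", 100_000 + li * 600_000, "link", -1, 0, ctype))
        rates[i, :] = config.background_rate
        rates[i, ti] = config.marker_rate
        i += 1
    # ballast peaks equalise each type's expected read mass with the
    # stem-cell total (at m = 0), so pseudo-bulk library normalisation does
    # not induce compositional correlations among unrelated features
    nb = config.ballast_peaks_per_type
    if nb:
        totals = rates[:i].sum(axis=0)
        deficit = totals.max() - totals
        for ti, ctype in enumerate(CELL_TYPES):
            per_peak = deficit[ti] / nb
            for j in range(nb):
                pos = 1000 + (ti * nb + j) * 5000
                rows.append((f"peak_{i:05d}", "chr7", pos, "ballast", -1, 0, ctype))
                rates[i, :] = 0.0
                rates[i, ti] = per_peak
                i += 1
    table = pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "role", "program", "direction", "celltype"]
    )
    table["end"] = table["start"] + PEAK_WIDTH
    return table, rates


def _build_gene_layout(config: SimConfig, peak_table: pd.DataFrame):
    n_prog = config.n_programs * config.genes_per_program
    n_marker = config.gene_markers_per_type * len(CELL_TYPES)
    n_ballast = config.ballast_genes_per_type * len(CELL_TYPES)
    n_decoy = min(50, max(config.n_genes - n_prog - n_marker - n_ballast - config.n_links, 0))
    n_house = config.n_genes - n_prog - n_marker - n_ballast - config.n_links - n_decoy

    rows = []
    rates = np.full((config.n_genes, len(CELL_TYPES)), config.background_rate_rna)
    i = 0
    for pg in range(config.n_programs):
        direction = 1 if pg % 2 == 0 else -1
        for j in range(config.genes_per_program):
            rows.append((f"gene_{i:05d}", "chr5", 1000 + i * 3000, "program", pg, direction, ""))
            base = 1.5 * (2.0**config.program_effect_rna if direction < 0 else 1.0)
            rates[i, :] = 0.2
            rates[i, 0] = base
            i += 1
    for ti, ctype in enumerate(CELL_TYPES):
        for j in range(config.gene_markers_per_type):
            rows.append((f"gene_{i:05d}", "chr5", 1000 + i * 3000, "marker", -1, 0, ctype))
            rates[i, :] = 0.2
            rates[i, ti] = 2.5
            i += 1
    link_peaks = peak_table[peak_table["role"] == "link"].reset_index(drop=True)
    for li in range(config.n_links):
        pk = link_peaks.iloc[li]
        ti = CELL_TYPES.index(pk["celltype"])
        rows.append(
            (f"gene_{i:05d}", pk["chrom"], int(pk["start"]) + config.link_window, "link", -1, 0, pk["celltype"])
        )
        rates[i, :] = 0.2
        rates[i, ti] = 2.5
        i += 1
    bg_peaks = peak_table[peak_table["role"] == "background"].reset_index(drop=True)
    for d in range(n_decoy):
        # flat "housekeeping" profile parked near background peaks on chr1
        pos = 1500 + d * 20_000 if len(bg_peaks) else 1500 + d * 20_000
        rows.append((f"gene_{i:05d}", "chr1", pos, "decoy", -1, 0, ""))
        rates[i, :] = 1.0
        i += 1
    for h in range(n_house):
        rows.append((f"gene_{i:05d}", "chr6", 1000 + h * 3000, "housekeeping", -1, 0, ""))
        rates[i, :] = 1.0
        i += 1
    nb = config.ballast_genes_per_type
    if nb:
        totals = rates[:i].sum(axis=0)
        deficit = totals.max() - totals
        for ti, ctype in enumerate(CELL_TYPES):
            per_gene = deficit[ti] / nb
            for j in range(nb):
                rows.append(
                    (f"gene_{i:05d}", "chr8", 1000 + (ti * nb + j) * 3000, "ballast", -1, 0, ctype)
                )
                rates[i, :] = 0.0
                rates[i, ti] = per_gene
                i += 1
    return (
        pd.DataFrame(
            rows, columns=["gene_id", "chrom", "tss", "role", "program", "direction", "celltype"]
        ),
        rates,
    )


def _build_motifs(
    config: SimConfig, peak_table: pd.DataFrame, rng: np.random.Generator
) -> tuple[MotifAnnotation, pd.Series]:
    n_motifs = max(config.n_motifs, config.n_programs)
    motif_ids = np.array([f"motif_{m:03d}" for m in range(n_motifs)], dtype=object)
    membership = (
        rng.random((n_motifs, len(peak_table))) < config.motif_background_prob
    ).astype(float)
    driver = {}
    programs = peak_table["program"].to_numpy()
    for pg in range(config.n_programs):
        driver[pg] = motif_ids[pg]
        member_cols = np.flatnonzero(programs == pg)
        hit = rng.random(len(member_cols)) < config.motif_enrichment_prob
        membership[pg, member_cols] = hit.astype(float)
    annotation = MotifAnnotation(
        membership=sp.csr_matrix(membership),
        motif_ids=motif_ids,
        peak_ids=peak_table["peak_id"].to_numpy(dtype=object),
    )
    return annotation, pd.Series(driver, name="driver_motif")


def _plant_probes(
    config: SimConfig, peak_table: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    """Place probes on program peaks, weak peaks, marker peaks and
    intergenic positions; classes anti-correlate with accessibility."""
    prog = peak_table[peak_table["role"] == "program"].reset_index(drop=True)
    weak = peak_table[peak_table["role"] == "weak"].reset_index(drop=True)
    marker = peak_table[peak_table["role"] == "marker"].reset_index(drop=True)
    n = config.n_probes
    n_strong = min(n * 3 // 10, len(prog) * 2)
    n_weakp = min(n * 3 // 10, len(weak))
    n_marker = min(n * 2 // 10, len(marker))
    n_intergenic = n - n_strong - n_weakp - n_marker

    def _class_for(direction: int) -> str:
        if config.probe_null:
            return "hypo" if rng.random() < 0.5 else "hyper"
        concordant = rng.random() < config.probe_anticorr_prob
        if direction > 0:  # accessibility gained -> methylation lost
            return "hypo" if concordant else "hyper"
        return "hyper" if concordant else "hypo"

    rows = []
    pid = 0
    for j in range(n_strong):
        pk = prog.iloc[j % len(prog)]
        offset = int(rng.integers(10, PEAK_WIDTH - 10))
        rows.append(
            (f"probe_{pid:05d}", pk["chrom"], int(pk["start"]) + offset,
             _class_for(int(pk["direction"])), pk["peak_id"])
        )
        pid += 1
    for j in range(n_weakp):
        pk = weak.iloc[j % len(weak)]
        offset = int(rng.integers(10, PEAK_WIDTH - 10))
        rows.append(
            (f"probe_{pid:05d}", pk["chrom"], int(pk["start"]) + offset,
             _class_for(int(pk["direction"])), pk["peak_id"])
        )
        pid += 1
    for j in range(n_marker):
        pk = marker.iloc[j % len(marker)]
        offset = int(rng.integers(10, PEAK_WIDTH - 10))
        rows.append(
            (f"probe_{pid:05d}", pk["chrom"], int(pk["start"]) + offset, "none", pk["peak_id"])
        )
        pid += 1
    for j in range(max(n_intergenic, 0)):
        # chr1 gaps: peaks occupy [1000, 1500) mod 5000, probes stay in [1600, 4600)
        pos = 1600 + j * 5000 + int(rng.integers(0, 3000))
        rows.append((f"probe_{pid:05d}", "chr1", pos, "none", None))
        pid += 1
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "position", "class", "peak_id"])


def _nb_counts(
    lam: np.ndarray, dispersion: float, rng: np.random.Generator
) -> np.ndarray:
    if dispersion <= 0:
        return rng.poisson(lam)
    # gamma-Poisson mixture == negative binomial with shape 1/dispersion
    shape = 1.0 / dispersion
    p = shape / (shape + lam)
    return rng.negative_binomial(shape, p)


def generate_cohort(config: SimConfig | None = None) -> SimulatedCohort:
    """Generate the full synthetic cohort plus planted ground truth."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)

    malignancy = _assign_malignancy(config, rng)
    for state in ("normal", "unaffected", "polyp", "CRC"):
        if int(config.n_samples.get(state, 0)) == 0:
            logger.warning(
                "no %s samples in the cohort; downstream stages using that "
                "state (e.g. as a background) will fail",
                state,
            )
    sample_ids = malignancy.index.to_numpy(dtype=object)
    states = pd.Series(
        [s.rsplit("_", 1)[0] for s in sample_ids], index=sample_ids, dtype=object
    )
    sample_df = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "donor_id": [f"donor_{i % 8}" for i in range(len(sample_ids))],
            "disease_state": states.to_numpy(),
            "region": [("ascending", "transverse", "descending")[i % 3] for i in range(len(sample_ids))],
        }
    )

    if len(sample_ids) == 0 or config.n_cells == 0 or config.n_peaks == 0:
        return _empty_cohort(config, sample_df, malignancy)

    peak_table, peak_rates = _build_peak_layout(config, rng)
    gene_table, gene_rates = _build_gene_layout(config, peak_table)
    motifs, driver = _build_motifs(config, peak_table, rng)
    probes = _plant_probes(config, peak_table, rng)

    prog_peak_rows = {
        pg: np.flatnonzero((peak_table["program"] == pg).to_numpy())
        for pg in range(config.n_programs)
    }
    weak_rows = np.flatnonzero((peak_table["role"] == "weak").to_numpy())
    weak_dirs = peak_table.loc[weak_rows, "direction"].to_numpy()
    prog_gene_rows = {
        pg: np.flatnonzero((gene_table["program"] == pg).to_numpy())
        for pg in range(config.n_programs)
    }
    directions = pd.Series(
        {pg: (1 if pg % 2 == 0 else -1) for pg in range(config.n_programs)},
        name="direction",
    )

    atac_blocks, rna_blocks = [], []
    barcodes, bc_sample, bc_label = [], [], []
    qc_rows = []
    doublet_flags = []
    for sample in sample_ids:
        m = float(malignancy[sample])
        comp = _composition(config, m)
        type_idx = rng.choice(len(CELL_TYPES), size=config.n_cells, p=comp)
        depth = rng.lognormal(0.0, config.depth_sigma, size=config.n_cells)

        lam_peak = peak_rates[:, type_idx] * depth[None, :]
        lam_gene = gene_rates[:, type_idx] * depth[None, :]
        stem_cols = np.flatnonzero(type_idx == 0)
        for pg in range(config.n_programs):
            ramp = _ramp(m, float(config.switch_points[pg]), config.ramp_steepness)
            if ramp == 0 or len(stem_cols) == 0:
                continue
            f_atac = 2.0 ** (directions[pg] * config.program_effect * ramp)
            f_rna = 2.0 ** (directions[pg] * config.program_effect_rna * ramp)
            lam_peak[np.ix_(prog_peak_rows[pg], stem_cols)] *= f_atac
            lam_gene[np.ix_(prog_gene_rows[pg], stem_cols)] *= f_rna
        if len(stem_cols) and len(weak_rows):
            ramp = _ramp(m, 0.5, config.ramp_steepness / 3)
            if ramp > 0:
                factors = 2.0 ** (weak_dirs * config.weak_effect * ramp)
                lam_peak[np.ix_(weak_rows, stem_cols)] *= factors[:, None]

        counts_peak = _nb_counts(lam_peak, config.nb_dispersion, rng)
        counts_gene = _nb_counts(lam_gene, config.nb_dispersion, rng)

        n_doublets = int(round(config.doublet_frac * config.n_cells))
        flags = np.zeros(config.n_cells, dtype=bool)
        if n_doublets:
            victims = rng.choice(config.n_cells, size=n_doublets, replace=False)
            partners = rng.integers(0, config.n_cells, size=n_doublets)
            counts_peak[:, victims] += counts_peak[:, partners]
            counts_gene[:, victims] += counts_gene[:, partners]
            flags[victims] = True
        doublet_flags.append(flags)

        atac_blocks.append(sp.csr_matrix(counts_peak.astype(np.int32)))
        rna_blocks.append(sp.csr_matrix(counts_gene.astype(np.int32)))
        bcs = [f"{sample}#cell{i:04d}" for i in range(config.n_cells)]
        barcodes.extend(bcs)
        bc_sample.extend([sample] * config.n_cells)
        bc_label.extend([CELL_TYPES[t] for t in type_idx])
        qc_rows.append(_qc_fields(config, rng, config.n_cells))

    barcodes = np.array(barcodes, dtype=object)
    sample_of = pd.Series(bc_sample, index=barcodes)
    atac = CountsMatrix(
        values=sp.hstack(atac_blocks, format="csr"),
        feature_ids=peak_table["peak_id"].to_numpy(dtype=object),
        feature_kind="peak",
        barcodes=barcodes,
        sample_of=sample_of,
    )
    rna = CountsMatrix(
        values=sp.hstack(rna_blocks, format="csr"),
        feature_ids=gene_table["gene_id"].to_numpy(dtype=object),
        feature_kind="gene",
        barcodes=barcodes,
        sample_of=sample_of,
    )
    qc = pd.concat(qc_rows, ignore_index=True)
    cells = CellMetadata(
        pd.DataFrame(
            {
                "barcode": barcodes,
                "sample_id": bc_sample,
                "tss_enrichment": qc["tss_enrichment"].to_numpy(),
                "n_fragments": qc["n_fragments"].to_numpy(),
                "n_genes": qc["n_genes"].to_numpy(),
                "total_counts": qc["total_counts"].to_numpy(),
                "pct_mito": qc["pct_mito"].to_numpy(),
                "label": bc_label,
                "doublet_flag": np.concatenate(doublet_flags),
            }
        )
    )
    peaks = GenomicIntervalSet(
        peak_table.rename(columns={"peak_id": "id"})[["chrom", "start", "end", "id"]]
    )
    truth = SimTruth(
        malignancy=malignancy,
        cell_labels=pd.Series(bc_label, index=barcodes),
        peak_program=pd.Series(
            peak_table["program"].to_numpy(), index=peak_table["peak_id"].to_numpy()
        ),
        gene_program=pd.Series(
            gene_table["program"].to_numpy(), index=gene_table["gene_id"].to_numpy()
        ),
        program_direction=directions,
        switch_points=config.switch_points.copy(),
        driver_motif=driver,
        weak_direction=pd.Series(
            weak_dirs, index=peak_table.loc[weak_rows, "peak_id"].to_numpy()
        ),
        probes=probes,
        links=pd.DataFrame(
            {
                "peak_id": peak_table.loc[peak_table["role"] == "link", "peak_id"].to_numpy(),
                "gene_id": gene_table.loc[gene_table["role"] == "link", "gene_id"].to_numpy(),
            }
        ),
        expected_stem_fraction=pd.Series(
            {s: expected_stem_fraction(config, float(malignancy[s])) for s in sample_ids}
        ),
    )
    truth.validate(peaks)
    return SimulatedCohort(
        atac=atac,
        rna=rna,
        samples=SampleTable(sample_df),
        cells=cells,
        motifs=motifs,
        peaks=peaks,
        gene_positions=gene_table[["gene_id", "chrom", "tss"]].copy(),
        truth=truth,
    )


def _qc_fields(config: SimConfig, rng: np.random.Generator, n: int) -> pd.DataFrame:
    rates = {
        k: config.qc_fail.get(k, 0.0)
        for k in ("tss", "fragments", "genes_low", "genes_high", "counts", "mito")
    }
    fail = {k: rng.random(n) < v for k, v in rates.items()}
    tss = np.clip(rng.normal(8.0, 1.5, n), 4.05, None)
    tss[fail.get("tss", np.zeros(n, bool))] = rng.uniform(0.5, 3.9, int(fail["tss"].sum()))
    frag = np.clip(rng.lognormal(9.0, 0.4, n), 3100, None).astype(int)
    frag[fail.get("fragments", np.zeros(n, bool))] = rng.integers(
        500, 2999, int(fail["fragments"].sum())
    )
    genes = rng.integers(500, 3500, n)
    genes[fail["genes_low"]] = rng.integers(50, 399, int(fail["genes_low"].sum()))
    genes[fail["genes_high"]] = rng.integers(4001, 8000, int(fail["genes_high"].sum()))
    counts = rng.integers(1500, 9500, n)
    counts[fail["counts"]] = rng.integers(10001, 30000, int(fail["counts"].sum()))
    mito = rng.uniform(0.2, 4.8, n)
    mito[fail["mito"]] = rng.uniform(5.1, 20.0, int(fail["mito"].sum()))
    return pd.DataFrame(
        {
            "tss_enrichment": tss,
            "n_fragments": frag,
            "n_genes": genes,
            "total_counts": counts,
            "pct_mito": mito,
        }
    )


def _empty_cohort(
    config: SimConfig, sample_df: pd.DataFrame, malignancy: pd.Series
) -> SimulatedCohort:
    if not len(sample_df):
        logger.warning("cohort has zero samples; downstream stages will have no input")
    empty_bc = np.array([], dtype=object)
    empty_sample_of = pd.Series(np.array([], dtype=object), index=empty_bc)
    atac = CountsMatrix(
        values=sp.csr_matrix((config.n_peaks, 0), dtype=np.int32),
        feature_ids=np.array([f"peak_{i:05d}" for i in range(config.n_peaks)], dtype=object),
        feature_kind="peak",
        barcodes=empty_bc,
        sample_of=empty_sample_of,
    )
    rna = CountsMatrix(
        values=sp.csr_matrix((config.n_genes, 0), dtype=np.int32),
        feature_ids=np.array([f"gene_{i:05d}" for i in range(config.n_genes)], dtype=object),
        feature_kind="gene",
        barcodes=empty_bc,
        sample_of=empty_sample_of,
    )
    cells = CellMetadata(
        pd.DataFrame(
            {
                "barcode": empty_bc,
                "sample_id": np.array([], dtype=object),
                "tss_enrichment": np.array([]),
                "n_fragments": np.array([], dtype=int),
                "n_genes": np.array([], dtype=int),
                "total_counts": np.array([], dtype=int),
                "pct_mito": np.array([]),
                "label": np.array([], dtype=object),
                "doublet_flag": np.array([], dtype=bool),
            }
        )
    )
    peaks = GenomicIntervalSet(
        pd.DataFrame(
            {
                "chrom": ["chr1"] * config.n_peaks,
                "start": np.arange(config.n_peaks) * 5000 + 1000,
                "end": np.arange(config.n_peaks) * 5000 + 1000 + PEAK_WIDTH,
                "id": atac.feature_ids,
            }
        )
        if config.n_peaks
        else pd.DataFrame(columns=["chrom", "start", "end", "id"])
    )
    motifs = MotifAnnotation(
        membership=sp.csr_matrix((0, config.n_peaks)),
        motif_ids=np.array([], dtype=object),
        peak_ids=atac.feature_ids,
    )
    truth = SimTruth(
        malignancy=malignancy,
        cell_labels=pd.Series(np.array([], dtype=object), index=empty_bc),
        peak_program=pd.Series(-1, index=atac.feature_ids),
        gene_program=pd.Series(-1, index=rna.feature_ids),
        program_direction=pd.Series(dtype=int),
        switch_points=config.switch_points.copy(),
        driver_motif=pd.Series(dtype=object),
        weak_direction=pd.Series(dtype=float),
        probes=pd.DataFrame(columns=["probe_id", "chrom", "position", "class", "peak_id"]),
        links=pd.DataFrame(columns=["peak_id", "gene_id"]),
        expected_stem_fraction=pd.Series(dtype=float),
    )
    return SimulatedCohort(
        atac=atac,
        rna=rna,
        samples=SampleTable(sample_df),
        cells=cells,
        motifs=motifs,
        peaks=peaks,
        gene_positions=pd.DataFrame(columns=["gene_id", "chrom", "tss"]),
        truth=truth,
    )


def generate_methylation(
    truth: SimTruth, config: SimConfig, seed: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Beta-value matrices for 'normal' and 'tumor' methylation groups.

    Hyper probes have a planted tumor-minus-normal mean difference of
    ``beta_high - beta_low``, hypo probes the mirror image, none-class
    probes share one mean; Beta-distributed noise keeps values in [0, 1].
    Returns ``(beta_normal, beta_tumor, probe_coordinates)``.
    """
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    probes = truth.probes
    n = len(probes)
    n_samp = config.n_meth_samples

    mean_normal = np.full(n, config.beta_none)
    mean_tumor = np.full(n, config.beta_none)
    cls = probes["class"].to_numpy()
    mean_normal[cls == "hyper"] = config.beta_low
    mean_tumor[cls == "hyper"] = config.beta_high
    mean_normal[cls == "hypo"] = config.beta_high
    mean_tumor[cls == "hypo"] = config.beta_low

    def _draw(means: np.ndarray) -> pd.DataFrame:
        k = config.beta_kappa
        if k <= 0:
            vals = np.tile(means[:, None], (1, n_samp))
        else:
            a = means[:, None] * k
            b = (1.0 - means[:, None]) * k
            vals = rng.beta(np.broadcast_to(a, (n, n_samp)), np.broadcast_to(b, (n, n_samp)))
        return pd.DataFrame(
            vals,
            index=probes["probe_id"].to_numpy(),
            columns=[f"s{j}" for j in range(n_samp)],
        )

    beta_normal = _draw(mean_normal)
    beta_tumor = _draw(mean_tumor)
    coords = probes[["probe_id", "chrom", "position", "class", "peak_id"]].copy()
    return beta_normal, beta_tumor, coords
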