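"""Synthetic study generator with known ground truth.

Emulates the structure of a two-library 5'-UMI blood transcriptome study:
negative-binomial gene counts with overdispersion, spike-ins with known
nominal concentrations carrying technical noise only, gene x library
multiplicative batch bias, correlated "pathway program" shifts in the case
(PE) group, planted single-gene biomarkers with specified separability, and
a clinical covariate table mirroring the cohort structure.

All randomness derives from one integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, GeneSet, GeneSetCollection

LOG2 = np.log(2.0)

#: circulating blood cell types used as default reference labels (24) plus
#: progenitor labels that marker derivation is expected to blacklist.
CIRCULATING_CELL_TYPES = (
    "erythrocytes", "reticulocytes", "platelets", "basophils", "eosinophils",
    "progenitor_neutrophils", "myelocytes", "metamyelocytes",
    "band_neutrophils", "mature_neutrophils", "classical_monocytes",
    "intermediate_monocytes", "nonclassical_monocytes", "myeloid_DC",
    "plasmacytoid_DC", "naive_B_cells", "memory_B_cells", "regulatory_B_cells",
    "plasma_cells", "naive_CD4_T_cells", "memory_CD4_T_cells", "CD8_T_cells",
    "NK_cells", "gamma_delta_T_cells",
)
PROGENITOR_CELL_TYPES = (
    "hematopoietic_stem_cells", "common_myeloid_progenitors",
    "megakaryocyte_erythroid_progenitors", "multipotent_progenitors",
)


@dataclass(frozen=True)
class PlantedPathway:
    set_id: str
    n_members: int
    log2_shift: float  # mean log2 shift of member genes in PE


@dataclass(frozen=True)
class PlantedBiomarker:
    gene_id: str  # resolved gene id, or "" to auto-assign
    delta: float  # standardized shift on the normalized-log scale


@dataclass
class SimulationConfig:
    n_samples_pe: int = 12
    n_samples_np: int = 52
    n_genes: int = 12000
    n_spikeins: int = 97
    library_fraction: float = 0.5  # fraction of samples assigned to library 2
    bias_sd: float = 0.25  # sd of gene-wise log2 library-bias factors
    dispersion: float | None = None  # fixed NB dispersion; None = draw per gene
    dispersion_range: tuple[float, float] = (0.01, 0.5)
    spikein_dispersion: float = 0.005
    planted_pathways: tuple[PlantedPathway, ...] = ()
    planted_biomarkers: tuple[PlantedBiomarker, ...] = ()
    n_decoy_sets: int = 50
    decoy_set_size: int = 30
    pathway_jitter_sd: float = 0.1  # gene-wise jitter on the planted shift (log2)
    pathway_latent_sd: float = 0.3  # per-sample program-activity sd (log2)
    spikein_concentrations: np.ndarray | None = None
    depth_range: tuple[float, float] = (0.7, 1.4)
    base_mean_log_mu: float = 3.0  # natural-log params of gene base means
    base_mean_log_sd: float = 1.3
    planted_gene_mean_range: tuple[float, float] = (150.0, 400.0)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_samples_pe", "n_samples_np", "n_genes", "n_spikeins"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v <= 0:
                raise ValueError(f"{name} must be a positive integer, got {v!r}")
        if self.bias_sd < 0:
            raise ValueError("bias_sd must be >= 0")
        if not (0 <= self.library_fraction <= 1):
            raise ValueError("library_fraction must be in [0, 1]")
        if self.depth_range[0] <= 0:
            raise ValueError("depth multipliers must be > 0")
        n_planted = sum(p.n_members for p in self.planted_pathways)
        n_planted += len(self.planted_biomarkers)
        if n_planted > self.n_genes:
            raise ValueError("planted genes exceed n_genes")
        for p in self.planted_pathways:
            if p.n_members > self.n_genes:
                raise ValueError(f"pathway {p.set_id}: member count > n_genes")


@dataclass
class GroundTruth:
    """Everything planted, recorded for recovery tests."""

    true_bias_factors: pd.DataFrame  # genes x {library1, library2}, log2
    true_fluctuating_genes: set[str]  # genes with planted excess biological variation
    pathway_direction: dict[str, str]  # set id -> "up" / "down" in PE
    pathway_members: dict[str, tuple[str, ...]] = field(default_factory=dict)
    biomarker_auc_expected: dict[str, float] = field(default_factory=dict)
    biomarker_delta: dict[str, float] = field(default_factory=dict)
    depths: pd.Series | None = None
    base_means: pd.Series | None = None

    def __post_init__(self):
        for g, a in self.biomarker_auc_expected.items():
            if not (0.5 <= a <= 1.0):
                raise ValueError(f"expected AUC for {g} outside [0.5, 1]: {a}")


def default_spikein_concentrations(n: int) -> np.ndarray:
    """Nominal molecule counts spanning ~4 decades, like a spike-in mix."""
    return np.geomspace(0.5, 5000.0, n)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mean mu, variance mu + alpha*mu^2) counts; alpha == 0 is Poisson."""
    mu = np.asarray(mu, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    pois = alpha <= 0
    if pois.any():
        out[pois] = rng.poisson(mu[pois])
    if (~pois).any():
        r = 1.0 / alpha[~pois]
        p = r / (r + mu[~pois])
        out[~pois] = rng.negative_binomial(r, p)
    return out


def generate_dataset(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, GeneSetCollection, GroundTruth]:
    """Generate counts, metadata, gene sets, and ground truth.

    Non-spike-in gene g in library l and sample s has NB expectation
    ``base_g * depth_s * 2**bias(g,l) * 2**effect(g,s)`` where the effect
    carries planted pathway and biomarker shifts; spike-in rows have
    expectation ``concentration_g * depth_s`` with technical noise only.
    For a planted biomarker with standardized shift delta under the
    equal-variance binormal model the expected AUC is ``Phi(delta/sqrt(2))``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    n = cfg.n_samples_pe + cfg.n_samples_np
    sample_ids = pd.Index([f"S{i + 1:03d}" for i in range(n)], name="sample_id")
    is_pe = np.zeros(n, dtype=bool)
    is_pe[: cfg.n_samples_pe] = True

    # library assignment, stratified by condition so the layout is balanced
    library = np.ones(n, dtype=np.int64)
    for mask in (is_pe, ~is_pe):
        idx = np.flatnonzero(mask)
        k = int(round(len(idx) * cfg.library_fraction))
        library[rng.choice(idx, size=k, replace=False)] = 2

    depths = rng.uniform(*cfg.depth_range, size=n)

    gene_ids = pd.Index(
        [f"ERCC-{i + 1:05d}" for i in range(cfg.n_spikeins)]
        + [f"GENE{i + 1:05d}" for i in range(cfg.n_genes)],
        name="gene_id",
    )
    is_spike = np.zeros(len(gene_ids), dtype=bool)
    is_spike[: cfg.n_spikeins] = True
    bio_ids = gene_ids[~is_spike]

    conc = cfg.spikein_concentrations
    if conc is None:
        conc = default_spikein_concentrations(cfg.n_spikeins)
    conc = np.asarray(conc, dtype=float)
    if conc.shape != (cfg.n_spikeins,):
        raise ValueError("spikein_concentrations length != n_spikeins")

    base = rng.lognormal(cfg.base_mean_log_mu, cfg.base_mean_log_sd, cfg.n_genes)
    if cfg.dispersion is not None:
        alpha = np.full(cfg.n_genes, float(cfg.dispersion))
    else:
        lo, hi = cfg.dispersion_range
        alpha = np.exp(rng.uniform(np.log(lo), np.log(hi), cfg.n_genes))

    bias_log2 = rng.normal(0.0, cfg.bias_sd, cfg.n_genes) if cfg.bias_sd > 0 \
        else np.zeros(cfg.n_genes)

    # --- reserve disjoint gene blocks for planted effects -----------------
    n_reserved = sum(p.n_members for p in cfg.planted_pathways) + len(
        cfg.planted_biomarkers
    )
    reserved = rng.choice(cfg.n_genes, size=n_reserved, replace=False)
    cursor = 0
    lo, hi = cfg.planted_gene_mean_range

    effect_log2 = np.zeros((cfg.n_genes, n))  # per gene x sample log2 multiplier
    pathway_members: dict[str, tuple[str, ...]] = {}
    pathway_direction: dict[str, str] = {}
    fluctuating: set[str] = set()

    for pw in cfg.planted_pathways:
        members = reserved[cursor : cursor + pw.n_members]
        cursor += pw.n_members
        base[members] = rng.uniform(lo, hi, pw.n_members)
        jitter = rng.normal(0.0, cfg.pathway_jitter_sd, pw.n_members)
        latent = rng.normal(0.0, cfg.pathway_latent_sd, n)
        effect_log2[members] += (
            (pw.log2_shift + jitter)[:, None] * is_pe[None, :] + latent[None, :]
        )
        ids = tuple(bio_ids[members])
        pathway_members[pw.set_id] = ids
        pathway_direction[pw.set_id] = "up" if pw.log2_shift > 0 else "down"
        fluctuating.update(ids)

    planted_so_far = set(np.flatnonzero(effect_log2.any(axis=1)))
    biomarker_auc: dict[str, float] = {}
    biomarker_delta: dict[str, float] = {}
    for bm in cfg.planted_biomarkers:
        if bm.gene_id:
            if bm.gene_id not in bio_ids:
                raise ValueError(f"planted biomarker {bm.gene_id!r} is not a gene id")
            gi = bio_ids.get_loc(bm.gene_id)
            if gi in planted_so_far:
                raise ValueError(f"biomarker {bm.gene_id!r} overlaps a planted pathway")
        else:
            gi = int(reserved[cursor])
            cursor += 1
        planted_so_far.add(gi)
        base[gi] = rng.uniform(lo, hi)
        alpha[gi] = min(alpha[gi], 0.1)  # keep the log-normal approximation tight
        mu = base[gi]
        # delta-method sd of log2(count + 1) at mean mu
        sd_log2 = np.sqrt(mu + alpha[gi] * mu**2) / ((mu + 1.0) * LOG2)
        effect_log2[gi] += bm.delta * sd_log2 * is_pe
        gid = str(bio_ids[gi])
        biomarker_auc[gid] = float(stats.norm.cdf(bm.delta / np.sqrt(2.0)))
        biomarker_delta[gid] = bm.delta
        fluctuating.add(gid)

    # --- draw counts -------------------------------------------------------
    lib2 = (library == 2).astype(float)
    mu_genes = (
        base[:, None]
        * depths[None, :]
        * np.exp2(bias_log2[:, None] * lib2[None, :] + effect_log2)
    )
    gene_counts = _nb_draw(rng, mu_genes, alpha[:, None])
    mu_spikes = conc[:, None] * depths[None, :]
    spike_counts = _nb_draw(rng, mu_spikes, np.full((cfg.n_spikeins, 1), cfg.spikein_dispersion))

    counts = pd.DataFrame(
        np.vstack([spike_counts, gene_counts]), index=gene_ids, columns=sample_ids
    )
    library_s = pd.Series(library, index=sample_ids, name="library")
    cm = CountMatrix(counts, pd.Series(is_spike, index=gene_ids), library_s)

    meta = _simulate_metadata(rng, sample_ids, is_pe, library)

    # --- gene sets: planted programs + size-matched decoys ----------------
    sets = [
        GeneSet(sid, "planted program", members)
        for sid, members in pathway_members.items()
    ]
    for d in range(cfg.n_decoy_sets):
        picked = rng.choice(cfg.n_genes, size=cfg.decoy_set_size, replace=False)
        sets.append(GeneSet(f"DECOY_{d + 1:03d}", "decoy set", tuple(bio_ids[picked])))
    collection = GeneSetCollection(sets)

    bias_df = pd.DataFrame(
        {"library1": np.zeros(cfg.n_genes), "library2": bias_log2}, index=bio_ids
    )
    truth = GroundTruth(
        true_bias_factors=bias_df,
        true_fluctuating_genes=fluctuating,
        pathway_direction=pathway_direction,
        pathway_members=pathway_members,
        biomarker_auc_expected=biomarker_auc,
        biomarker_delta=biomarker_delta,
        depths=pd.Series(depths, index=sample_ids, name="depth"),
        base_means=pd.Series(base, index=bio_ids, name="base_mean"),
    )
    return cm, meta, collection, truth


def _simulate_metadata(
    rng: np.random.Generator,
    sample_ids: pd.Index,
    is_pe: np.ndarray,
    library: np.ndarray,
) -> pd.DataFrame:
    """Clinical covariates mirroring the cohort-table structure.

    Group means/SDs follow the published cohort summary so cohort-comparison
    code sees realistic contrasts (earlier delivery, lower birth weight and
    occasional obesity in the case group).
    """
    n = len(sample_ids)
    pe = is_pe.astype(float)

    def two_group(mu_pe, sd_pe, mu_np, sd_np):
        return rng.normal(mu_pe * pe + mu_np * (1 - pe), sd_pe * pe + sd_np * (1 - pe))

    bmi = np.where(
        is_pe & (rng.random(n) < 0.3),
        rng.normal(32.0, 1.5, n),  # obese stratum, cases only
        two_group(23.0, 2.0, 22.0, 1.6),
    )
    meta = pd.DataFrame(
        {
            "condition": np.where(is_pe, "PE", "NP"),
            "library": library,
            "maternal_age": np.round(two_group(35.0, 3.0, 34.0, 5.0), 1),
            "bmi": np.round(bmi, 1),
            "parity": rng.choice([0, 1, 2], size=n, p=[0.5, 0.35, 0.15]),
            "gestational_age": np.round(two_group(38.0, 1.5, 40.0, 1.3), 1),
            "child_sex": rng.choice(["male", "female"], size=n),
            "birth_weight": np.round(two_group(3100.0, 470.0, 3500.0, 360.0)),
            "rin": np.round(two_group(8.7, 0.39, 8.3, 0.49), 2),
        },
        index=sample_ids,
    )
    return meta


QC_METRICS = (
    "mapped_reads",
    "spikein_reads",
    "spikein_5prime_rate",
    "mapped_rate",
    "mapped_spikein_ratio",
    "coding_5prime_rate",
)


def simulate_qc_table(
    cm: CountMatrix, seed: int = 0, n_outliers: int = 0
) -> pd.DataFrame:
    """Per-sample QC metric table derived from the counts.

    Read-level metrics are scaled up from UMI counts; rate metrics carry
    technical noise only.  ``n_outliers`` samples (chosen at random) get a
    grossly deviant mapped-read count so outlier detection has work to do.
    """
    rng = np.random.default_rng(seed)
    spike = cm.counts.loc[cm.is_spikein.to_numpy()].sum(axis=0).to_numpy().astype(float)
    total = cm.counts.sum(axis=0).to_numpy().astype(float)
    dup = rng.uniform(2.5, 3.5, cm.n_samples)  # reads per UMI
    mapped = np.round(total * dup)
    spike_reads = np.round(spike * dup)
    qc = pd.DataFrame(
        {
            "mapped_reads": mapped,
            "spikein_reads": spike_reads,
            "spikein_5prime_rate": np.clip(rng.normal(0.85, 0.02, cm.n_samples), 0, 1),
            "mapped_rate": np.clip(rng.normal(0.80, 0.02, cm.n_samples), 0, 1),
            "mapped_spikein_ratio": mapped / np.maximum(spike_reads, 1.0),
            "coding_5prime_rate": np.clip(rng.normal(0.75, 0.02, cm.n_samples), 0, 1),
        },
        index=cm.sample_ids,
    )
    if n_outliers:
        out = rng.choice(cm.n_samples, size=n_outliers, replace=False)
        qc.iloc[out, qc.columns.get_loc("mapped_reads")] *= 0.05
        qc.iloc[out, qc.columns.get_loc("mapped_rate")] *= 0.4
    return qc


# ---------------------------------------------------------------------------
# labelled cell-type reference
# ---------------------------------------------------------------------------

@dataclass
class LabeledReference:
    """Cells x genes count matrix with one cell-type label per cell."""

    counts: pd.DataFrame  # genes x cells
    labels: pd.Series  # per cell
    marker_truth: dict[str, tuple[str, ...]]  # type -> planted marker genes

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.labels.unique())


def generate_celltype_reference(
    n_types: int = 24,
    cells_per_type: int = 30,
    markers_per_type: int = 20,
    fold: float = 2.6,
    seed: int = 0,
    n_genes: int = 2000,
    include_progenitors: int = 0,
) -> LabeledReference:
    """Reference with exactly ``markers_per_type`` genes per type whose
    expectation is ``2**fold`` above the other types.

    ``fold`` must be >= 0 (0 plants nothing).  ``include_progenitors`` adds
    that many extra progenitor-labelled types for blacklist testing.
    """
    if fold < 0:
        raise ValueError("fold must be >= 0")
    total_types = n_types + include_progenitors
    if markers_per_type * total_types > n_genes:
        raise ValueError("markers_per_type * n_types exceeds n_genes")
    rng = np.random.default_rng(seed)

    names = list(CIRCULATING_CELL_TYPES[:n_types])
    names += [f"celltype_{i + 1:02d}" for i in range(n_types - len(names))]
    names += list(PROGENITOR_CELL_TYPES[:include_progenitors])

    gene_ids = pd.Index([f"GENE{i + 1:05d}" for i in range(n_genes)], name="gene_id")
    base = rng.lognormal(1.0, 1.0, n_genes)
    alpha = np.full(n_genes, 0.15)

    labels = np.repeat(names, cells_per_type)
    n_cells = len(labels)
    cell_ids = pd.Index([f"C{i + 1:04d}" for i in range(n_cells)], name="cell_id")
    depth = rng.uniform(0.8, 1.2, n_cells)

    marker_truth: dict[str, tuple[str, ...]] = {}
    order = rng.permutation(n_genes)
    # planted markers need enough base expression that the downstream
    # pseudocount does not swallow the fold change
    n_marked = markers_per_type * len(names)
    base[order[:n_marked]] = rng.uniform(5.0, 50.0, n_marked)
    mu = base[:, None] * depth[None, :]
    for t, name in enumerate(names):
        genes = order[t * markers_per_type : (t + 1) * markers_per_type]
        cells = np.flatnonzero(labels == name)
        if fold > 0:
            mu[np.ix_(genes, cells)] *= 2.0**fold
            marker_truth[name] = tuple(gene_ids[sorted(genes)])
        else:
            marker_truth[name] = ()

    counts = pd.DataFrame(
        _nb_draw(rng, mu, alpha[:, None]), index=gene_ids, columns=cell_ids
    )
    return LabeledReference(counts, pd.Series(labels, index=cell_ids), marker_truth)
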