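"""Synthetic WGS cohort generator with known copy-number ground truth.

The generator emulates the statistical structure the rDNA pipeline assumes,
so every downstream stage can be tested end-to-end without any sequencing
data:

* Per individual, total 5S and 45S array copies per cell are lognormal with
  a configurable correlation (concerted CNV across genotypes; natural
  variation spans roughly an order of magnitude at the default log-sd).
* Each patient contributes a "tumor" and an "adjacent" sample.  Tumor rDNA
  copies are the adjacent copies times a lognormal fold change whose medians
  (``tumor_5s_gain_mean``, ``tumor_45s_loss_mean``) encode the recurrent 5S
  expansion / 45S loss phenotype; a simulated driver mutation shifts the log
  fold changes further (+ for 5S, - for 45S).
* Observed depth at every base of a locus carrying k copies per cell is
  Poisson(per_copy_depth x k x site_rate x batch_multiplier).  Background
  genes carry k = 2 + C where C is the GISTIC-style gene value (block
  constant along each chromosome, mimicking arm-level SCNAs); adjacent
  samples are fully diploid.
* 18S and 28S get per-(site, sample) i.i.d. lognormal depth-rate
  heterogeneity, standing in for between-individual sequence polymorphism
  and truncated repeat units; one designated 150 bp window per component is
  homogeneous (rate = 1 for everyone) and is what CV-based window selection
  should find.  5.8S and 5S are homogeneous throughout, matching their
  near-constant observed depth profiles.
* A 1q42 segmental gain (probability ``locus_1q42_gain_rate`` per tumor)
  multiplies true 5S copies by its ploidy ratio and is visible in the ploidy
  table through two flanking proxy genes (RNF187, RHOU).
* A per-tumor proliferation factor is correlated (``proliferation_coupling``)
  with the realised tumor log(5S/45S) change and drives the expression of a
  designated proliferation gene set in the RNA-seq count simulator.

Identical config (including seed) gives bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .estimate import PloidyTable
from .regions import CHROM_GROUP_45S, GenomicInterval, RegionSet

NONSILENT_CLASSES = (
    "Missense_Mutation",
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
    "In_Frame_Del",
    "In_Frame_Ins",
    "Translation_Start_Site",
    "Nonstop_Mutation",
)

#: GISTIC-style gene copy-number values drawn for aneuploid blocks
ANEUPLOIDY_C_VALUES = (-1.0, -0.5, 0.5, 1.0, 2.0)

DRIVER_GENE = "TP53"
PROXY_GENES_1Q42 = ("RNF187", "RHOU")


class ConfigurationError(ValueError):
    """Invalid simulation or pipeline configuration."""


@dataclass
class SimulationConfig:
    """All knobs of the synthetic cohort; defaults are the study conditions.

    Copy-number scale: ``cn_*_log_mean/sd`` parameterise the lognormal total
    copies per cell.  The defaults put 5S around 150 and 45S around 400
    copies with a log-sd of 0.6, i.e. a ~10-fold range across +-2 sd, the
    breadth reported for human populations.
    """

    n_patients: int = 40
    per_copy_depth: float = 15.0  # reads/base per DNA copy; 15 = 30x diploid

    cn_5s_log_mean: float = math.log(150.0)
    cn_5s_log_sd: float = 0.6
    cn_45s_log_mean: float = math.log(400.0)
    cn_45s_log_sd: float = 0.6
    ccnv_rho: float = 0.6

    tumor_5s_gain_mean: float = 1.3
    tumor_45s_loss_mean: float = 0.8
    tumor_fold_log_sd: float = 0.2

    n_batches: int = 3
    batch_sd: float = 0.1
    batch_cn_bias_sd: float = 0.0  # extra batch multiplier on rDNA loci only
    fraction_cross_plate: float = 0.1  # patients whose pair spans two plates

    site_het_sd: float = 0.3

    aneuploidy_rate: float = 0.3
    aneuploidy_block_genes: int = 4

    driver_effect: float = 0.2
    driver_mutation_rate: float = 0.5
    driver_hotspot_fraction: float = 0.4

    locus_1q42_gain_rate: float = 0.3

    proliferation_coupling: float = 0.5
    proliferation_log_sd: float = 0.3

    n_cancer_types: int = 2

    # reference layout
    component_lengths: dict = field(
        default_factory=lambda: {"18S": 1869, "5.8S": 157, "28S": 5070, "5S": 121}
    )
    homogeneous_windows: dict = field(
        default_factory=lambda: {"18S": (1145, 1294), "28S": (1522, 1671)}
    )
    n_genes_chr1: int = 24
    n_genes_per_acrocentric: int = 8
    gene_length: int = 300
    gene_gap: int = 100

    # expression simulator
    n_expression_genes: int = 300
    pri_set_size: int = 40
    nucleolar_set_size: int = 30
    crpg_set_size: int = 15
    nb_dispersion: float = 0.05

    seed: int = 0

    def __post_init__(self):
        for name, val in asdict(self).items():
            if isinstance(val, (int, float)) and not math.isfinite(val):
                raise ConfigurationError(f"{name} is not finite")
        if self.n_patients < 0:
            raise ConfigurationError("n_patients must be >= 0")
        if not -1.0 <= self.ccnv_rho <= 1.0:
            raise ConfigurationError("ccnv_rho must lie in [-1, 1]")
        if not -1.0 <= self.proliferation_coupling <= 1.0:
            raise ConfigurationError("proliferation_coupling must lie in [-1, 1]")
        for name in (
            "cn_5s_log_sd", "cn_45s_log_sd", "tumor_fold_log_sd", "batch_sd",
            "batch_cn_bias_sd", "site_het_sd", "aneuploidy_rate",
            "driver_mutation_rate", "locus_1q42_gain_rate",
            "proliferation_log_sd", "nb_dispersion", "fraction_cross_plate",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.per_copy_depth <= 0:
            raise ConfigurationError("per_copy_depth must be > 0")
        if self.tumor_5s_gain_mean <= 0 or self.tumor_45s_loss_mean <= 0:
            raise ConfigurationError("tumor fold-change means must be > 0")
        if self.n_batches < 1:
            raise ConfigurationError("n_batches must be >= 1")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort.

    ``samples`` has one row per sample with the true copies per cell (k) and
    the diploid-relative values (k/2) the depth-ratio estimator recovers, the
    batch multiplier, driver status, and proliferation factor.  ``site_rates``
    maps component name to a (samples x length) matrix of per-site depth-rate
    multipliers, ordered as ``samples``.
    """

    samples: pd.DataFrame
    site_rates: dict
    gene_sets: dict = field(default_factory=dict)


@dataclass
class SyntheticCohort:
    """Everything a pipeline run needs, plus the truth table."""

    depth_by_sample: dict
    ploidy: PloidyTable
    metadata: pd.DataFrame
    mutations: pd.DataFrame
    regions: RegionSet
    truth: CohortTruth
    config: SimulationConfig


METADATA_COLUMNS = ["sample_id", "patient_id", "tissue", "cancer_type", "plate_id"]
TRUTH_COLUMNS = [
    "sample_id", "patient_id", "tissue", "cancer_type", "plate_id",
    "true_copies_5s", "true_copies_45s", "true_cn_5s", "true_cn_45s",
    "batch_multiplier", "driver_mutation_present", "proliferation_factor",
    "c_1q42",
]
MAF_COLUMNS = [
    "Hugo_Symbol", "Variant_Classification", "Change", "Tumor_Sample_Barcode",
]


def _background_layout(config: SimulationConfig):
    """Gene intervals per chromosome; chr1 alternates exon/intron features."""
    intervals = []
    step = config.gene_length + config.gene_gap
    for i in range(config.n_genes_chr1):
        start = i * step + 1
        intervals.append(
            GenomicInterval(
                "chr1", start, start + config.gene_length - 1,
                "exon" if i % 2 == 0 else "intron", f"G1_{i:04d}",
            )
        )
    for chrom in CHROM_GROUP_45S:
        cn = chrom.removeprefix("chr")
        for i in range(config.n_genes_per_acrocentric):
            start = i * step + 1
            intervals.append(
                GenomicInterval(
                    chrom, start, start + config.gene_length - 1,
                    "exon", f"G{cn}_{i:04d}",
                )
            )
    return intervals


def _site_rates(config: SimulationConfig, rng, n_samples: int) -> dict:
    """Per-(site, sample) lognormal depth rates for 18S/28S; 1 elsewhere."""
    rates = {}
    for comp, length in config.component_lengths.items():
        mat = np.ones((n_samples, length))
        if comp in ("18S", "28S") and config.site_het_sd > 0:
            mat = rng.lognormal(0.0, config.site_het_sd, size=(n_samples, length))
            win = config.homogeneous_windows.get(comp)
            if win is not None:
                mat[:, win[0] - 1 : win[1]] = 1.0
        rates[comp] = mat
    return rates


def _empty_cohort(config: SimulationConfig) -> SyntheticCohort:
    regions = RegionSet(kept=_background_layout(config))
    return SyntheticCohort(
        depth_by_sample={},
        ploidy=PloidyTable(pd.DataFrame(index=pd.Index([], name="gene_id"))),
        metadata=pd.DataFrame(columns=METADATA_COLUMNS),
        mutations=pd.DataFrame(columns=MAF_COLUMNS),
        regions=regions,
        truth=CohortTruth(
            samples=pd.DataFrame(columns=TRUTH_COLUMNS),
            site_rates={c: np.zeros((0, l)) for c, l in config.component_lengths.items()},
        ),
        config=config,
    )


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw a full synthetic cohort under the configured generative model."""
    if config.n_patients == 0:
        return _empty_cohort(config)
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    patients = [f"P{i:04d}" for i in range(n)]
    cancer_types = [f"CT{i % config.n_cancer_types + 1}" for i in range(n)]

    # --- batches / plates -------------------------------------------------
    batch_ids = [f"plate{b + 1:02d}" for b in range(config.n_batches)]
    batch_mult = dict(
        zip(batch_ids, rng.lognormal(0.0, config.batch_sd, size=config.n_batches))
    )
    batch_rdna_bias = dict(
        zip(batch_ids,
            rng.lognormal(0.0, config.batch_cn_bias_sd, size=config.n_batches)
            if config.batch_cn_bias_sd > 0 else np.ones(config.n_batches))
    )
    patient_plate = rng.choice(batch_ids, size=n)
    cross = rng.random(n) < config.fraction_cross_plate
    adjacent_plate = patient_plate.copy()
    if config.n_batches > 1:
        shift = rng.integers(1, config.n_batches, size=n)
        for i in np.flatnonzero(cross):
            adjacent_plate[i] = batch_ids[
                (batch_ids.index(patient_plate[i]) + shift[i]) % config.n_batches
            ]

    # --- true copies ------------------------------------------------------
    cov = np.array(
        [
            [config.cn_5s_log_sd**2,
             config.ccnv_rho * config.cn_5s_log_sd * config.cn_45s_log_sd],
            [config.ccnv_rho * config.cn_5s_log_sd * config.cn_45s_log_sd,
             config.cn_45s_log_sd**2],
        ]
    )
    # svd factorisation tolerates degenerate (sd = 0 or |rho| = 1) covariances
    logk = rng.multivariate_normal(
        [config.cn_5s_log_mean, config.cn_45s_log_mean], cov, size=n,
        method="svd",
    )
    k5_adj, k45_adj = np.exp(logk[:, 0]), np.exp(logk[:, 1])

    driver = rng.random(n) < config.driver_mutation_rate
    log_f5 = rng.normal(math.log(config.tumor_5s_gain_mean),
                        config.tumor_fold_log_sd, size=n)
    log_f45 = rng.normal(math.log(config.tumor_45s_loss_mean),
                         config.tumor_fold_log_sd, size=n)
    log_f5 = log_f5 + config.driver_effect * driver
    log_f45 = log_f45 - config.driver_effect * driver

    c_1q42 = np.zeros(n)
    gained = rng.random(n) < config.locus_1q42_gain_rate
    c_1q42[gained] = rng.choice([0.5, 1.0], size=int(gained.sum()))

    k5_tum = k5_adj * np.exp(log_f5) * (2.0 + c_1q42) / 2.0
    k45_tum = k45_adj * np.exp(log_f45)

    # --- proliferation factor coupled to the tumor log-ratio change -------
    delta = (log_f5 + np.log((2.0 + c_1q42) / 2.0)) - log_f45
    z = (delta - delta.mean()) / delta.std(ddof=0) if n > 1 and delta.std() > 0 \
        else np.zeros(n)
    eps = rng.normal(size=n)
    rho_p = config.proliferation_coupling
    prolif = np.exp(
        config.proliferation_log_sd * (rho_p * z + math.sqrt(1 - rho_p**2) * eps)
    )

    # --- background aneuploidy (block-constant GISTIC C per tumor) --------
    regions_list = _background_layout(config)
    regions = RegionSet(kept=list(regions_list))
    gene_ids = [iv.gene_id for iv in regions_list]
    gene_chrom = {iv.gene_id: iv.chrom for iv in regions_list}
    tumor_samples = [f"{p}-T" for p in patients]
    c_by_gene = pd.DataFrame(
        0.0, index=pd.Index(gene_ids + list(PROXY_GENES_1Q42), name="gene_id"),
        columns=tumor_samples,
    )
    by_chrom: dict[str, list[str]] = {}
    for g in gene_ids:
        by_chrom.setdefault(gene_chrom[g], []).append(g)
    for j, ts in enumerate(tumor_samples):
        for chrom, genes in by_chrom.items():
            for b0 in range(0, len(genes), config.aneuploidy_block_genes):
                if rng.random() < config.aneuploidy_rate:
                    c = rng.choice(ANEUPLOIDY_C_VALUES)
                    for g in genes[b0 : b0 + config.aneuploidy_block_genes]:
                        c_by_gene.at[g, ts] = c
        for g in PROXY_GENES_1Q42:
            c_by_gene.at[g, ts] = c_1q42[j]
    gene_info = pd.DataFrame(
        {
            "Locus ID": np.arange(len(c_by_gene.index)) + 1,
            "Cytoband": [
                "1q42.13" if g in PROXY_GENES_1Q42
                else f"{gene_chrom.get(g, 'chr1').removeprefix('chr')}q11"
                for g in c_by_gene.index
            ],
        },
        index=c_by_gene.index,
    )
    ploidy = PloidyTable(c_by_gene, gene_info=gene_info)

    # --- site rates (fixed per sample, shared order with metadata) --------
    site_rates = _site_rates(config, rng, 2 * n)

    # --- metadata / truth -------------------------------------------------
    meta_rows, truth_rows = [], []
    sample_order = []
    for i, p in enumerate(patients):
        for tissue, plate, k5, k45, pf in (
            ("tumor", patient_plate[i], k5_tum[i], k45_tum[i], prolif[i]),
            ("adjacent", adjacent_plate[i], k5_adj[i], k45_adj[i], 1.0),
        ):
            sid = f"{p}-{'T' if tissue == 'tumor' else 'A'}"
            sample_order.append(sid)
            meta_rows.append(
                dict(sample_id=sid, patient_id=p, tissue=tissue,
                     cancer_type=cancer_types[i], plate_id=plate)
            )
            truth_rows.append(
                dict(
                    sample_id=sid, patient_id=p, tissue=tissue,
                    cancer_type=cancer_types[i], plate_id=plate,
                    true_copies_5s=k5, true_copies_45s=k45,
                    true_cn_5s=k5 / 2.0, true_cn_45s=k45 / 2.0,
                    batch_multiplier=batch_mult[plate],
                    driver_mutation_present=bool(driver[i]) and tissue == "tumor",
                    proliferation_factor=pf,
                    c_1q42=c_1q42[i] if tissue == "tumor" else 0.0,
                )
            )
    metadata = pd.DataFrame(meta_rows, columns=METADATA_COLUMNS)
    truth = CohortTruth(
        samples=pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS),
        site_rates=site_rates,
    )

    # --- depth ------------------------------------------------------------
    depth_by_sample: dict[str, dict[str, np.ndarray]] = {}
    chrom_len = {}
    step = config.gene_length + config.gene_gap
    chrom_len["chr1"] = config.n_genes_chr1 * step
    for chrom in CHROM_GROUP_45S:
        chrom_len[chrom] = config.n_genes_per_acrocentric * step

    for s_idx, sid in enumerate(sample_order):
        row = truth_rows[s_idx]
        bm = row["batch_multiplier"]
        rdna_bias = batch_rdna_bias[row["plate_id"]]
        is_tumor = row["tissue"] == "tumor"
        depth: dict[str, np.ndarray] = {}
        for comp, length in config.component_lengths.items():
            k = row["true_copies_5s"] if comp == "5S" else row["true_copies_45s"]
            lam = (
                config.per_copy_depth * k * site_rates[comp][s_idx] * bm * rdna_bias
            )
            depth[comp] = rng.poisson(lam).astype(float)
        for chrom, clen in chrom_len.items():
            arr = np.zeros(clen)
            for iv in regions_list:
                if iv.chrom != chrom:
                    continue
                c = c_by_gene.at[iv.gene_id, sid] if is_tumor else 0.0
                lam = config.per_copy_depth * (2.0 + c) * bm
                arr[iv.start - 1 : iv.end] = rng.poisson(lam, size=iv.length)
            depth[chrom] = arr
        depth_by_sample[sid] = depth

    # --- somatic mutations (MAF-like) -------------------------------------
    maf_rows = []
    hotspot = ("chr17:7577120C>T", "R273H")
    for i, p in enumerate(patients):
        ts = f"{p}-T"
        if driver[i]:
            if rng.random() < config.driver_hotspot_fraction:
                change = f"{hotspot[0]}|{hotspot[1]}"
            else:
                pos = int(rng.integers(7571720, 7590868))
                change = f"chr17:{pos}C>T|X{pos % 999}Y"
            maf_rows.append(
                dict(Hugo_Symbol=DRIVER_GENE,
                     Variant_Classification="Missense_Mutation",
                     Change=change, Tumor_Sample_Barcode=ts)
            )
        for g_idx in range(8):  # recurrent passenger genes
            if rng.random() < 0.15:
                maf_rows.append(
                    dict(Hugo_Symbol=f"PSG{g_idx + 1}",
                         Variant_Classification="Missense_Mutation",
                         Change=f"chr2:{int(rng.integers(1e6, 2e6))}A>G|P{g_idx}",
                         Tumor_Sample_Barcode=ts)
                )
        if rng.random() < 0.1:  # silent calls exercise the non-silent filter
            maf_rows.append(
                dict(Hugo_Symbol="PSG1", Variant_Classification="Silent",
                     Change=f"chr2:{int(rng.integers(1e6, 2e6))}G>A|=",
                     Tumor_Sample_Barcode=ts)
            )
    mutations = pd.DataFrame(maf_rows, columns=MAF_COLUMNS)

    return SyntheticCohort(
        depth_by_sample=depth_by_sample,
        ploidy=ploidy,
        metadata=metadata,
        mutations=mutations,
        regions=regions,
        truth=truth,
        config=config,
    )


def simulate_expression(
    config: SimulationConfig, truth: CohortTruth
) -> tuple[pd.DataFrame, pd.Series, dict]:
    """RNA-seq counts: genes x samples negative binomial with known structure.

    Library sizes span a 2.5-fold range by construction (to exercise
    between-sample normalization).  The designated proliferation (PRI) gene
    set scales with the per-sample proliferation factor; nucleolar and cRPG
    sets scale with softened powers of it.  Gene-set memberships are returned
    and recorded on the truth object.

    Returns (counts, gene_lengths, gene_sets).
    """
    rng = np.random.default_rng(config.seed + 1_000_003)
    samples = list(truth.samples["sample_id"])
    n_genes = config.n_expression_genes
    genes = [f"GENE{i:04d}" for i in range(n_genes)]
    gene_sets = {
        "YW_PRI": genes[: config.pri_set_size],
        "nucleolar": genes[
            config.pri_set_size : config.pri_set_size + config.nucleolar_set_size
        ],
        "cRPG": genes[
            config.pri_set_size + config.nucleolar_set_size :
            config.pri_set_size + config.nucleolar_set_size + config.crpg_set_size
        ],
    }
    truth.gene_sets = gene_sets

    lengths = pd.Series(
        rng.integers(500, 5000, size=n_genes).astype(int), index=genes,
        name="gene_length",
    )
    baseline = rng.lognormal(math.log(200.0), 1.0, size=n_genes)
    n_s = len(samples)
    if n_s == 0:
        return (pd.DataFrame(index=pd.Index(genes, name="gene_id")), lengths, gene_sets)
    # deterministic 2.5-fold library-size spread, shuffled across samples
    spread = 0.5 * 2.5 ** (np.arange(n_s) / max(n_s - 1, 1))
    lib = spread[rng.permutation(n_s)]

    prolif = truth.samples.set_index("sample_id")["proliferation_factor"]
    size = 1.0 / config.nb_dispersion if config.nb_dispersion > 0 else None
    counts = np.empty((n_genes, n_s), dtype=np.int64)
    in_pri = np.isin(genes, gene_sets["YW_PRI"])
    in_nuc = np.isin(genes, gene_sets["nucleolar"])
    in_crpg = np.isin(genes, gene_sets["cRPG"])
    for j, sid in enumerate(samples):
        f = float(prolif[sid])
        eff = np.ones(n_genes)
        eff[in_pri] = f
        eff[in_nuc] = f**0.7
        eff[in_crpg] = f**0.3
        mu = baseline * lib[j] * eff
        if size is None:
            counts[:, j] = rng.poisson(mu)
        else:
            counts[:, j] = rng.negative_binomial(size, size / (size + mu))
    counts_df = pd.DataFrame(counts, index=pd.Index(genes, name="gene_id"),
                             columns=samples)
    return counts_df, lengths, gene_sets
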