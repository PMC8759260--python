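"""Synthetic whole-blood cohort generator with known ground truth.

The generator emulates the data-generating process that the downstream
analyses are designed to detect: bulk whole-blood DNA methylation (beta
values) and RNA-seq counts are both driven by a latent immune-cell
composition whose naive/activated balance shifts with age
(immuno-senescence).  Nine cell compartments are modelled:

* naive T, activated T, canonical NK, adaptive NK  — the age-informative
  lymphocyte subtypes,
* B cells, monocytes, neutrophils, eosinophils, basophils — broad types
  that dominate composition but carry no activation signal.

Clock CpGs come in three flavours: "cluster1" CpGs are highly methylated
in naive compartments and lowly methylated in activated ones, "cluster2"
CpGs are the mirror image, and "neutral" CpGs have identical methylation
in every compartment.  Marker genes are affine in the matching
compartment fraction (naive markers track naive T + canonical NK,
activated markers track activated T + adaptive NK); null genes carry no
composition signal.  Bulk beta values are the fraction-weighted mixture
of per-compartment reference profiles plus Gaussian measurement noise
(truncated to [0, 1]); counts are negative-binomial around exp(log-mean)
with log-normal library sizes.  Additive batch shifts and a latent
expression confounder provide the nuisance structure that the regression
covariates and latent factors must absorb.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from ._utils import as_rng
from .clocks import ClockModel, horvath_forward_transform, zhang_standardize

CELL_TYPES = [
    "naive_T",
    "activated_T",
    "canonical_NK",
    "adaptive_NK",
    "B",
    "monocyte",
    "neutrophil",
    "eosinophil",
    "basophil",
]

NAIVE_COMPARTMENTS = ["naive_T", "canonical_NK"]
ACTIVATED_COMPARTMENTS = ["activated_T", "adaptive_NK"]


@dataclass
class QTLSpec:
    """One injected genetic effect: a SNP acting as cis-meQTL for a CpG
    and trans-eQTL for a gene."""

    snp: str
    cpg: str
    gene: str
    allele_freq: float = 0.5
    beta_shift: float = 0.1      # beta units per allele
    expr_shift: float = 0.3      # natural-log expression units per allele


@dataclass
class SimulationConfig:
    n_samples: int = 500
    age_range: tuple[float, float] = (18.0, 87.0)
    n_clock_cpgs: int = 200
    cluster_sizes: tuple[int, int] = (70, 70)  # cluster1, cluster2; rest neutral
    n_genes: int = 300
    marker_sizes: tuple[int, int] = (45, 45)   # naive-marker, activated-marker; rest null
    n_noncoding_null: int = 10                 # null genes annotated non-protein-coding
    n_low_abundance_null: int = 8              # null genes below the median-count filter
    beta_noise_sd: float = 0.01
    count_dispersion: float = 0.15             # NB dispersion alpha; 0 -> Poisson
    batch_levels: dict = field(
        default_factory=lambda: {"bisulphite_plate": 4, "sentrix_position": 6, "flowcell": 3}
    )
    batch_sd_beta: float = 0.004
    batch_sd_expr: float = 0.05
    activation_slope: float = 0.07             # logit units per year
    activation_midpoint_age: float = 52.0
    activation_logit_sd: float = 0.5
    fraction_noise_scale: float = 1.0          # 0 -> deterministic composition given age
    n_latent_confounders: int = 1
    confounder_sd: float = 0.3
    library_log_sd: float = 0.2
    n_cohorts: int = 3
    n_replicate_pairs: int = 0
    cellcount_noise_sd: float = 0.5            # percentage points on measured counts
    qtl_spec: Optional[list[QTLSpec]] = None
    seed: int = 0

    @property
    def n_neutral_cpgs(self) -> int:
        return self.n_clock_cpgs - sum(self.cluster_sizes)

    @property
    def n_null_genes(self) -> int:
        return self.n_genes - sum(self.marker_sizes)

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        lo, hi = self.age_range
        if not lo < hi:
            raise ValueError("age_range must satisfy low < high")
        if min(self.n_clock_cpgs, self.n_genes) <= 0:
            raise ValueError("n_clock_cpgs and n_genes must be positive")
        if min(self.cluster_sizes) <= 0 or min(self.marker_sizes) <= 0:
            raise ValueError("cluster/marker sizes must be positive")
        if self.n_neutral_cpgs < 0:
            raise ValueError(
                f"cluster CpG counts {self.cluster_sizes} exceed n_clock_cpgs={self.n_clock_cpgs}"
            )
        if self.n_null_genes < 0:
            raise ValueError(f"marker gene counts {self.marker_sizes} exceed n_genes={self.n_genes}")
        if self.n_noncoding_null + self.n_low_abundance_null > self.n_null_genes:
            raise ValueError("non-coding plus low-abundance null genes exceed null gene count")
        for name in ("beta_noise_sd", "batch_sd_beta", "batch_sd_expr", "count_dispersion",
                     "activation_logit_sd", "fraction_noise_scale", "confounder_sd",
                     "library_log_sd", "cellcount_noise_sd"):
            v = getattr(self, name)
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")
        if not np.isfinite(self.activation_slope):
            raise ValueError("activation_slope must be finite")


@dataclass
class GroundTruth:
    cell_fractions: pd.DataFrame          # sample x cell type, rows on the simplex
    cpg_cluster_labels: pd.Series         # cpg -> {cluster1, cluster2, neutral}
    gene_cluster_labels: pd.Series        # gene -> {naive_marker, activated_marker, null}
    reference_beta: pd.DataFrame          # cell type x cpg, in [0, 1]
    reference_expr: pd.DataFrame          # cell type x gene, mean log-expression
    gene_base_log_mean: pd.Series
    gene_marker_slope: pd.Series
    confounder_scores: Optional[np.ndarray] = None
    confounder_loadings: Optional[pd.DataFrame] = None
    qtl_truth: Optional[dict[str, pd.DataFrame]] = None
    true_clock: Optional[ClockModel] = None


@dataclass
class SyntheticCohort:
    beta: pd.DataFrame                    # sample x cpg, in [0, 1]
    counts: pd.DataFrame                  # sample x gene, non-negative int
    covariates: pd.DataFrame              # per-sample covariates, indexed by sample
    cpg_coords: pd.DataFrame              # cpg -> chrom, pos (1-based)
    gene_coords: pd.DataFrame             # gene -> chrom, start, end, strand, biotype
    replicate_pairs: list[tuple[str, str]] = field(default_factory=list)
    genotypes: Optional[pd.DataFrame] = None  # sample x snp, 0/1/2


@dataclass
class SortedCellReference:
    """Per-donor paired naive/activated sorted-cell profiles."""

    beta: pd.DataFrame                    # sample x cpg
    sample_meta: pd.DataFrame             # sample -> donor, lineage, phenotype
    beta_celltype_medians: pd.DataFrame   # (lineage, phenotype) cell type x cpg
    expr_celltype_medians: pd.DataFrame   # cell type x gene (median log-expression)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _beta_draw(mean: float, conc: float, n: int, scale: float,
               rng: np.random.Generator) -> np.ndarray:
    """Beta draw with given mean and concentration; noise scaled by `scale`
    (scale 0 returns the mean exactly)."""
    if scale == 0:
        return np.full(n, mean)
    c = conc / scale**2
    return rng.beta(mean * c, (1.0 - mean) * c, size=n)


def _dirichlet_draw(means: np.ndarray, conc: float, n: int, scale: float,
                    rng: np.random.Generator) -> np.ndarray:
    if scale == 0:
        return np.tile(means, (n, 1))
    return rng.dirichlet(means * conc / scale**2, size=n)


def simulate_cell_fractions(ages: Sequence[float], config: SimulationConfig,
                            rng: np.random.Generator | int | None = None) -> pd.DataFrame:
    """Draw per-sample immune-cell fractions on the simplex.

    Composition is built hierarchically: neutrophils take a Beta-distributed
    share; a small Beta share of the remainder goes to monocytes,
    eosinophils and basophils; the rest is lymphocytes, split into T, NK
    and B cells.  The activated share of T cells follows a logistic trend
    in age (slope `activation_slope` on the logit scale) with per-sample
    logit noise; the adaptive share of NK cells rises linearly with age.
    Because the neutrophil share is the dominant noise source, neutrophil
    and total lymphocyte fractions are strongly anticorrelated, mirroring
    real whole-blood differentials.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ValueError("empty age vector")
    lo, hi = config.age_range
    if ages.min() < lo - 1e-9 or ages.max() > hi + 1e-9:
        raise ValueError("ages outside the configured age_range")
    rng = as_rng(rng)
    n = ages.size
    s = config.fraction_noise_scale

    neut = _beta_draw(0.55, 60.0, n, s, rng)
    other_frac = _beta_draw(0.18, 150.0, n, s, rng)          # of the non-neutrophil rest
    other_total = (1.0 - neut) * other_frac
    lymph = (1.0 - neut) * (1.0 - other_frac)

    meb = _dirichlet_draw(np.array([0.70, 0.25, 0.05]), 100.0, n, s, rng) * other_total[:, None]
    tnb = _dirichlet_draw(np.array([0.65, 0.15, 0.20]), 150.0, n, s, rng)
    t_total = lymph * tnb[:, 0]
    nk_total = lymph * tnb[:, 1]
    b_total = lymph * tnb[:, 2]

    logit_noise = rng.normal(0.0, config.activation_logit_sd * (1 if s > 0 else 0), n) if s > 0 else 0.0
    act = _sigmoid(config.activation_slope * (ages - config.activation_midpoint_age) + logit_noise)

    # adaptive NK share: linear trend in age (kept linear so that a linear
    # clock can represent age exactly in the noise-free limit)
    adpt = 0.10 + 0.006 * (ages - lo)
    if s > 0:
        adpt = adpt + rng.normal(0.0, 0.05 * s, n)
    adpt = np.clip(adpt, 0.0, 0.9)

    frac = np.column_stack([
        t_total * (1.0 - act),        # naive_T
        t_total * act,                # activated_T
        nk_total * (1.0 - adpt),      # canonical_NK
        nk_total * adpt,              # adaptive_NK
        b_total,                      # B
        meb[:, 0],                    # monocyte
        neut,                         # neutrophil
        meb[:, 1],                    # eosinophil
        meb[:, 2],                    # basophil
    ])
    frac = frac / frac.sum(axis=1, keepdims=True)
    return pd.DataFrame(frac, columns=CELL_TYPES)


def _cpg_ids(n: int) -> list[str]:
    return [f"cg{i:05d}" for i in range(n)]


def _gene_ids(n: int) -> list[str]:
    return [f"G{i:04d}" for i in range(n)]


def build_reference_profiles(config: SimulationConfig,
                             rng: np.random.Generator | int | None = None
                             ) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Build per-compartment reference methylation and expression profiles.

    Returns (reference_beta, reference_expr, meta) where meta carries the
    per-gene base log-mean, marker slope, and label series used by
    :func:`simulate_cohort`.
    """
    config.validate()
    rng = as_rng(rng)
    n1, n2 = config.cluster_sizes
    n_neutral = config.n_neutral_cpgs
    cpgs = _cpg_ids(config.n_clock_cpgs)
    cpg_labels = pd.Series(
        ["cluster1"] * n1 + ["cluster2"] * n2 + ["neutral"] * n_neutral,
        index=cpgs, name="cpg_cluster")

    ref_beta = pd.DataFrame(index=CELL_TYPES, columns=cpgs, dtype=float)
    for j, cpg in enumerate(cpgs):
        lab = cpg_labels.iloc[j]
        if lab == "neutral":
            ref_beta[cpg] = rng.uniform(0.2, 0.8)
        else:
            # independent naive-vs-activated gaps for the T and NK axes,
            # so the two activation trajectories are not collinear
            hi_t = rng.uniform(0.75, 0.90)
            gap_t = rng.uniform(0.45, 0.60)
            hi_nk = rng.uniform(0.75, 0.90)
            gap_nk = rng.uniform(0.45, 0.60)
            mid = rng.uniform(0.30, 0.70, size=len(CELL_TYPES))
            col = pd.Series(mid, index=CELL_TYPES)
            if lab == "cluster1":
                col["naive_T"], col["activated_T"] = hi_t, hi_t - gap_t
                col["canonical_NK"], col["adaptive_NK"] = hi_nk, hi_nk - gap_nk
            else:
                col["naive_T"], col["activated_T"] = hi_t - gap_t, hi_t
                col["canonical_NK"], col["adaptive_NK"] = hi_nk - gap_nk, hi_nk
            ref_beta[cpg] = col

    m1, m2 = config.marker_sizes
    n_null = config.n_null_genes
    genes = _gene_ids(config.n_genes)
    gene_labels = pd.Series(
        ["naive_marker"] * m1 + ["activated_marker"] * m2 + ["null"] * n_null,
        index=genes, name="gene_cluster")

    base = pd.Series(np.log(rng.uniform(20.0, 500.0, config.n_genes)), index=genes)
    # low-abundance null genes fall below the median-count filter downstream
    low_idx = genes[m1 + m2 + config.n_noncoding_null:
                    m1 + m2 + config.n_noncoding_null + config.n_low_abundance_null]
    base[low_idx] = np.log(rng.uniform(0.1, 0.4, len(low_idx)))
    slope = pd.Series(0.0, index=genes)
    slope[gene_labels == "naive_marker"] = rng.uniform(8.0, 12.0, m1)
    slope[gene_labels == "activated_marker"] = rng.uniform(8.0, 12.0, m2)

    ref_expr = pd.DataFrame(
        np.tile(base.values, (len(CELL_TYPES), 1)), index=CELL_TYPES, columns=genes)
    for g in genes:
        lab = gene_labels[g]
        if lab == "null":
            continue
        high_in = NAIVE_COMPARTMENTS if lab == "naive_marker" else ACTIVATED_COMPARTMENTS
        low_in = ACTIVATED_COMPARTMENTS if lab == "naive_marker" else NAIVE_COMPARTMENTS
        ref_expr.loc[high_in, g] = base[g] + 0.5 * slope[g]
        ref_expr.loc[low_in, g] = base[g] - 0.5 * slope[g]

    meta = {"cpg_labels": cpg_labels, "gene_labels": gene_labels,
            "gene_base_log_mean": base, "gene_marker_slope": slope}
    return ref_beta, ref_expr, meta


def _make_coordinates(config: SimulationConfig, cpgs: list[str], genes: list[str],
                      gene_labels: pd.Series) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Place CpGs on chr1-6 and most genes on chr7-18 (all-trans pairs);
    a few null genes are placed near the first CpGs to exercise the cis,
    excluded and same-chromosome-trans distance classes."""
    cpg_chrom = [f"chr{1 + (i % 6)}" for i in range(len(cpgs))]
    cpg_pos = [10_000_000 + 2_000_000 * (i // 6) for i in range(len(cpgs))]
    cpg_coords = pd.DataFrame({"chrom": cpg_chrom, "pos": cpg_pos}, index=pd.Index(cpgs, name="cpg"))

    null_genes = list(gene_labels.index[gene_labels == "null"])
    special = {}
    # cis companions: 50 kb from CpGs 0-3
    for k in range(min(4, len(null_genes))):
        g = null_genes[k]
        special[g] = (cpg_chrom[k], cpg_pos[k] + 50_000, cpg_pos[k] + 70_000)
    # excluded-zone companions: 2 Mb from CpGs 4-5
    for k in range(4, min(6, len(null_genes))):
        g = null_genes[k]
        special[g] = (cpg_chrom[k], cpg_pos[k] + 2_000_000, cpg_pos[k] + 2_020_000)
    # same-chromosome trans companions: 6 Mb from CpGs 6-7
    for k in range(6, min(8, len(null_genes))):
        g = null_genes[k]
        special[g] = (cpg_chrom[k], cpg_pos[k] + 6_000_000, cpg_pos[k] + 6_020_000)

    rows = []
    reg = 0
    noncoding = set(null_genes[8:8 + config.n_noncoding_null]) if len(null_genes) > 8 else set()
    for j, g in enumerate(genes):
        if g in special:
            chrom, start, end = special[g]
        else:
            chrom = f"chr{7 + (reg % 12)}"
            start = 5_000_000 + 1_500_000 * (reg // 12)
            end = start + 20_000
            reg += 1
        biotype = "lincRNA" if g in noncoding else "protein_coding"
        rows.append((chrom, start, end, "+", biotype))
    gene_coords = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "strand", "biotype"],
        index=pd.Index(genes, name="gene"))
    return cpg_coords, gene_coords


def simulate_cohort(config: SimulationConfig) -> tuple[SyntheticCohort, GroundTruth]:
    """Generate a full synthetic cohort plus its ground truth.

    Deterministic for a fixed ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]

    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, n)
    sex = rng.choice(["F", "M"], size=n)
    cohort_lab = rng.choice([f"cohort{k + 1}" for k in range(config.n_cohorts)], size=n)

    ref_beta, ref_expr, meta = build_reference_profiles(config, rng)
    fractions = simulate_cell_fractions(ages, config, rng)
    fractions.index = pd.Index(sample_ids, name="sample")

    mixture = fractions.values @ ref_beta.values  # n x n_cpgs

    # batch assignments and additive per-level shifts (both modalities)
    batch_assign = {}
    beta_shift = np.zeros(n)
    expr_shift = np.zeros(n)
    for cov, n_levels in config.batch_levels.items():
        levels = rng.integers(0, n_levels, n)
        batch_assign[cov] = np.array([f"{cov[:2]}{v + 1}" for v in levels])
        off_b = rng.normal(0.0, config.batch_sd_beta, n_levels)
        off_e = rng.normal(0.0, config.batch_sd_expr, n_levels)
        beta_shift = beta_shift + off_b[levels]
        expr_shift = expr_shift + off_e[levels]

    noise = rng.normal(0.0, config.beta_noise_sd, mixture.shape) if config.beta_noise_sd > 0 else 0.0
    beta = np.clip(mixture + beta_shift[:, None] + noise, 0.0, 1.0)
    beta_df = pd.DataFrame(beta, index=sample_ids, columns=ref_beta.columns)
    beta_df.index.name = "sample"

    # expression: affine in the matching aggregate compartment fraction
    naive_agg = fractions[NAIVE_COMPARTMENTS].sum(axis=1).values
    act_agg = fractions[ACTIVATED_COMPARTMENTS].sum(axis=1).values
    base = meta["gene_base_log_mean"].values
    slope = meta["gene_marker_slope"].values
    glab = meta["gene_labels"].values
    agg = np.zeros((n, config.n_genes))
    agg[:, glab == "naive_marker"] = (naive_agg - naive_agg.mean())[:, None]
    agg[:, glab == "activated_marker"] = (act_agg - act_agg.mean())[:, None]
    log_mu = base[None, :] + slope[None, :] * agg

    conf_scores = None
    conf_loadings = None
    if config.n_latent_confounders > 0 and config.confounder_sd > 0:
        conf_scores = rng.normal(0.0, 1.0, (n, config.n_latent_confounders))
        loadings = np.zeros((config.n_latent_confounders, config.n_genes))
        for k in range(config.n_latent_confounders):
            affected = rng.random(config.n_genes) < 0.5
            loadings[k, affected] = rng.normal(0.0, config.confounder_sd, affected.sum())
        conf_loadings = pd.DataFrame(loadings, columns=meta["gene_labels"].index)
        log_mu = log_mu + conf_scores @ loadings

    lib = np.exp(rng.normal(0.0, config.library_log_sd, n)) if config.library_log_sd > 0 else np.ones(n)
    mu = np.exp(log_mu + expr_shift[:, None]) * lib[:, None]
    if config.count_dispersion > 0:
        r = 1.0 / config.count_dispersion
        counts = rng.negative_binomial(r, r / (r + mu))
    else:
        counts = rng.poisson(mu)
    counts_df = pd.DataFrame(counts, index=sample_ids, columns=meta["gene_labels"].index)
    counts_df.index.name = "sample"

    cpg_coords, gene_coords = _make_coordinates(
        config, list(ref_beta.columns), list(meta["gene_labels"].index), meta["gene_labels"])

    pct = fractions.copy()
    lymph_pct = pct[["naive_T", "activated_T", "canonical_NK", "adaptive_NK", "B"]].sum(axis=1) * 100
    cov = pd.DataFrame({
        "age": ages, "sex": sex, "cohort": cohort_lab,
        **batch_assign,
        "lymphocyte_pct": lymph_pct.values,
        "monocyte_pct": pct["monocyte"].values * 100,
        "neutrophil_pct": pct["neutrophil"].values * 100,
        "eosinophil_pct": pct["eosinophil"].values * 100,
        "basophil_pct": pct["basophil"].values * 100,
    }, index=sample_ids)
    cov.index.name = "sample"
    if config.cellcount_noise_sd > 0:
        for c in ["lymphocyte_pct", "monocyte_pct", "neutrophil_pct",
                  "eosinophil_pct", "basophil_pct"]:
            cov[c] = np.clip(cov[c] + rng.normal(0.0, config.cellcount_noise_sd, n), 0.0, 100.0)

    replicate_pairs: list[tuple[str, str]] = []
    if config.n_replicate_pairs > 0:
        k = min(config.n_replicate_pairs, n)
        rep_rows = []
        rep_ids = []
        for i in range(k):
            rid = f"{sample_ids[i]}_R2"
            re_noise = rng.normal(0.0, config.beta_noise_sd, mixture.shape[1]) \
                if config.beta_noise_sd > 0 else 0.0
            rep_rows.append(np.clip(mixture[i] + beta_shift[i] + re_noise, 0.0, 1.0))
            rep_ids.append(rid)
            replicate_pairs.append((sample_ids[i], rid))
        rep_df = pd.DataFrame(rep_rows, index=rep_ids, columns=beta_df.columns)
        beta_df = pd.concat([beta_df, rep_df])
        beta_df.index.name = "sample"
        rep_cov = cov.iloc[:k].copy()
        rep_cov.index = rep_ids
        cov = pd.concat([cov, rep_cov])
        cov.index.name = "sample"

    cohort = SyntheticCohort(
        beta=beta_df, counts=counts_df, covariates=cov,
        cpg_coords=cpg_coords, gene_coords=gene_coords,
        replicate_pairs=replicate_pairs)
    truth = GroundTruth(
        cell_fractions=fractions,
        cpg_cluster_labels=meta["cpg_labels"],
        gene_cluster_labels=meta["gene_labels"],
        reference_beta=ref_beta,
        reference_expr=ref_expr,
        gene_base_log_mean=meta["gene_base_log_mean"],
        gene_marker_slope=meta["gene_marker_slope"],
        confounder_scores=conf_scores,
        confounder_loadings=conf_loadings,
    )

    if config.qtl_spec:
        cohort, tables = inject_qtl_effects(cohort, truth, config.qtl_spec,
                                            rng=np.random.default_rng(config.seed + 101))
        truth.qtl_truth = tables

    truth.true_clock = make_synthetic_clock(truth, cohort, seed=config.seed + 202)
    return cohort, truth


def make_synthetic_clock(truth: GroundTruth, cohort: SyntheticCohort,
                         transform_kind: str = "identity", n_cpgs: int = 60,
                         adult_age: float = 20.0, name: str | None = None,
                         cpg_subset: Optional[Sequence[str]] = None,
                         seed: int | None = None) -> ClockModel:
    """Fit a linear CpG age predictor on the cohort by least squares.

    Selects a balanced subset of cluster1/cluster2 CpGs (they carry the
    age signal through cell composition) unless ``cpg_subset`` is given,
    regresses the transform of chronological age on their beta values,
    and packages the solution as a :class:`ClockModel`.
    """
    ages = cohort.covariates.loc[cohort.beta.index.intersection(cohort.covariates.index), "age"]
    samples = [s for s in cohort.beta.index if s in ages.index and not s.endswith("_R2")]
    beta = cohort.beta.loc[samples]
    ages = ages.loc[samples].values.astype(float)

    if cpg_subset is None:
        labels = truth.cpg_cluster_labels
        c1 = list(labels.index[labels == "cluster1"])
        c2 = list(labels.index[labels == "cluster2"])
        if seed is not None:
            r = np.random.default_rng(seed)
            r.shuffle(c1)
            r.shuffle(c2)
        half = n_cpgs // 2
        cpg_subset = c1[:half] + c2[:n_cpgs - half]
    cpg_subset = list(cpg_subset)
    if len(samples) < len(cpg_subset) + 1:
        raise ValueError("fewer samples than selected clock CpGs")

    if transform_kind == "zhang":
        X = zhang_standardize(beta)[cpg_subset].values
        y = ages
    elif transform_kind == "horvath":
        X = beta[cpg_subset].values
        y = horvath_forward_transform(ages, adult_age=adult_age)
    elif transform_kind == "identity":
        X = beta[cpg_subset].values
        y = ages
    else:
        raise ValueError(f"unknown transform_kind {transform_kind!r}")

    design = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    model = ClockModel(
        name=name or f"synthetic_{transform_kind}",
        intercept=float(coef[0]),
        coefficients=dict(zip(cpg_subset, coef[1:].astype(float))),
        transform=transform_kind,
        adult_age=adult_age,
        training_means={c: float(beta[c].mean()) for c in cpg_subset},
    )
    return model


def inject_qtl_effects(cohort: SyntheticCohort, truth: GroundTruth,
                       qtl_spec: Sequence[QTLSpec],
                       rng: np.random.Generator | int | None = None
                       ) -> tuple[SyntheticCohort, dict[str, pd.DataFrame]]:
    """Add biallelic genotype effects: each spec shifts its CpG's beta
    additively per allele (cis-meQTL) and its gene's log-expression
    (trans-eQTL).  Returns the modified cohort plus truth tables in the
    QTL file dialect."""
    rng = as_rng(rng)
    beta = cohort.beta.copy()
    counts = cohort.counts.copy()
    n = len(counts.index)
    genos = {}
    me_rows, e_rows = [], []
    for spec in qtl_spec:
        if spec.cpg not in beta.columns:
            raise KeyError(f"unknown CpG ID {spec.cpg!r}")
        if spec.gene not in counts.columns:
            raise KeyError(f"unknown gene ID {spec.gene!r}")
        g = rng.binomial(2, spec.allele_freq, len(beta.index)).astype(float)
        genos[spec.snp] = g
        shifted = beta[spec.cpg].values + spec.beta_shift * g
        if shifted.min() < -1e-12 or shifted.max() > 1 + 1e-12:
            warnings.warn(
                f"beta shift for {spec.cpg} leaves [0,1]; values truncated", stacklevel=2)
        beta[spec.cpg] = np.clip(shifted, 0.0, 1.0)
        g_expr = g[:n]  # counts have no replicate rows
        counts[spec.gene] = np.rint(
            counts[spec.gene].values * np.exp(spec.expr_shift * g_expr)).astype(np.int64)
        me_rows.append((spec.snp, spec.cpg))
        e_rows.append((spec.snp, spec.gene))
    meqtl = pd.DataFrame(me_rows, columns=["snp", "target"]).drop_duplicates()
    eqtl = pd.DataFrame(e_rows, columns=["snp", "target"]).drop_duplicates()
    geno_df = pd.DataFrame(genos, index=beta.index).astype(int)
    out = SyntheticCohort(
        beta=beta, counts=counts, covariates=cohort.covariates,
        cpg_coords=cohort.cpg_coords, gene_coords=cohort.gene_coords,
        replicate_pairs=cohort.replicate_pairs, genotypes=geno_df)
    return out, {"cis_meqtl": meqtl, "trans_eqtl": eqtl}


LINEAGES = {
    "CD4": ("naive_T", "activated_T"),
    "CD8": ("naive_T", "activated_T"),
    "NK": ("canonical_NK", "adaptive_NK"),
}


def emit_sorted_cell_reference(truth: GroundTruth, n_donors: int,
                               rng: np.random.Generator | int | None = None,
                               clock: Optional[ClockModel] = None,
                               age_offset: float = 30.0,
                               base_age: float = 55.0,
                               donor_sd: float = 0.01,
                               noise_sd: float = 0.005,
                               lineage_sd: float = 0.02) -> SortedCellReference:
    """Emit paired naive/activated sorted-cell methylation profiles.

    For each lineage (CD4, CD8, NK) every donor contributes one naive and
    one activated sample.  The activated profile is the naive profile
    shifted along the activated-minus-naive reference direction, scaled so
    that the supplied clock (default: the cohort's true clock) predicts
    the activated sample ``age_offset`` years older than its naive
    partner.  Donor random effects are shared within each pair.
    """
    if n_donors < 2:
        raise ValueError("n_donors must be >= 2")
    rng = as_rng(rng)
    clock = clock if clock is not None else truth.true_clock
    if clock is None:
        raise ValueError("no clock available for offset injection")
    cpgs = list(truth.reference_beta.columns)

    w = np.array([clock.coefficients.get(c, 0.0) for c in cpgs])
    if clock.transform == "horvath":
        score_offset = (horvath_forward_transform(np.array([base_age + age_offset / 2]),
                                                  clock.adult_age)
                        - horvath_forward_transform(np.array([base_age - age_offset / 2]),
                                                    clock.adult_age))[0]
    else:
        score_offset = age_offset

    rows, metas = [], []
    for lineage, (naive_ct, act_ct) in LINEAGES.items():
        naive_ref = truth.reference_beta.loc[naive_ct].values
        act_ref = truth.reference_beta.loc[act_ct].values
        d = act_ref - naive_ref
        denom = float(w @ d)
        if abs(denom) < 1e-12:
            raise ValueError(f"clock insensitive to the {lineage} activation direction")
        s = score_offset / denom
        lineage_off = rng.normal(0.0, lineage_sd, len(cpgs)) if lineage_sd > 0 else 0.0
        for donor in range(n_donors):
            did = f"{lineage}_D{donor + 1}"
            donor_eff = rng.normal(0.0, donor_sd, len(cpgs)) if donor_sd > 0 else 0.0
            base_prof = naive_ref + lineage_off + donor_eff
            for phen, prof in (("naive", base_prof),
                               ("activated", base_prof + s * d)):
                meas = prof + (rng.normal(0.0, noise_sd, len(cpgs)) if noise_sd > 0 else 0.0)
                rows.append(np.clip(meas, 0.0, 1.0))
                sid = f"{did}_{phen}"
                metas.append((sid, did, lineage, phen))
    beta = pd.DataFrame(rows, columns=cpgs,
                        index=[m[0] for m in metas])
    beta.index.name = "sample"
    meta = pd.DataFrame(metas, columns=["sample", "donor", "lineage", "phenotype"]
                        ).set_index("sample")

    groups = meta.assign(cell_type=meta["lineage"] + "_" + meta["phenotype"])
    med = beta.groupby(groups["cell_type"]).median()
    expr_med = truth.reference_expr.copy()
    return SortedCellReference(beta=beta, sample_meta=meta,
                               beta_celltype_medians=med,
                               expr_celltype_medians=expr_med)
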