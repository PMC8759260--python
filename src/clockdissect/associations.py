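"""Per-CpG regression of genome-wide expression on methylation.

For every clock CpG, the (rank-inverse-normal transformed) expression of
every gene is regressed on the CpG's beta value plus known covariates
(cohort, age, sex, broad cell percentages minus neutrophils, technical
batches) and latent factors estimated from the expression residuals.
All genes for one CpG share a single design factorization
(Frisch-Waugh-Lovell through a QR decomposition), so the scan is a
handful of matrix products.

Residual bias/inflation in each CpG's 14k-odd t statistics is estimated
from the central mass of the z-converted statistics (truncated-normal
central matching, median/MAD fallback) and divided out.  CpG-gene pairs are classified cis (gap <= 100 kb), trans (gap >
5 Mb or different chromosome) or excluded; Bonferroni correction is
applied within cis and trans separately.  A label-permutation test
(methylation sample identifiers shuffled, covariates staying with the
expression) provides the global null for the trans-association count.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .clocks import ClockModel

CIS, TRANS, EXCLUDED = "cis", "trans", "excluded"

AUTOSOMES = {f"chr{i}" for i in range(1, 23)} | {str(i) for i in range(1, 23)}

MODEL_CELL_PCTS = ["basophil_pct", "eosinophil_pct", "lymphocyte_pct", "monocyte_pct"]
CATEGORICAL_COVARIATES = ["cohort", "sex", "bisulphite_plate", "sentrix_position", "flowcell"]


@dataclass
class PreprocessedExpression:
    expr: pd.DataFrame            # sample x gene, RIN-transformed log-CPM
    log_cpm: pd.DataFrame         # sample x gene, before RIN
    gene_coords: pd.DataFrame     # retained gene intervals
    n_genes_in: int
    n_genes_kept: int


@dataclass
class AssociationResults:
    t: pd.DataFrame               # CpG x gene raw t statistics
    p: pd.DataFrame
    t_corrected: pd.DataFrame     # empirical-null corrected z statistics
    p_corrected: pd.DataFrame
    mask: pd.DataFrame            # CpG x gene in {cis, trans, excluded}
    bias: pd.Series               # per-CpG empirical-null location
    inflation: pd.Series          # per-CpG empirical-null scale
    df_resid: int
    null_flags: pd.Series = field(default=None)  # per-CpG "em" or "fallback"

    def domain_sizes(self) -> dict[str, int]:
        vals = self.mask.values
        return {d: int((vals == d).sum()) for d in (CIS, TRANS, EXCLUDED)}


@dataclass
class CoreSet:
    genes: list[str]
    cpgs: list[str]
    clock_thresholds: dict[str, int]       # clock name -> ceil(0.05 * size)
    min_trans_genes: int
    gene_counts: pd.DataFrame              # gene x clock significant-CpG counts
    cpg_counts: pd.Series                  # per-CpG significant trans-gene count


@dataclass
class PermutationResult:
    observed: int
    perm_counts: np.ndarray
    empirical_p: float


def preprocess_expression(counts: pd.DataFrame, gene_coords: pd.DataFrame,
                          autosomes_only: bool = True) -> PreprocessedExpression:
    """Filter, normalize and RIN-transform a count matrix.

    Keeps protein-coding genes with median raw count strictly greater
    than 1 (and, by default, autosomal location).  Library sizes are the
    per-sample totals over all supplied genes.  log-CPM uses a 0.5/1.0
    offset pair to avoid log of zero; the per-gene RIN transform maps
    average ranks r to normal quantiles of (r - 0.5)/n.
    """
    if (counts.values < 0).any():
        raise ValueError("counts must be non-negative")
    if "biotype" not in gene_coords.columns:
        raise ValueError("gene annotation must include a biotype column")
    lib = counts.sum(axis=1).astype(float)
    if (lib == 0).any():
        bad = lib.index[lib == 0][0]
        raise ValueError(f"zero library size for sample {bad!r}")

    genes = [g for g in counts.columns if g in gene_coords.index]
    keep = []
    for g in genes:
        if gene_coords.loc[g, "biotype"] != "protein_coding":
            continue
        if autosomes_only and str(gene_coords.loc[g, "chrom"]) not in AUTOSOMES:
            continue
        if counts[g].median() > 1:
            keep.append(g)
    if not keep:
        raise ValueError("all genes removed by biotype/abundance filtering")

    sub = counts[keep].values.astype(float)
    log_cpm = np.log2((sub + 0.5) / (lib.values[:, None] + 1.0) * 1e6)
    log_cpm = pd.DataFrame(log_cpm, index=counts.index, columns=keep)

    n = log_cpm.shape[0]
    ranks = np.apply_along_axis(stats.rankdata, 0, log_cpm.values)  # average ranks
    rin = stats.norm.ppf((ranks - 0.5) / n)
    expr = pd.DataFrame(rin, index=counts.index, columns=keep)
    return PreprocessedExpression(
        expr=expr, log_cpm=log_cpm, gene_coords=gene_coords.loc[keep],
        n_genes_in=counts.shape[1], n_genes_kept=len(keep))


def rank_inverse_normal(x: np.ndarray) -> np.ndarray:
    """RIN transform of a single vector: Phi^-1((rank - 0.5)/n), average
    ranks for ties."""
    x = np.asarray(x, dtype=float)
    return stats.norm.ppf((stats.rankdata(x) - 0.5) / x.size)


def build_design(covariates: pd.DataFrame,
                 categorical: Sequence[str] = tuple(CATEGORICAL_COVARIATES),
                 numeric: Sequence[str] = ("age", *MODEL_CELL_PCTS),
                 min_level_count: int = 5) -> pd.DataFrame:
    """Dummy-coded design matrix from the per-sample covariate table.

    Neutrophil percentage is deliberately not part of the default
    numeric set: it is almost perfectly collinear with the lymphocyte
    percentage.  Categorical covariates are dummy-coded against a
    reference level; levels observed fewer than ``min_level_count``
    times are pooled before coding.
    """
    cols = [c for c in (*categorical, *numeric) if c in covariates.columns]
    if covariates[cols].isna().any().any():
        bad = covariates[cols].isna().any()
        raise ValueError(f"missing covariate values in {list(bad.index[bad])}")
    parts = [pd.Series(1.0, index=covariates.index, name="intercept")]
    for c in numeric:
        if c in covariates.columns:
            parts.append(covariates[c].astype(float))
    for c in categorical:
        if c not in covariates.columns:
            continue
        col = covariates[c].astype(str)
        vc = col.value_counts()
        rare = vc.index[vc < min_level_count]
        if len(rare):
            col = col.where(~col.isin(rare), other="_pooled")
        dummies = pd.get_dummies(col, prefix=c, drop_first=True, dtype=float)
        parts.append(dummies)
    design = pd.concat(parts, axis=1)
    _check_full_rank(design)
    return design


def _check_full_rank(design: pd.DataFrame) -> None:
    x = design.values.astype(float)
    r = np.linalg.matrix_rank(x)
    if r < x.shape[1]:
        # locate offending columns via QR pivot magnitudes
        q, rr = np.linalg.qr(x)
        diag = np.abs(np.diag(rr))
        bad = [design.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; collinear columns include {bad}")


def estimate_latent_factors(expr: pd.DataFrame, design: pd.DataFrame,
                            k: int = 5,
                            protect: Optional[np.ndarray] = None,
                            n_protect: int = 10) -> pd.DataFrame:
    """Top-k left singular vectors of the expression residuals after
    removing known covariates; orthonormal, sign-fixed so each factor's
    largest-magnitude gene loading is positive.

    ``protect`` (n_samples x m) optionally supplies a data matrix —
    typically the methylation matrix itself — whose within-design
    principal directions (top ``n_protect``) must NOT be captured by the
    factors.  Latent confounders are then estimated only from expression
    variation orthogonal to what the methylation predictors could
    explain, so the factors cannot absorb the signal of interest.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    x = design.values.astype(float)
    if k >= expr.shape[0] - np.linalg.matrix_rank(x):
        raise ValueError("k must be smaller than the residual degrees of freedom")
    q, _ = np.linalg.qr(x)
    resid = expr.values - q @ (q.T @ expr.values)
    if protect is not None and n_protect > 0:
        pm = np.asarray(protect, dtype=float)
        pm = pm - q @ (q.T @ pm)              # within-design variation only
        pu, ps, _ = np.linalg.svd(pm, full_matrices=False)
        keep = min(n_protect, int((ps > 1e-12 * ps[0]).sum()) if ps.size else 0)
        if keep:
            pb = pu[:, :keep]
            resid = resid - pb @ (pb.T @ resid)
    u, s, vt = np.linalg.svd(resid, full_matrices=False)
    factors = u[:, :k].copy()
    for j in range(k):
        i = np.argmax(np.abs(vt[j]))
        if vt[j, i] < 0:
            factors[:, j] = -factors[:, j]
    return pd.DataFrame(factors, index=expr.index,
                        columns=[f"LF{j + 1}" for j in range(k)])


def _qr_basis(design: np.ndarray) -> np.ndarray:
    q, _ = np.linalg.qr(design)
    return q


def scan_tstats(beta: np.ndarray, expr: np.ndarray, design: np.ndarray
                ) -> tuple[np.ndarray, int]:
    """t statistics of the methylation coefficient for every CpG x gene
    pair, via a single QR factorization of the shared design.

    ``beta``: n x n_cpgs, ``expr``: n x n_genes, ``design``: n x p
    (including intercept).  Returns (t, df) with t of shape
    n_cpgs x n_genes.  Perfect fits yield +-inf (flagged by the caller).
    """
    n = design.shape[0]
    q = _qr_basis(design)
    er = expr - q @ (q.T @ expr)
    br = beta - q @ (q.T @ beta)
    bb = np.einsum("ij,ij->j", br, br)                 # per CpG
    if np.any(bb <= 0):
        raise ValueError("a CpG beta column is collinear with the design")
    num = br.T @ er                                    # cpg x gene
    slope = num / bb[:, None]
    yy = np.einsum("ij,ij->j", er, er)                 # per gene
    df = n - design.shape[1] - 1
    if df <= 0:
        raise ValueError("non-positive residual degrees of freedom")
    sse = np.maximum(yy[None, :] - slope * num, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = slope * np.sqrt(bb)[:, None] / np.sqrt(sse / df)
    t[sse == 0] = np.sign(slope[sse == 0]) * np.inf
    return t, df


def fit_cpg_gene_models(beta_col: pd.Series, expr: pd.DataFrame,
                        design: pd.DataFrame) -> pd.DataFrame:
    """OLS of every gene on one CpG plus covariates; returns per-gene
    (t, p) for the methylation coefficient."""
    x = design.values.astype(float)
    _check_full_rank(design)
    t, df = scan_tstats(beta_col.values[:, None].astype(float),
                        expr.values.astype(float), x)
    t = t[0]
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"t": t, "p": p}, index=expr.columns)


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t statistics to standard-normal scale, stable in the tails."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = -stats.norm.ppf(np.clip(stats.t.sf(t[pos], df), 1e-300, 1.0))
    z[~pos] = stats.norm.ppf(np.clip(stats.t.cdf(t[~pos], df), 1e-300, 1.0))
    return z


_SQRT2 = math.sqrt(2.0)
_SQRT2PI = math.sqrt(2.0 * math.pi)


def _phi(x: float) -> float:
    return math.exp(-0.5 * x * x) / _SQRT2PI


def _Phi(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / _SQRT2))


def _central_null(z: np.ndarray, width: float = 1.96, n_outer: int = 3,
                  n_inner: int = 50, tol: float = 1e-10
                  ) -> tuple[float, float, bool]:
    """Empirical-null location/scale by central matching.

    Starting from (median, MAD-scale), restricts to the central window
    mu +- width*sigma and fits a truncated normal there by maximum
    likelihood (moment fixed point); the window is refreshed from the
    updated estimate.  Genuine signal lives in the tails, outside the
    window, so the estimate tracks the null component only.  Returns
    (mu, sigma, converged).
    """
    med = float(np.median(z))
    mad = float(np.median(np.abs(z - med))) * 1.4826
    if mad <= 0:
        mad = float(np.std(z)) or 1.0
    mu, sg = med, mad
    converged = False
    for _ in range(n_outer):
        lo, hi = mu - width * sg, mu + width * sg
        x = z[(z >= lo) & (z <= hi)]
        if x.size < 10:
            return mu, sg, False
        m_s, v_s = float(x.mean()), float(x.var())
        if v_s <= 0:
            return mu, sg, False
        for _ in range(n_inner):
            a, b = (lo - mu) / sg, (hi - mu) / sg
            zmass = _Phi(b) - _Phi(a)
            if zmass <= 0:
                return mu, sg, False
            pa, pb = _phi(a), _phi(b)
            lam = (pa - pb) / zmass
            delta = 1.0 + (a * pa - b * pb) / zmass - lam * lam
            if delta <= 0:
                return mu, sg, False
            sg_new = math.sqrt(max(v_s / delta, 1e-12))
            mu_new = m_s - sg_new * lam
            moved = abs(sg_new - sg) + abs(mu_new - mu)
            mu, sg = mu_new, sg_new
            if moved < tol:
                converged = True
                break
    ok = converged and np.isfinite(mu) and np.isfinite(sg) and sg > 0
    return float(mu), float(sg), ok


def empirical_null_correct(t_stats: np.ndarray, df: int, min_stats: int = 100,
                           inflation_floor: float = 1.0
                           ) -> tuple[np.ndarray, np.ndarray, float, float, str]:
    """Correct one CpG's genome-wide t statistics for residual bias and
    inflation.

    Converts to z, estimates the empirical-null (mu, sigma) from the
    central mass by truncated-normal matching (median/MAD fallback if
    the fit degenerates), and returns
    (z_corrected, p_corrected, bias, inflation, method).

    The reported inflation is the raw estimate, but the correction
    divides by ``max(sigma, inflation_floor)``: with the default floor
    of 1 the correction removes inflation and bias but never sharpens
    statistics on the strength of an estimated deflation, whose
    sampling noise would otherwise make a genome-wide Bonferroni screen
    anti-conservative.  Set ``inflation_floor=0`` for a symmetric
    correction.
    """
    t_stats = np.asarray(t_stats, dtype=float)
    if t_stats.size < min_stats:
        raise ValueError(f"need at least {min_stats} statistics, got {t_stats.size}")
    z = t_to_z(t_stats, df)
    mu, sg, ok = _central_null(z)
    method = "central"
    if not ok:
        med = float(np.median(z))
        mad = float(np.median(np.abs(z - med))) * 1.4826
        mu, sg = med, (mad if mad > 0 else float(np.std(z)) or 1.0)
        method = "fallback"
    zc = (z - mu) / max(sg, inflation_floor)
    pc = 2.0 * stats.norm.sf(np.abs(zc))
    return zc, pc, mu, sg, method


def _chrom_style(values: Iterable[str]) -> set[bool]:
    return {str(v).startswith("chr") for v in values}


def classify_cis_trans(cpg_coords: pd.DataFrame, gene_coords: pd.DataFrame,
                       cis_window: int = 100_000,
                       trans_window: int = 5_000_000) -> pd.DataFrame:
    """Classify every CpG-gene pair as cis / trans / excluded.

    Distance is the bp gap between the CpG point and the nearest gene
    edge (0 inside the gene).  gap <= cis_window -> cis; different
    chromosome or gap > trans_window -> trans; otherwise excluded.
    """
    styles = _chrom_style(cpg_coords["chrom"]) | _chrom_style(gene_coords["chrom"])
    if len(styles) > 1:
        raise ValueError("inconsistent chromosome naming between CpGs and genes")
    cpg_chrom = cpg_coords["chrom"].astype(str).values
    cpg_pos = cpg_coords["pos"].astype(np.int64).values
    g_chrom = gene_coords["chrom"].astype(str).values
    g_start = gene_coords["start"].astype(np.int64).values
    g_end = gene_coords["end"].astype(np.int64).values

    out = np.empty((len(cpg_coords), len(gene_coords)), dtype=object)
    for i in range(len(cpg_coords)):
        same = cpg_chrom[i] == g_chrom
        gap = np.maximum.reduce([g_start - cpg_pos[i], cpg_pos[i] - g_end,
                                 np.zeros(len(g_start), dtype=np.int64)])
        row = np.where(~same, TRANS,
                       np.where(gap <= cis_window, CIS,
                                np.where(gap > trans_window, TRANS, EXCLUDED)))
        out[i] = row
    return pd.DataFrame(out, index=cpg_coords.index, columns=gene_coords.index)


def classify_pair(cpg_chrom: str, cpg_pos: int, gene_chrom: str,
                  gene_start: int, gene_end: int,
                  cis_window: int = 100_000, trans_window: int = 5_000_000) -> str:
    if str(cpg_chrom).startswith("chr") != str(gene_chrom).startswith("chr"):
        raise ValueError("inconsistent chromosome naming")
    if str(cpg_chrom) != str(gene_chrom):
        return TRANS
    gap = max(gene_start - cpg_pos, cpg_pos - gene_end, 0)
    if gap <= cis_window:
        return CIS
    if gap > trans_window:
        return TRANS
    return EXCLUDED


def association_scan(beta: pd.DataFrame, expression: PreprocessedExpression,
                     design: pd.DataFrame, cpg_coords: pd.DataFrame,
                     n_latent_factors: int = 5,
                     autosomes_only: bool = True,
                     correct: bool = True,
                     cis_window: int = 100_000,
                     trans_window: int = 5_000_000,
                     n_protect_components: int = 10) -> AssociationResults:
    """Full CpG x gene association scan.

    Aligns samples across modalities, estimates latent factors, computes
    t statistics per pair, applies the per-CpG empirical-null
    correction, and classifies pairs cis/trans/excluded.  The latent
    factors are estimated orthogonally to the top
    ``n_protect_components`` methylation principal components so that
    genuine methylation-driven expression signal is not regressed out.
    """
    samples = beta.index.intersection(expression.expr.index).intersection(design.index)
    if len(samples) < design.shape[1] + 2:
        raise ValueError("too few shared samples for the design")
    cpgs = [c for c in beta.columns if c in cpg_coords.index]
    if autosomes_only:
        cpgs = [c for c in cpgs if str(cpg_coords.loc[c, "chrom"]) in AUTOSOMES]
    if not cpgs:
        raise ValueError("no CpGs left after coordinate filtering")

    b = beta.loc[samples, cpgs]
    e = expression.expr.loc[samples]
    d = design.loc[samples]
    if n_latent_factors > 0:
        lf = estimate_latent_factors(e, d, k=n_latent_factors,
                                     protect=b.values.astype(float),
                                     n_protect=n_protect_components)
        d = pd.concat([d, lf], axis=1)
    _check_full_rank(d)

    t, df = scan_tstats(b.values.astype(float), e.values.astype(float),
                        d.values.astype(float))
    p = 2.0 * stats.t.sf(np.abs(t), df)

    genes = list(e.columns)
    if correct:
        tc = np.empty_like(t)
        pc = np.empty_like(t)
        bias = np.empty(len(cpgs))
        infl = np.empty(len(cpgs))
        flags = []
        for i in range(len(cpgs)):
            tc[i], pc[i], bias[i], infl[i], flag = empirical_null_correct(t[i], df)
            flags.append(flag)
    else:
        tc = t_to_z(t, df)
        pc = 2.0 * stats.norm.sf(np.abs(tc))
        bias = np.zeros(len(cpgs))
        infl = np.ones(len(cpgs))
        flags = ["none"] * len(cpgs)

    mask = classify_cis_trans(cpg_coords.loc[cpgs], expression.gene_coords,
                              cis_window=cis_window, trans_window=trans_window)
    idx = pd.Index(cpgs, name="cpg")
    cols = pd.Index(genes, name="gene")
    return AssociationResults(
        t=pd.DataFrame(t, index=idx, columns=cols),
        p=pd.DataFrame(p, index=idx, columns=cols),
        t_corrected=pd.DataFrame(tc, index=idx, columns=cols),
        p_corrected=pd.DataFrame(pc, index=idx, columns=cols),
        mask=mask.loc[cpgs, genes],
        bias=pd.Series(bias, index=idx, name="bias"),
        inflation=pd.Series(infl, index=idx, name="inflation"),
        df_resid=df,
        null_flags=pd.Series(flags, index=idx, name="null_method"))


def select_significant(results: AssociationResults, domain: str,
                       alpha: float = 0.05, use_corrected: bool = True
                       ) -> pd.DataFrame:
    """Bonferroni-significant pairs within one distance domain.

    The Bonferroni family is the number of tested pairs in that domain.
    Returns a long-format frame (cpg, gene, t, p, p_bonf).
    """
    if domain not in (CIS, TRANS):
        raise ValueError(f"domain must be cis or trans, got {domain!r}")
    in_dom = results.mask.values == domain
    n_dom = int(in_dom.sum())
    if n_dom == 0:
        raise ValueError(f"no pairs in the {domain} domain")
    p = (results.p_corrected if use_corrected else results.p).values
    t = (results.t_corrected if use_corrected else results.t).values
    p_adj = np.minimum(p * n_dom, 1.0)
    sig = in_dom & (p_adj < alpha)
    ii, jj = np.where(sig)
    return pd.DataFrame({
        "cpg": results.mask.index[ii],
        "gene": results.mask.columns[jj],
        "t": t[ii, jj],
        "p": p[ii, jj],
        "p_bonf": p_adj[ii, jj],
    })


def core_set_threshold(clock_size: int, fraction: float = 0.05) -> int:
    return int(np.ceil(fraction * clock_size))


def select_core_set(results: AssociationResults,
                    clocks: Sequence[ClockModel] | Mapping[str, Iterable[str]],
                    fraction: float = 0.05, min_trans_genes: int = 10,
                    alpha: float = 0.05) -> CoreSet:
    """Core trans-association set.

    A gene is kept when its Bonferroni-significant trans-CpG count
    within ANY single clock reaches ceil(fraction * that clock's size);
    a CpG is kept when it is significantly associated with at least
    ``min_trans_genes`` trans-genes.
    """
    if isinstance(clocks, Mapping):
        membership = {name: set(cpgs) for name, cpgs in clocks.items()}
    else:
        membership = {c.name: set(c.coefficients) for c in clocks}
    sig = select_significant(results, TRANS, alpha=alpha)
    thresholds = {name: core_set_threshold(len(cpgs), fraction)
                  for name, cpgs in membership.items()}

    counts = {}
    for name, cpgs in membership.items():
        sub = sig[sig["cpg"].isin(cpgs)]
        counts[name] = sub.groupby("gene").size()
    gene_counts = pd.DataFrame(counts).reindex(results.mask.columns).fillna(0).astype(int)
    keep_gene = pd.Series(False, index=gene_counts.index)
    for name, thr in thresholds.items():
        keep_gene |= gene_counts[name] >= thr

    cpg_counts = sig.groupby("cpg").size().reindex(results.mask.index).fillna(0).astype(int)
    keep_cpg = cpg_counts >= min_trans_genes
    return CoreSet(
        genes=list(gene_counts.index[keep_gene]),
        cpgs=list(cpg_counts.index[keep_cpg]),
        clock_thresholds=thresholds,
        min_trans_genes=min_trans_genes,
        gene_counts=gene_counts,
        cpg_counts=cpg_counts)


def permutation_test(beta: pd.DataFrame, expression: PreprocessedExpression,
                     design: pd.DataFrame, cpg_coords: pd.DataFrame,
                     n_perm: int = 1000, seed: int = 0,
                     n_latent_factors: int = 5, alpha: float = 0.05,
                     observed: Optional[int] = None,
                     correct: bool = True,
                     n_protect_components: int = 10) -> PermutationResult:
    """Global-null permutation test on the trans-association count.

    Each permutation shuffles the methylation sample identifiers only
    (covariates and latent factors stay with the expression), reruns the
    trans analysis and counts Bonferroni-significant associations.
    The empirical p uses +1 smoothing.  Deterministic for a fixed seed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    samples = beta.index.intersection(expression.expr.index).intersection(design.index)
    cpgs = [c for c in beta.columns if c in cpg_coords.index
            and str(cpg_coords.loc[c, "chrom"]) in AUTOSOMES]
    b = beta.loc[samples, cpgs].values.astype(float)
    e = expression.expr.loc[samples].values.astype(float)
    d = design.loc[samples]
    if n_latent_factors > 0:
        lf = estimate_latent_factors(expression.expr.loc[samples], d,
                                     k=n_latent_factors, protect=b,
                                     n_protect=n_protect_components)
        d = pd.concat([d, lf], axis=1)
    x = d.values.astype(float)
    q = _qr_basis(x)
    er = e - q @ (q.T @ e)

    mask = classify_cis_trans(cpg_coords.loc[cpgs], expression.gene_coords)
    trans_mask = mask.values == TRANS
    n_trans = int(trans_mask.sum())
    if n_trans == 0:
        raise ValueError("no trans pairs to test")
    n, p_cols = x.shape
    df = n - p_cols - 1
    yy = np.einsum("ij,ij->j", er, er)

    def count_sig(bmat: np.ndarray) -> int:
        br = bmat - q @ (q.T @ bmat)
        bb = np.einsum("ij,ij->j", br, br)
        num = br.T @ er
        slope = num / bb[:, None]
        sse = np.maximum(yy[None, :] - slope * num, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = slope * np.sqrt(bb)[:, None] / np.sqrt(sse / df)
        t[sse == 0] = np.sign(slope[sse == 0]) * np.inf
        total = 0
        for i in range(t.shape[0]):
            if correct:
                _, pc, _, _, _ = empirical_null_correct(t[i], df)
            else:
                pc = 2.0 * stats.t.sf(np.abs(t[i]), df)
            total += int(((pc * n_trans) < alpha)[trans_mask[i]].sum())
        return total

    if observed is None:
        observed = count_sig(b)
    perm_counts = np.empty(n_perm, dtype=int)
    for k in range(n_perm):
        perm = rng.permutation(n)
        perm_counts[k] = count_sig(b[perm])
    emp_p = (1.0 + float((perm_counts >= observed).sum())) / (1.0 + n_perm)
    return PermutationResult(observed=int(observed), perm_counts=perm_counts,
                             empirical_p=emp_p)
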