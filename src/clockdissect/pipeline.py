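"""End-to-end orchestration: simulate -> clocks -> similarity ->
associations -> clustering -> crosscheck.

A single YAML/dict config drives all stages.  One global seed feeds
per-stage derived seeds (a stable hash of the stage name), so stages
are individually reproducible; rerunning an identical config reproduces
identical outputs.  Every run directory receives a ``summary.json``
stamped with the config hash and seed.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import io as cio
from ._utils import derive_seed
from .associations import (AssociationResults, CoreSet, association_scan,
                           build_design, permutation_test, preprocess_expression,
                           select_core_set, select_significant)
from .celltypes import (cluster_core_set, core_t_matrix, differential_group_test,
                        minmax_normalize_profiles, paired_delta_age,
                        predict_sorted_cell_ages)
from .clocks import (ClockModel, clock_concordance, extreme_deviation_overlap,
                     predict_age, prediction_error_summary, read_clock_model,
                     write_clock_model)
from .qtl import QTLRecord, crosscheck, summary_line
from .similarity import (cpg_overlap_matrix, feature_enrichment, annotate_cpgs,
                         proxy_fraction)
from .simulate import (GroundTruth, SimulationConfig, SyntheticCohort,
                       emit_sorted_cell_reference, make_synthetic_clock,
                       simulate_cohort)

log = logging.getLogger("clockdissect")

DEFAULT_CONFIG: dict = {
    "out_dir": "clockdissect_run",
    "seed": 0,
    "stages": ["simulate", "predict", "similarity", "assoc", "cluster", "crosscheck"],
    "simulation": {},
    "n_clocks": 4,
    "clock_transforms": ["identity", "horvath", "zhang", "identity"],
    "clock_n_cpgs": 60,
    "use_cellcounts": True,
    "n_latent_factors": 5,
    "n_perm": 100,
    "cis_window": 100_000,
    "trans_window": 5_000_000,
    "core_fraction": 0.05,
    "min_trans_genes": 10,
    "extreme_threshold": 10.0,
    "proxy_thresholds": [0.5, 0.7, 0.9],
    "enrichment_bonferroni": 9,
    "alpha": 0.05,
    "sorted_n_donors": 6,
    "sorted_age_offset": 30.0,
}

NAIVE_CELLTYPES = ["CD4_naive", "CD8_naive", "NK_naive"]
ACTIVATED_CELLTYPES = ["CD4_activated", "CD8_activated", "NK_activated"]


def load_config(source=None) -> dict:
    """Merge a YAML file / dict over the defaults."""
    cfg = {k: (v.copy() if isinstance(v, (dict, list)) else v)
           for k, v in DEFAULT_CONFIG.items()}
    if source is None:
        return cfg
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh) or {}
    for k, v in source.items():
        if k not in cfg:
            raise KeyError(f"unknown config key {k!r}")
        if isinstance(cfg.get(k), dict) and isinstance(v, dict):
            cfg[k].update(v)
        else:
            cfg[k] = v
    return cfg


def config_hash(cfg: dict) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    cfg = {k: v for k, v in cfg.items() if k != "out_dir"}
    return hashlib.sha1(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:12]


def make_synthetic_tracks(cpg_coords: pd.DataFrame, seed: int
                          ) -> dict[str, pd.DataFrame]:
    """Generate CGI / histone-peak / chromatin-state interval tracks over
    the cohort's chromosomes (BED, 0-based half-open), for exercising the
    enrichment analysis on synthetic data."""
    rng = np.random.default_rng(seed)
    rows_cgi, rows_peak, rows_state = [], [], []
    states = ["TssA", "ReprPC", "Quies"]
    for chrom, grp in cpg_coords.groupby("chrom"):
        lo = int(grp["pos"].min()) - 50_000
        hi = int(grp["pos"].max()) + 50_000
        for pos in grp["pos"]:
            if rng.random() < 0.3:          # CGI covering the CpG
                start = int(pos) - 1 - rng.integers(50, 400)
                rows_cgi.append((chrom, max(0, start), int(pos) + rng.integers(50, 400)))
            if rng.random() < 0.4:          # histone peak
                start = int(pos) - 1 - rng.integers(100, 1000)
                rows_peak.append((chrom, max(0, start), int(pos) + rng.integers(100, 1000)))
        # tile the chromosome with mutually exclusive state segments
        edges = np.sort(rng.integers(lo, hi, 6))
        bounds = [lo, *edges.tolist(), hi]
        for k in range(len(bounds) - 1):
            if bounds[k] < bounds[k + 1]:
                rows_state.append((chrom, bounds[k], bounds[k + 1],
                                   states[k % len(states)]))
    return {
        "cgi": pd.DataFrame(rows_cgi, columns=["chrom", "start", "end"]),
        "H3K4me3": pd.DataFrame(rows_peak, columns=["chrom", "start", "end"]),
        "states": pd.DataFrame(rows_state, columns=["chrom", "start", "end", "name"]),
    }


def build_clock_panel(truth: GroundTruth, cohort: SyntheticCohort,
                      cfg: dict, seed: int) -> list[ClockModel]:
    """Fit a panel of synthetic clocks with overlapping CpG subsets and
    different transforms, mimicking a set of published predictors."""
    clocks = []
    transforms = cfg["clock_transforms"][: cfg["n_clocks"]]
    for k, tr in enumerate(transforms):
        clocks.append(make_synthetic_clock(
            truth, cohort, transform_kind=tr, n_cpgs=cfg["clock_n_cpgs"],
            name=f"clock{k + 1}_{tr}", seed=derive_seed(seed, f"clock{k}")))
    return clocks


def _primary_samples(cohort: SyntheticCohort) -> list[str]:
    reps = {r for _, r in cohort.replicate_pairs}
    return [s for s in cohort.beta.index if s not in reps]


def run_pipeline(config=None, out_dir=None) -> dict:
    """Run the configured stages and return the machine-readable summary."""
    cfg = load_config(config)
    if out_dir is not None:
        cfg["out_dir"] = str(out_dir)
    out = Path(cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = list(cfg["stages"])
    summary: dict = {"config_hash": config_hash(cfg), "seed": seed, "stages": {}}

    def begin(stage):
        log.info("stage=%s start params=%s", stage,
                 {k: cfg[k] for k in ("seed",) if k in cfg})
        return time.time()

    def done(stage, t0, payload):
        log.info("stage=%s wall_time=%.2fs", stage, time.time() - t0)
        summary["stages"][stage] = payload

    cohort: Optional[SyntheticCohort] = None
    truth: Optional[GroundTruth] = None
    clocks: list[ClockModel] = []
    results: Optional[AssociationResults] = None
    core: Optional[CoreSet] = None
    expression = None

    if "simulate" in stages:
        t0 = begin("simulate")
        sim_cfg = SimulationConfig(**{**cfg["simulation"],
                                      "seed": derive_seed(seed, "simulate")})
        cohort, truth = simulate_cohort(sim_cfg)
        cio.write_cohort(cohort, out / "cohort")
        truth.cpg_cluster_labels.to_csv(out / "cohort" / "true_cpg_clusters.tsv", sep="\t")
        truth.gene_cluster_labels.to_csv(out / "cohort" / "true_gene_clusters.tsv", sep="\t")
        truth.cell_fractions.to_csv(out / "cohort" / "true_cell_fractions.tsv", sep="\t")
        clocks = build_clock_panel(truth, cohort, cfg, seed)
        for c in clocks:
            write_clock_model(c, out / f"{c.name}.csv")
        if truth.qtl_truth:
            for name, tab in truth.qtl_truth.items():
                cio.write_qtl_table(tab, out / f"qtl_{name}.tsv")
        done("simulate", t0, {
            "n_samples": int(sim_cfg.n_samples),
            "n_cpgs": int(sim_cfg.n_clock_cpgs),
            "n_genes": int(sim_cfg.n_genes),
            "clocks": [c.name for c in clocks]})

    if cohort is None and set(stages) - {"simulate"}:
        cohort = cio.read_cohort(out / "cohort")
        clocks = [read_clock_model(p) for p in sorted(out.glob("clock*.csv"))]

    primary = _primary_samples(cohort) if cohort else []

    if "predict" in stages:
        t0 = begin("predict")
        beta = cohort.beta.loc[primary]
        ages = cohort.covariates.loc[primary, "age"]
        preds = {c.name: predict_age(c, beta) for c in clocks}
        summaries = [prediction_error_summary(p, ages) for p in preds.values()]
        pred_df = pd.DataFrame({n: p.predicted for n, p in preds.items()})
        cio.write_matrix(pred_df, out / "predicted_ages.tsv")
        conc = clock_concordance(summaries)
        cio.write_matrix(conc, out / "error_concordance.tsv")
        errs = pd.DataFrame({s.clock_name: s.errors for s in summaries})
        ext = extreme_deviation_overlap(errs, threshold=cfg["extreme_threshold"])
        cio.write_matrix(ext, out / "extreme_overlap.tsv")
        done("predict", t0, {
            "mae": {s.clock_name: s.mae for s in summaries},
            "pearson_r": {s.clock_name: s.pearson_r for s in summaries},
            "error_concordance_min": float(np.nanmin(conc.values))})

    if "similarity" in stages:
        t0 = begin("similarity")
        ov = cpg_overlap_matrix(clocks)
        cio.write_matrix(ov.counts, out / "cpg_overlap_counts.tsv")
        cio.write_matrix(ov.percent, out / "cpg_overlap_percent.tsv")
        beta = cohort.beta.loc[primary]
        prox = {}
        for c in clocks:
            others = set().union(*(set(o.coefficients) for o in clocks if o.name != c.name))
            prox[f"{c.name}:within"] = proxy_fraction(
                c, beta, thresholds=cfg["proxy_thresholds"])
            prox[f"{c.name}:between"] = proxy_fraction(
                c, beta, reference_cpgs=others, thresholds=cfg["proxy_thresholds"])
        prox_df = pd.DataFrame(prox)
        cio.write_matrix(prox_df, out / "proxy_fractions.tsv")
        tracks = make_synthetic_tracks(cohort.cpg_coords, derive_seed(seed, "tracks"))
        annot = annotate_cpgs(cohort.cpg_coords, tracks["cgi"],
                              peak_tracks={"H3K4me3": tracks["H3K4me3"]},
                              state_track=tracks["states"])
        background = list(cohort.cpg_coords.index)
        enr_summary = {}
        for c in clocks:
            enr = feature_enrichment(list(c.coefficients), background, annot,
                                     m_bonferroni=cfg["enrichment_bonferroni"])
            enr.to_csv(out / f"enrichment_{c.name}.tsv", sep="\t")
            enr_summary[c.name] = int((enr["p_bonf"] < cfg["alpha"]).sum())
        done("similarity", t0, {
            "overlap_counts": ov.counts.to_dict(),
            "proxy_within_at_0.5": {c.name: float(prox[f"{c.name}:within"].iloc[0])
                                    for c in clocks},
            "n_enriched_features": enr_summary})

    if "assoc" in stages:
        t0 = begin("assoc")
        expression = preprocess_expression(cohort.counts, cohort.gene_coords)
        numeric = ("age", "basophil_pct", "eosinophil_pct", "lymphocyte_pct",
                   "monocyte_pct") if cfg["use_cellcounts"] else ("age",)
        design = build_design(cohort.covariates.loc[primary], numeric=numeric)
        union_cpgs = sorted(set().union(*(set(c.coefficients) for c in clocks)))
        beta = cohort.beta.loc[primary, [c for c in union_cpgs
                                         if c in cohort.beta.columns]]
        results = association_scan(
            beta, expression, design, cohort.cpg_coords,
            n_latent_factors=cfg["n_latent_factors"],
            cis_window=cfg["cis_window"], trans_window=cfg["trans_window"])
        long = []
        for domain in ("cis", "trans"):
            sig = select_significant(results, domain, alpha=cfg["alpha"])
            sig.insert(2, "class", domain)
            long.append(sig)
        sig_long = pd.concat(long, ignore_index=True)
        sig_long.to_csv(out / "significant_associations.tsv", sep="\t", index=False)
        core = select_core_set(results, clocks, fraction=cfg["core_fraction"],
                               min_trans_genes=cfg["min_trans_genes"],
                               alpha=cfg["alpha"])
        pd.Series(core.genes, name="gene").to_csv(out / "core_genes.tsv",
                                                  sep="\t", index=False)
        pd.Series(core.cpgs, name="cpg").to_csv(out / "core_cpgs.tsv",
                                                sep="\t", index=False)
        pd.DataFrame({"bias": results.bias, "inflation": results.inflation,
                      "method": results.null_flags}).to_csv(
            out / "null_correction.tsv", sep="\t")
        payload = {
            "n_cis_sig": int((sig_long["class"] == "cis").sum()),
            "n_trans_sig": int((sig_long["class"] == "trans").sum()),
            "core_genes": len(core.genes),
            "core_cpgs": len(core.cpgs),
            "clock_thresholds": core.clock_thresholds,
            "mean_inflation": float(results.inflation.mean())}
        if cfg["n_perm"] > 0:
            perm = permutation_test(
                beta, expression, design, cohort.cpg_coords,
                n_perm=cfg["n_perm"], seed=derive_seed(seed, "perm"),
                n_latent_factors=cfg["n_latent_factors"], alpha=cfg["alpha"])
            pd.DataFrame({"perm_count": perm.perm_counts}).to_csv(
                out / "permutation_counts.tsv", sep="\t", index=False)
            payload["permutation_p"] = perm.empirical_p
            payload["observed_trans_sig"] = perm.observed
            payload["perm_zero_fraction"] = float((perm.perm_counts == 0).mean())
        done("assoc", t0, payload)

    if "cluster" in stages:
        t0 = begin("cluster")
        if results is None or core is None:
            raise RuntimeError("cluster stage requires the assoc stage "
                               "(run 'assoc' first or include it in stages)")
        tmat = core_t_matrix(results, core, alpha=cfg["alpha"])
        heat = cluster_core_set(tmat)
        labels = pd.DataFrame({
            "id": [*heat.row_labels.index, *heat.col_labels.index],
            "axis": ["cpg"] * len(heat.row_labels) + ["gene"] * len(heat.col_labels),
            "cluster": [*heat.row_labels.values, *heat.col_labels.values]})
        labels.to_csv(out / "cluster_labels.tsv", sep="\t", index=False)
        payload = {
            "cpg_cluster_sizes": heat.row_labels.value_counts().to_dict(),
            "gene_cluster_sizes": heat.col_labels.value_counts().to_dict()}
        if truth is not None:
            from sklearn.metrics import adjusted_rand_score
            truth_labels = truth.cpg_cluster_labels.loc[heat.row_labels.index]
            payload["cpg_cluster_ari"] = float(adjusted_rand_score(
                truth_labels.values, heat.row_labels.values))
        if truth is not None:
            ref = emit_sorted_cell_reference(
                truth, n_donors=cfg["sorted_n_donors"],
                rng=np.random.default_rng(derive_seed(seed, "sorted")),
                age_offset=cfg["sorted_age_offset"])
            cio.write_sorted_reference(ref, out / "sorted_reference.tsv")
            norm_beta = minmax_normalize_profiles(ref.beta_celltype_medians)
            tests = []
            for cl in (1, 2):
                members = list(heat.row_labels.index[heat.row_labels == cl])
                tt, pp = differential_group_test(
                    norm_beta, members, NAIVE_CELLTYPES, ACTIVATED_CELLTYPES)
                tests.append(("cpg_cluster", cl, tt, pp))
            pd.DataFrame(tests, columns=["axis", "cluster", "t", "p"]).to_csv(
                out / "differential_tests.tsv", sep="\t", index=False)
            preds = predict_sorted_cell_ages(clocks, ref.beta)
            delta = paired_delta_age(preds, ref.sample_meta)
            delta.table.to_csv(out / "delta_age.tsv", sep="\t", index=False)
            payload["median_delta_age"] = {
                f"{r.clock}:{r.lineage}": r.median_delta
                for r in delta.table.itertuples()}
        done("cluster", t0, payload)

    if "crosscheck" in stages:
        t0 = begin("crosscheck")
        if results is None or core is None:
            raise RuntimeError("crosscheck stage requires the assoc stage")
        sig_trans = select_significant(results, "trans", alpha=cfg["alpha"])
        pairs = [(r.cpg, r.gene) for r in sig_trans.itertuples()
                 if r.cpg in set(core.cpgs) and r.gene in set(core.genes)]
        meqtls, eqtls = [], []
        if truth is not None and truth.qtl_truth:
            meqtls = [QTLRecord(r.snp, r.target, "methylation", "cis")
                      for r in truth.qtl_truth["cis_meqtl"].itertuples()]
            eqtls = [QTLRecord(r.snp, r.target, "expression", "trans")
                     for r in truth.qtl_truth["trans_eqtl"].itertuples()]
        res = crosscheck(pairs, meqtls, eqtls, direction="cpg_first")
        res.flagged.to_csv(out / "qtl_flagged.tsv", sep="\t", index=False)
        (out / "qtl_summary.txt").write_text(summary_line(res) + "\n")
        done("crosscheck", t0, {
            "n_pairs_checked": len(pairs),
            "n_flagged": int(len(res.flagged)),
            "summary": summary_line(res)})

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=str)
    return summary
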