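"""Config-driven orchestration: preprocess -> concordance -> pQTL -> cross-platform
-> PAV adjustment -> epidemiology, with a reproducible log.

`run_analysis` operates on in-memory objects (the synthetic generator's
output or objects read from files); `run_pipeline` is the file-level wrapper
driven by a YAML config.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import __version__
from .adjustment import (SignalComparison, adjustment_report_row,
                         compare_signals_post_adjustment, effect_heterogeneity,
                         pav_adjust)
from .concordance import (concordance_table, correlation_heterogeneity,
                          pairwise_correlation, per_ancestry_correlations)
from .crossplatform import (classify_protein, differentiation_flags,
                            eaf_by_group, eaf_chi_square_table, pair_table,
                            sentinel_overlap, trans_regions,
                            CATEGORY_DISCORDANT)
from .epi import association_table, lod_table, phenotype_association
from .io import (GenotypeData, PAV_CLASSES, ProteinMatrix, check_sample_alignment,
                 write_result_table)
from .pqtl import (cis_variants, credible_sets_table, dedup_credible_sets,
                   finemap, trans_variants)
from .preprocess import build_covariates, pc_scores, residualize_matrix, transform_matrix

ALL_STAGES = ("preprocess", "concordance", "pqtl", "crossplat", "adjust", "epi")


@dataclass
class PipelineConfig:
    groups: list[str] = field(default_factory=lambda: ["AFR", "AMR", "EAS", "EUR"])
    cis_window: int = 1_000_000
    cis_p: float = 5e-8
    trans_p: float = 1e-11
    ld_r2: float = 0.1
    pleio_min: int = 5
    pleio_max_other: int = 1
    pleio_half_window: int = 500_000
    diff_quantile: float = 0.75
    alpha: float = 0.05
    prior_variance: float = 0.04
    max_signals: int = 5
    int_offset: float = 0.5
    # PC covariates default to 0 at desk scale: scores computed from a
    # handful of simulated probes/variants would absorb the signal itself
    # (see docs); set to 10/10 for genome-scale inputs as in the reference design.
    n_protein_pcs: int = 0
    n_genotype_pcs: int = 0
    phenotypes: tuple = ("age", "sex", "bmi", "t2d")
    adjust_auto: bool = True
    pav_list: dict | None = None  # uniprot_id -> variant_id override
    stages: tuple = ALL_STAGES
    seed: int = 0

    def validate(self):
        for name, lo, hi in [("cis_p", 0, 1), ("trans_p", 0, 1), ("alpha", 0, 1),
                             ("ld_r2", 0, 1), ("diff_quantile", 0, 1)]:
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"config: {name}={v} out of range ({lo}, {hi})")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"config: unknown stages {sorted(unknown)}")
        return self


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_analysis(samples: pd.DataFrame, genotypes: GenotypeData,
                 mat_a: ProteinMatrix, mat_b: ProteinMatrix,
                 probe_map: pd.DataFrame, controls: pd.DataFrame | None = None,
                 ext_sentinels: pd.DataFrame | None = None,
                 config: PipelineConfig | None = None) -> dict:
    """Run the enabled stages in order and return a dict of result tables."""
    cfg = (config or PipelineConfig()).validate()
    log: dict = {"version": __version__, "seed": cfg.seed,
                 "thresholds": {"cis_p": cfg.cis_p, "trans_p": cfg.trans_p,
                                "ld_r2": cfg.ld_r2, "alpha": cfg.alpha,
                                "cis_window": cfg.cis_window,
                                "pleio_half_window": cfg.pleio_half_window,
                                "pleio_min": cfg.pleio_min,
                                "pleio_max_other": cfg.pleio_max_other,
                                "diff_quantile": cfg.diff_quantile,
                                "prior_variance": cfg.prior_variance,
                                "max_signals": cfg.max_signals,
                                "int_offset": cfg.int_offset,
                                "n_protein_pcs": cfg.n_protein_pcs,
                                "n_genotype_pcs": cfg.n_genotype_pcs},
                 "counts": {}}
    results: dict = {"log": log}
    sample_ids = list(samples.index)
    for what, ids in [("platform A matrix", mat_a.sample_ids),
                      ("platform B matrix", mat_b.sample_ids),
                      ("genotypes", genotypes.sample_ids)]:
        check_sample_alignment(sample_ids, ids, what)

    stage = "preprocess"
    try:
        t_a = transform_matrix(mat_a, cfg.int_offset)
        t_b = transform_matrix(mat_b, cfg.int_offset)
        extra = []
        if cfg.n_genotype_pcs > 0:
            dos = genotypes.dosages.copy()
            dos = dos.fillna(dos.mean())
            extra.append(pc_scores(dos, cfg.n_genotype_pcs, "gPC"))
        if cfg.n_protein_pcs > 0:
            extra.append(pc_scores(t_a.values.fillna(0.0), cfg.n_protein_pcs, "aPC"))
            extra.append(pc_scores(t_b.values.fillna(0.0), cfg.n_protein_pcs, "bPC"))
        extra_df = pd.concat(extra, axis=1) if extra else None
        covariates = build_covariates(samples, extra=extra_df)
        r_a = residualize_matrix(t_a, covariates)
        r_b = residualize_matrix(t_b, covariates)
        results["transformed"] = {"A": t_a, "B": t_b}
        results["residualized"] = {"A": r_a, "B": r_b}
        log["counts"]["covariate_columns"] = covariates.shape[1]
    except Exception as exc:  # noqa: BLE001 - abort with stage context
        raise StageError(stage, exc) from exc
    if "concordance" not in cfg.stages:
        return results

    stage = "concordance"
    try:
        conc = concordance_table(t_a, t_b, probe_map, samples, cfg.groups, cfg.alpha)
        results["concordance"] = conc
        log["counts"]["proteins_compared"] = len(conc)
        log["counts"]["het_significant"] = int(conc["het_significant"].sum())
    except Exception as exc:
        raise StageError(stage, exc) from exc
    if "pqtl" not in cfg.stages:
        return results

    stage = "pqtl"
    try:
        gene_of, tss_of, chrom_of = {}, {}, {}
        for row in probe_map.itertuples():
            gene_of[row.probe_id] = row.gene_symbol
            tss_of[row.probe_id] = int(row.tss)
            chrom_of[row.probe_id] = str(row.chrom)
        sets = {}  # (uniprot_id, platform, kind) -> list[CredibleSet]
        resid = {"A": r_a, "B": r_b}
        for row in conc.itertuples():
            probes = {"A": row.probe_id_A, "B": row.probe_id_B}
            for platform, probe in probes.items():
                y = resid[platform].values[probe].to_numpy(dtype=float)
                cis_ids = cis_variants(tss_of[probe], chrom_of[probe],
                                       genotypes.variants, cfg.cis_window)
                trans_ids = trans_variants(tss_of[probe], chrom_of[probe],
                                           genotypes.variants, cfg.cis_window)
                cis_sets = finemap(y, genotypes, "cis", probe, platform,
                                   variant_ids=cis_ids, threshold=cfg.cis_p,
                                   prior_variance=cfg.prior_variance,
                                   max_signals=cfg.max_signals)
                trans_sets = finemap(y, genotypes, "trans", probe, platform,
                                     variant_ids=trans_ids, threshold=cfg.trans_p,
                                     prior_variance=cfg.prior_variance,
                                     max_signals=cfg.max_signals) if trans_ids else []
                sets[(row.uniprot_id, platform)] = dedup_credible_sets(
                    cis_sets + trans_sets, genotypes)
        all_sets = [s for ss in sets.values() for s in ss]
        results["credible_sets"] = credible_sets_table(all_sets)
        results["_sets"] = sets
        log["counts"]["credible_sets"] = len(all_sets)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    if "crossplat" not in cfg.stages:
        return results

    stage = "crossplat"
    try:
        pairs = []
        for row in conc.itertuples():
            uid = row.uniprot_id
            cis_a = [s for s in sets.get((uid, "A"), []) if s.kind == "cis"]
            cis_b = [s for s in sets.get((uid, "B"), []) if s.kind == "cis"]
            pairs.extend(classify_protein(uid, cis_a, cis_b, genotypes.variants,
                                          gene_of[row.probe_id_A]))
        results["pairs"] = pair_table(pairs)
        results["_pairs"] = pairs
        eafs = eaf_by_group(genotypes, samples["ancestry"], cfg.groups)
        diff = eaf_chi_square_table(eafs, cfg.groups)
        threshold, flags = differentiation_flags(diff["x2"], cfg.diff_quantile)
        diff["differentiated"] = flags
        results["ancestry_diff"] = diff.reset_index()
        log["counts"]["x2_threshold"] = threshold
        trans_leads = pd.DataFrame([
            {"platform": s.platform, "probe_id": s.probe_id,
             "chrom": genotypes.variants.loc[s.lead, "chrom"],
             "pos": int(genotypes.variants.loc[s.lead, "pos"]), "p": s.lead_p}
            for ss in sets.values() for s in ss if s.kind == "trans" and s.significant
        ])
        results["pleio_regions"] = trans_regions(
            trans_leads, cfg.pleio_half_window, cfg.pleio_min, cfg.pleio_max_other)
        if ext_sentinels is not None:
            results["sentinel_overlap"] = sentinel_overlap(
                all_sets, ext_sentinels, gene_of)
        log["counts"]["pair_categories"] = (
            results["pairs"]["category"].value_counts().to_dict()
            if len(results["pairs"]) else {})
    except Exception as exc:
        raise StageError(stage, exc) from exc
    if "adjust" not in cfg.stages:
        return results

    stage = "adjust"
    try:
        targets = {}  # uniprot_id -> pav variant id
        if cfg.pav_list:
            targets.update(cfg.pav_list)
        elif cfg.adjust_auto:
            for pc in pairs:
                if pc.category != CATEGORY_DISCORDANT:
                    continue
                gene = gene_of[pc.set_A.probe_id]
                candidates = [pc.compared_sentinel] + sorted(
                    set(pc.set_A.members) & set(pc.set_B.members))
                for vid in candidates:
                    if vid is None or vid not in genotypes.variants.index:
                        continue
                    v = genotypes.variants.loc[vid]
                    if (v["consequence_class"] in PAV_CLASSES
                            and v["consequence_gene"] == gene):
                        targets[pc.uniprot_id] = vid
                        break
        adj_rows, comparisons, het_rows = [], {}, []
        labels = samples["ancestry"].to_numpy()
        for row in conc.itertuples():
            uid = row.uniprot_id
            if uid not in targets:
                continue
            pav_id = targets[uid]
            dose = genotypes.dosage(pav_id)
            xa = t_a.values[row.probe_id_A].to_numpy(dtype=float)
            xb = t_b.values[row.probe_id_B].to_numpy(dtype=float)
            xa_post, xb_post = pav_adjust(xa, dose), pav_adjust(xb, dose)
            r_pre, _ = pairwise_correlation(xa, xb)
            r_post, _ = pairwise_correlation(xa_post, xb_post)
            pre_g = per_ancestry_correlations(xa, xb, labels, cfg.groups)
            post_g = per_ancestry_correlations(xa_post, xb_post, labels, cfg.groups)
            q_pre = q_post = p_pre = p_post = np.nan
            if len(pre_g) >= 2:
                q_pre, _, p_pre = correlation_heterogeneity(
                    [(r, n) for _, r, n in pre_g])
            if len(post_g) >= 2:
                q_post, _, p_post = correlation_heterogeneity(
                    [(r, n) for _, r, n in post_g])
            adj_rows.append(adjustment_report_row(
                uid, pav_id, r_pre, r_post, pre_g, post_g,
                q_pre, q_post, p_pre, p_post))
            # phenotype associations pre/post with cross-platform heterogeneity
            for pheno in cfg.phenotypes:
                for tag, va, vb in [("pre", xa, xb), ("post", xa_post, xb_post)]:
                    fa = phenotype_association(va, pheno, samples,
                                               row.probe_id_A, "A")
                    fb = phenotype_association(vb, pheno, samples,
                                               row.probe_id_B, "B")
                    if fa.flagged or fb.flagged:
                        continue
                    q, p = effect_heterogeneity(fa.beta, fa.se, fb.beta, fb.se)
                    het_rows.append({"uniprot_id": uid, "phenotype": pheno,
                                     "stage": tag,
                                     "beta_A": fa.beta, "se_A": fa.se,
                                     "beta_B": fb.beta, "se_B": fb.se,
                                     "Q": q, "p": p})
            # re-map cis signals with the PAV as covariate
            for platform, probe in [("A", row.probe_id_A), ("B", row.probe_id_B)]:
                pre_sets = [s for s in sets.get((uid, platform), []) if s.kind == "cis"]
                y = resid[platform].values[probe].to_numpy(dtype=float)
                y_post = pav_adjust(y, dose)
                cis_ids = cis_variants(tss_of[probe], chrom_of[probe],
                                       genotypes.variants, cfg.cis_window)
                post_sets = dedup_credible_sets(
                    finemap(y_post, genotypes, "cis", probe, platform,
                            variant_ids=cis_ids, threshold=cfg.cis_p,
                            prior_variance=cfg.prior_variance,
                            max_signals=cfg.max_signals), genotypes)
                comparisons[(uid, platform)] = compare_signals_post_adjustment(
                    pre_sets, post_sets, genotypes)
        results["adjustment"] = pd.DataFrame(adj_rows)
        results["adjustment_het"] = pd.DataFrame(het_rows)
        results["_signal_comparison"] = comparisons
        results["signal_comparison"] = pd.DataFrame([
            {"uniprot_id": uid, "platform": plat,
             "strengthened": len(c.strengthened), "attenuated": len(c.attenuated),
             "newly_associated": len(c.newly_associated),
             "ld_filtered": len(c.unmatched_ld_filtered)}
            for (uid, plat), c in comparisons.items()])
        log["counts"]["adjusted_proteins"] = len(adj_rows)
    except Exception as exc:
        raise StageError(stage, exc) from exc
    if "epi" not in cfg.stages:
        return results

    stage = "epi"
    try:
        assocs = []
        for row in conc.itertuples():
            for platform, probe, mat in [("A", row.probe_id_A, t_a),
                                         ("B", row.probe_id_B, t_b)]:
                for pheno in cfg.phenotypes:
                    assocs.append(phenotype_association(
                        mat.values[probe].to_numpy(dtype=float), pheno,
                        samples, probe, platform))
        results["epi_assoc"] = association_table(assocs)
        if controls is not None:
            results["lod"] = lod_table(mat_b, controls)
            log["counts"]["probes_with_lod"] = len(results["lod"])
    except Exception as exc:
        raise StageError(stage, exc) from exc
    return results


OUTPUT_TABLES = ["concordance", "credible_sets", "pairs", "ancestry_diff",
                 "pleio_regions", "sentinel_overlap", "adjustment",
                 "adjustment_het", "signal_comparison", "epi_assoc", "lod"]


def write_results(results: dict, out_dir) -> list[str]:
    """Write every result table plus the run log; returns written paths."""
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for name in OUTPUT_TABLES:
        if name in results and isinstance(results[name], pd.DataFrame):
            path = os.path.join(out_dir, f"{name}.tsv")
            write_result_table(results[name], path, precision=8)
            written.append(path)
    log_path = os.path.join(out_dir, "log.json")
    with open(log_path, "w") as fh:
        json.dump(results["log"], fh, indent=2, sort_keys=True)
    written.append(log_path)
    return written


def run_pipeline(config: dict, out_dir) -> dict:
    """File-level entry point: ``config`` maps input paths plus options.

    Required keys: genotypes (VCF), protein_a, protein_b, samples, probe_map
    (TSV paths).  Optional: annotation, negative_controls, sentinels, and
    any :class:`PipelineConfig` field under ``options``.
    """
    from .io import (attach_annotation, read_genotype_vcf, read_matrix_tsv,
                     read_negative_controls, read_probe_map, read_sample_table,
                     read_sentinel_table, read_variant_annotation)

    for key in ("genotypes", "protein_a", "protein_b", "samples", "probe_map"):
        if key not in config:
            raise ValueError(f"config missing required input path: {key!r}")
        if not os.path.exists(config[key]):
            raise FileNotFoundError(config[key])
    opts = PipelineConfig(**config.get("options", {})).validate()
    samples = read_sample_table(config["samples"], opts.groups)
    genotypes = read_genotype_vcf(config["genotypes"], samples=list(samples.index))
    if config.get("annotation"):
        genotypes = attach_annotation(genotypes,
                                      read_variant_annotation(config["annotation"]))
    mat_a = read_matrix_tsv(config["protein_a"], "A")
    mat_b = read_matrix_tsv(config["protein_b"], "B")
    probe_map = read_probe_map(config["probe_map"])
    controls = (read_negative_controls(config["negative_controls"])
                if config.get("negative_controls") else None)
    ext = (read_sentinel_table(config["sentinels"])
           if config.get("sentinels") else None)
    results = run_analysis(samples, genotypes, mat_a, mat_b, probe_map,
                           controls, ext, opts)
    write_results(results, out_dir)
    return results
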