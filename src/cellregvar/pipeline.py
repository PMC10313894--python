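"""End-to-end toy pipeline on generated data.

Runs the full chain — simulate, train cluster models, project variant
effects, test specificity and select functional variants, map interaction
eQTLs, merge by LD, and run the GWAS downstream steps — inside one seeded
workspace, writing deterministic TSV artifacts plus a JSON metrics summary.
Identical configurations and seeds produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coloc as coloc_mod
from . import enrichment  # noqa: F401  (re-exported for pipeline users)
from . import integration as integ
from . import io as cio
from . import simulate as sim
from .feature_model import (TrainConfig, evaluate_model, split_by_chromosome,
                            train_expression_model)
from .ieqtl import (adjust_pvalues, classify_negative_ieqtl,
                    inverse_normal_transform, map_cis_ieqtls)
from .mutagenesis import effect_matrix, select_functional_variants, \
    specificity_table

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Toy-scale pipeline configuration with the framework's thresholds."""

    seed: int = 0
    # simulation sizes
    n_genes: int = 120
    n_features: int = 6
    n_bins: int = 10
    grid_rank: int = 3
    grid_noise_sd: float = 0.05
    expression_noise_sd: float = 0.01
    n_clusters: int = 8
    n_celltypes: int = 4
    n_samples: int = 150
    n_variants: int = 60
    ld_block: int = 4
    copy_prob: float = 0.99  # tight within-block LD: links are unambiguous
    n_qtl_genes: int = 6
    causal_min_maf: float = 0.2  # planted ieQTL causals sit at common variants
    planted_beta1: float = 1.0
    cohort_noise_sd: float = 1.0
    delta_planted_fraction: float = 0.2
    delta_effect_size: float = 6.0
    # training
    max_rounds: int = 40
    early_stop_rounds: int = 10
    eta: float = 0.5
    l2_lambda: float = 100.0
    holdout_chromosome: str = "chr8"
    # thresholds (framework defaults)
    maf_floor: float = 0.05
    cis_window_bp: float = 1e6
    fdr_ceiling: float = 0.4
    r2_floor: float = 0.8
    abs_effect_floor: float = 0.5
    top_k: int = 2000
    gwas_p_ceiling: float = 1e-5
    pp4_floor: float = 0.85
    credible_coverage: float = 0.95

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g", **kwargs)


def run_pipeline(config: PipelineConfig, workdir: str | Path) -> dict:
    """Execute every stage on seeded synthetic inputs; return the metrics.

    Artifacts land under ``workdir`` (created if needed): stage TSVs, a
    manifest, and metrics.json with the headline recovery numbers.
    """
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    # --- stage 0: simulate -------------------------------------------------
    gene_table = sim.gen_gene_table(cfg.n_genes, seed=cfg.seed)
    grids, grid_truth = sim.gen_feature_grids(
        cfg.n_genes, cfg.n_features, cfg.n_bins, rank=cfg.grid_rank,
        noise_sd=cfg.grid_noise_sd, seed=cfg.seed)
    p = cfg.n_features * cfg.n_bins
    true_w = rng.normal(scale=1.0, size=(cfg.n_clusters, p)) / np.sqrt(p)
    expr, _ = sim.gen_expression_from_grids(
        grids, true_w, noise_sd=cfg.expression_noise_sd, seed=cfg.seed)
    celltypes = [f"CT{i}" for i in range(cfg.n_celltypes)]
    cluster_celltypes = {f"C{j:02d}": celltypes[j % cfg.n_celltypes]
                         for j in range(cfg.n_clusters)}
    genotypes = sim.gen_genotypes(
        cfg.n_samples, cfg.n_variants, ld_block=cfg.ld_block,
        copy_prob=cfg.copy_prob, seed=cfg.seed)
    cio.write_feature_store(grids, workdir / "features.h5")
    gene_table.to_csv(workdir / "genes.tsv", sep="\t", index=False)
    cio.write_dosage_tsv(genotypes, workdir / "dosages.tsv")

    # --- stage 1: train per-cluster expression models ----------------------
    train_ids, test_ids = split_by_chromosome(gene_table,
                                              cfg.holdout_chromosome)
    X = np.stack([grids[g].flatten() for g in expr.index])
    idx = {g: i for i, g in enumerate(expr.index)}
    Xtr = X[[idx[g] for g in train_ids]]
    Xte = X[[idx[g] for g in test_ids]]
    tc = TrainConfig(max_rounds=cfg.max_rounds,
                     early_stop_rounds=cfg.early_stop_rounds, eta=cfg.eta,
                     l2_lambda=cfg.l2_lambda,
                     holdout_chromosome=cfg.holdout_chromosome)
    models, eval_rows = [], []
    for j, cluster in enumerate(expr.columns):
        m = train_expression_model(Xtr, expr.loc[train_ids, cluster].to_numpy(),
                                   tc, seed=cfg.seed + j, cluster_id=cluster)
        ev = evaluate_model(m, Xte, expr.loc[test_ids, cluster].to_numpy())
        models.append(m)
        eval_rows.append({"cluster_id": cluster, "pcc": ev.pcc,
                          "n_test": ev.n_test, "rounds_used": m.rounds_used})
    eval_table = pd.DataFrame(eval_rows).set_index("cluster_id")
    _write_tsv(eval_table, workdir / "model_eval.tsv")

    # --- stage 2: in-silico mutagenesis ------------------------------------
    deltas, delta_truth = sim.gen_variant_deltas(
        cfg.n_variants, np.stack([m.weights for m in models]),
        [cluster_celltypes[m.cluster_id] for m in models],
        planted_fraction=cfg.delta_planted_fraction,
        effect_size=cfg.delta_effect_size, seed=cfg.seed)
    effects = effect_matrix(deltas, models)
    _write_tsv(effects, workdir / "effects.tsv", index_label="variant_id")
    functional_sets = {}
    spec_tables = {}
    for ct in celltypes:
        spec = specificity_table(effects, cluster_celltypes, ct)
        spec_tables[ct] = spec
        _write_tsv(spec, workdir / f"specificity_{ct}.tsv")
        fs = select_functional_variants(spec, effects, cluster_celltypes, ct,
                                        abs_floor=cfg.abs_effect_floor,
                                        top_k=cfg.top_k)
        functional_sets[ct] = fs.variant_ids
    pd.DataFrame([{"celltype": ct, "variant_id": v}
                  for ct in sorted(functional_sets)
                  for v in functional_sets[ct]]).to_csv(
        workdir / "functional_variants.tsv", sep="\t", index=False)

    # --- stage 3: interaction-eQTL mapping ---------------------------------
    # planted causal variants must themselves be testable and common enough
    # for a well-powered interaction test at this cohort size
    maf = genotypes.maf
    planted = [v for v in sorted(delta_truth.specific_celltype)
               if maf[v] >= max(cfg.maf_floor, cfg.causal_min_maf)]
    chr1_genes = gene_table[gene_table["chrom"] == "chr1"]
    qtl_genes = list(chr1_genes["gene_id"].iloc[:cfg.n_qtl_genes])
    causal_map = {}
    records = []
    for i, gid in enumerate(qtl_genes):
        causal = planted[i % len(planted)] if planted else \
            genotypes.dosages.columns[i]
        causal_map[gid] = causal
        y, frac_raw, covs, _ = sim.gen_ieqtl_cohort(
            genotypes, beta1=cfg.planted_beta1, beta2=0.3, beta3=0.2,
            causal_variant=causal, noise_sd=cfg.cohort_noise_sd,
            seed=cfg.seed + 100 + i)
        f = inverse_normal_transform(frac_raw)
        tss = int(gene_table.set_index("gene_id").loc[gid, "tss"])
        _, rec = map_cis_ieqtls(gid, "chr1", tss, y.to_numpy(), genotypes, f,
                                covs.to_numpy(), window_bp=cfg.cis_window_bp,
                                maf_floor=cfg.maf_floor)
        if rec is None:
            continue
        rec.cluster_id = "C00"
        rec.negative_flag = classify_negative_ieqtl(
            y.to_numpy(), genotypes.dosages[rec.variant_id].to_numpy(), f,
            covs.to_numpy())
        records.append(rec)
    top_p = pd.Series({r.gene_id: r.fit.p_interaction for r in records})
    m_eff = pd.Series({r.gene_id: r.m_eff for r in records})
    adj = adjust_pvalues(top_p, m_eff)
    qtl_table = pd.DataFrame([
        {"gene_id": r.gene_id, "cluster_id": r.cluster_id,
         "variant_id": r.variant_id, "beta1": r.fit.beta1,
         "beta2": r.fit.beta2, "beta3": r.fit.beta3,
         "p_interaction": r.fit.p_interaction,
         "n_cis_variants": r.n_cis_variants, "m_eff": r.m_eff,
         "pval_emt": adj.loc[r.gene_id, "pval_emt"],
         "pval_adj_bh": adj.loc[r.gene_id, "pval_adj_bh"],
         "negative_flag": r.negative_flag, "source": "ieQTL"}
        for r in records]).sort_values("gene_id")
    _write_tsv(qtl_table, workdir / "ieqtl.tsv", index=False)

    # --- stage 4: LD integration -------------------------------------------
    ld = integ.compute_ld(genotypes.dosages)
    candidates = integ.select_candidate_qtls(qtl_table, cfg.fdr_ceiling)
    all_functional = sorted({v for vs in functional_sets.values() for v in vs})
    links = integ.merge_variants(all_functional, candidates, ld,
                                 r2_floor=cfg.r2_floor)
    link_table = pd.DataFrame([
        {"functional_variant": r.functional_variant,
         "qtl_variant": r.qtl_variant, "r2": r.r2, "gene_id": r.gene_id,
         "source": r.source, "fdr": r.fdr} for r in links])
    _write_tsv(link_table, workdir / "integration.tsv", index=False)

    truth_pairs = set()
    for gid, causal in causal_map.items():
        if causal not in ld.r2.index:
            continue
        for v in delta_truth.causal_variant_ids:
            r2 = ld.get(v, causal)
            if np.isfinite(r2) and r2 > cfg.r2_floor:
                truth_pairs.add((v, gid))
    found_pairs = {(r.functional_variant, r.gene_id) for r in links}
    recall = (len(found_pairs & truth_pairs) / len(truth_pairs)
              if truth_pairs else np.nan)
    precision = (len(found_pairs & truth_pairs) / len(found_pairs)
                 if found_pairs else np.nan)

    # --- stage 5: GWAS downstream ------------------------------------------
    gwas_causal = causal_map[qtl_genes[0]]
    gwas = sim.gen_gwas_summary(genotypes, gwas_causal, effect=0.6,
                                seed=cfg.seed)
    cio.write_gwas_tsv(gwas, workdir / "gwas.tsv")
    regions = coloc_mod.define_gwas_regions(gwas, cfg.gwas_p_ceiling)
    credible = {}
    for _, reg in regions.iterrows():
        in_reg = gwas[(gwas["chrom"] == reg["chrom"])
                      & (gwas["pos"] >= reg["start"])
                      & (gwas["pos"] <= reg["end"])]
        credible[reg["region_id"]] = coloc_mod.abf_credible_set(
            in_reg, coverage=cfg.credible_coverage,
            region_id=reg["region_id"])
    cs_rows = [{"region_id": rid, "variant_id": v,
                "pip": cs.pips[v]}
               for rid, cs in sorted(credible.items())
               for v in cs.variant_ids]
    _write_tsv(pd.DataFrame(cs_rows, columns=["region_id", "variant_id",
                                              "pip"]),
               workdir / "credible_sets.tsv", index=False)
    gene_links = pd.Series({r.functional_variant: r.gene_id for r in links})
    v2f = coloc_mod.variant_to_function_map(
        credible, functional_sets, regions, gwas, gene_links, trait="trait1")
    _write_tsv(v2f, workdir / "v2f.tsv", index=False)

    metrics = {
        "median_holdout_pcc": float(eval_table["pcc"].median()),
        "n_functional_variants": len(all_functional),
        "n_candidate_qtls": int(len(candidates)),
        "n_integration_links": int(len(links)),
        "integration_recall": float(recall),
        "integration_precision": float(precision),
        "n_gwas_regions": int(len(regions)),
        "n_v2f_mappings": int(len(v2f)),
        "seed": cfg.seed,
    }
    with open(workdir / "metrics.json", "w") as fh:
        json.dump(metrics, fh, indent=2, sort_keys=True)
    manifest = sorted(f.name for f in workdir.iterdir() if f.is_file())
    with open(workdir / "manifest.json", "w") as fh:
        json.dump({"files": manifest}, fh, indent=2)
    return metrics
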