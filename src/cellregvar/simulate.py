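"""Seeded synthetic-data generators with known ground truth.

Every input the pipeline consumes can be generated here: low-rank chromatin
feature grids, linear expression truth, LD-blocked dosage matrices, cohorts
with planted genotype-by-fraction interaction effects, variant delta vectors
with planted cell type-specific signal, and GWAS summaries with a planted
causal variant.  All generators are pure functions of (parameters, seed); a
single top-level seed fans out to independent child streams by fixed offsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .feature_model import FeatureGrid, FeatureLayout
from .ieqtl import GenotypeMatrix, inverse_normal_transform
from .mutagenesis import DeltaVector

__all__ = [
    "SimTruth",
    "gen_feature_grids",
    "gen_gene_table",
    "gen_expression_from_grids",
    "gen_genotypes",
    "gen_ieqtl_cohort",
    "gen_variant_deltas",
    "gen_gwas_summary",
    "child_seed",
]

# fixed offsets give independent child streams from one global seed
_SEED_OFFSETS = {
    "grids": 11, "expression": 23, "genotypes": 37, "cohort": 53,
    "deltas": 71, "gwas": 89,
}


def child_seed(seed: int, stream: str) -> int:
    return (int(seed) * 1000 + _SEED_OFFSETS[stream]) % (2 ** 31 - 1)


@dataclass
class SimTruth:
    """Planted ground truth of a simulation, for recovery tests."""

    seed: int
    true_weights: np.ndarray | None = None           # per-cluster (k x p)
    intercepts: np.ndarray | None = None
    planted_beta1: float | None = None
    planted_beta2: float | None = None
    planted_beta3: float | None = None
    causal_variant_ids: list[str] = field(default_factory=list)
    specific_celltype: dict[str, str] = field(default_factory=dict)
    extras: dict = field(default_factory=dict)


def gen_gene_table(n_genes: int, seed: int = 0,
                   chroms: tuple[str, ...] = ("chr1", "chr2", "chr8"),
                   ) -> pd.DataFrame:
    """Gene annotation table (gene_id, chrom, tss, strand) for fixtures.

    Genes are spread round-robin across chromosomes with 50 kb TSS spacing.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_genes):
        chrom = chroms[i % len(chroms)]
        rows.append({"gene_id": f"G{i:04d}", "chrom": chrom,
                     "tss": 100_000 + (i // len(chroms)) * 50_000,
                     "strand": "+" if rng.random() < 0.5 else "-"})
    return pd.DataFrame(rows)


def gen_feature_grids(n_genes: int, n_features: int, n_bins: int,
                      rank: int = 3, noise_sd: float = 0.1, seed: int = 0,
                      ) -> tuple[dict[str, FeatureGrid], SimTruth]:
    """Low-rank structured chromatin feature grids plus Gaussian noise.

    Each gene's grid is a gene-specific mixture of ``rank`` shared patterns;
    with noise_sd=0 and rank=1 every grid is a scalar multiple of a single
    pattern.
    """
    if n_genes < 1 or n_features < 1 or n_bins < 1:
        raise ValueError("dimensions must be positive")
    p = n_features * n_bins
    if rank > min(p, n_genes):
        raise ValueError("rank must be <= min(n_features*n_bins, n_genes)")
    rng = np.random.default_rng(child_seed(seed, "grids"))
    # bin width 200 bp; half-window chosen so the bin count comes out exact
    layout = FeatureLayout(window_bp=n_bins * 100, bin_bp=200,
                           n_features=n_features)
    patterns = rng.normal(size=(rank, n_features, n_bins))
    loadings = rng.normal(size=(n_genes, rank))
    grids = {}
    for i in range(n_genes):
        g = np.tensordot(loadings[i], patterns, axes=1)
        if noise_sd > 0:
            g = g + rng.normal(scale=noise_sd, size=g.shape)
        grids[f"G{i:04d}"] = FeatureGrid(gene_id=f"G{i:04d}", values=g,
                                         layout=layout)
    truth = SimTruth(seed=seed, extras={"patterns": patterns,
                                        "loadings": loadings,
                                        "layout": layout})
    return grids, truth


def gen_expression_from_grids(grids: dict[str, FeatureGrid],
                              true_weights: np.ndarray,
                              noise_sd: float = 0.1, seed: int = 0,
                              intercepts: np.ndarray | None = None,
                              ) -> tuple[pd.DataFrame, SimTruth]:
    """Linear expression truth: intercept + weights . flattened grid + noise.

    ``true_weights`` is (n_clusters x p) or (p,) for a single cluster; the
    returned table is gene-by-cluster.
    """
    W = np.atleast_2d(np.asarray(true_weights, dtype=float))
    k = W.shape[0]
    gene_ids = sorted(grids)
    p = grids[gene_ids[0]].flatten().shape[0]
    if W.shape[1] != p:
        raise ValueError(f"weight length {W.shape[1]} != grid size {p}")
    if intercepts is None:
        intercepts = np.zeros(k)
    rng = np.random.default_rng(child_seed(seed, "expression"))
    X = np.stack([grids[g].flatten() for g in gene_ids])
    expr = intercepts[None, :] + X @ W.T
    if noise_sd > 0:
        expr = expr + rng.normal(scale=noise_sd, size=expr.shape)
    table = pd.DataFrame(expr, index=gene_ids,
                         columns=[f"C{j:02d}" for j in range(k)])
    truth = SimTruth(seed=seed, true_weights=W, intercepts=np.asarray(intercepts))
    return table, truth


def gen_genotypes(n_samples: int, n_variants: int,
                  maf_low: float = 0.05, maf_high: float = 0.5,
                  ld_block: int = 5, copy_prob: float = 0.9,
                  chrom: str = "chr1", start_pos: int = 10_000,
                  spacing_bp: int = 1_000, seed: int = 0) -> GenotypeMatrix:
    """LD-blocked dosage matrix with dosages in {0, 1, 2}.

    Within a block of ``ld_block`` consecutive variants, each variant copies
    the previous one's dosage per sample with probability ``copy_prob`` and
    otherwise redraws it binomially at the block's MAF, so empirical r^2
    decays geometrically with within-block distance.  Blocks are independent.
    """
    if not (0 < maf_low <= maf_high <= 0.5):
        raise ValueError("need 0 < maf_low <= maf_high <= 0.5")
    if n_samples < 1 or n_variants < 1 or ld_block < 1:
        raise ValueError("dimensions must be positive")
    rng = np.random.default_rng(child_seed(seed, "genotypes"))
    dosages = np.empty((n_samples, n_variants), dtype=np.int64)
    for v in range(n_variants):
        new_block = v % ld_block == 0
        if new_block:
            maf = rng.uniform(maf_low, maf_high)
            dosages[:, v] = rng.binomial(2, maf, size=n_samples)
            block_maf = maf
        else:
            fresh = rng.binomial(2, block_maf, size=n_samples)
            copy = rng.random(n_samples) < copy_prob
            dosages[:, v] = np.where(copy, dosages[:, v - 1], fresh)
    ids = [f"V{v:05d}" for v in range(n_variants)]
    variants = pd.DataFrame({
        "chrom": chrom,
        "pos": start_pos + spacing_bp * np.arange(n_variants),
        "ref": "A", "alt": "C",
    }, index=pd.Index(ids, name="variant_id"))
    dos = pd.DataFrame(dosages, columns=ids,
                       index=[f"S{s:04d}" for s in range(n_samples)])
    return GenotypeMatrix(dosages=dos, variants=variants)


def gen_ieqtl_cohort(genotypes: GenotypeMatrix, beta1: float, beta2: float,
                     beta3: float, causal_variant: str | None = None,
                     covariate_effects: np.ndarray | None = None,
                     n_covariates: int = 2, noise_sd: float = 1.0,
                     seed: int = 0) -> tuple[pd.Series, pd.Series,
                                             pd.DataFrame, SimTruth]:
    """Cohort with a planted genotype-by-fraction interaction.

    Fractions are drawn log-normal on the positive scale and passed through
    the same rank-based inverse normal transform the mapper uses; the
    phenotype is y = b1*g*f + b2*g + b3*f + C@gamma + eps with the
    transformed fraction f.  Returns (y, fraction_raw, covariates, truth).
    """
    rng = np.random.default_rng(child_seed(seed, "cohort"))
    samples = genotypes.dosages.index
    n = len(samples)
    if causal_variant is None:
        causal_variant = genotypes.dosages.columns[0]
    g = genotypes.dosages[causal_variant].to_numpy(dtype=float)
    raw_fraction = rng.lognormal(mean=0.0, sigma=0.6, size=n)
    f = inverse_normal_transform(raw_fraction)
    if covariate_effects is None:
        covariate_effects = rng.normal(scale=0.3, size=n_covariates)
    covariate_effects = np.asarray(covariate_effects, dtype=float)
    C = rng.normal(size=(n, covariate_effects.size))
    y = beta1 * g * f + beta2 * g + beta3 * f + C @ covariate_effects
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=n)
    truth = SimTruth(seed=seed, planted_beta1=beta1, planted_beta2=beta2,
                     planted_beta3=beta3, causal_variant_ids=[causal_variant],
                     extras={"covariate_effects": covariate_effects})
    return (pd.Series(y, index=samples, name="y"),
            pd.Series(raw_fraction, index=samples, name="fraction"),
            pd.DataFrame(C, index=samples,
                         columns=[f"cov{j}" for j in range(C.shape[1])]),
            truth)


def gen_variant_deltas(n_variants: int, cluster_weights: np.ndarray,
                       cluster_celltypes: list[str],
                       planted_fraction: float = 0.2,
                       effect_size: float = 1.0, noise_sd: float = 1.0,
                       seed: int = 0) -> tuple[list[DeltaVector], SimTruth]:
    """Delta vectors with cell type-specific signal planted in a subset.

    A ``planted_fraction`` of variants receives, on top of isotropic noise,
    ``effect_size`` times the unit mean-weight direction of one randomly
    chosen cell type's clusters — so only that cell type's models project a
    large effect.  The remaining variants are pure noise.
    """
    if not (0 <= planted_fraction <= 1):
        raise ValueError("planted_fraction must lie in [0, 1]")
    W = np.atleast_2d(np.asarray(cluster_weights, dtype=float))
    celltypes = sorted(set(cluster_celltypes))
    rng = np.random.default_rng(child_seed(seed, "deltas"))
    p = W.shape[1]
    n_planted = int(round(planted_fraction * n_variants))
    planted_idx = set(rng.choice(n_variants, size=n_planted, replace=False))
    deltas, specific = [], {}
    for v in range(n_variants):
        vec = rng.normal(scale=noise_sd, size=p) / np.sqrt(p)
        vid = f"V{v:05d}"
        if v in planted_idx:
            ct = celltypes[rng.integers(len(celltypes))]
            mask = np.asarray([c == ct for c in cluster_celltypes])
            direction = W[mask].mean(axis=0)
            norm = np.linalg.norm(direction)
            if norm > 0:
                vec = vec + effect_size * direction / norm
            specific[vid] = ct
        deltas.append(DeltaVector(variant_id=vid, gene_id="G0000", values=vec))
    truth = SimTruth(seed=seed, causal_variant_ids=sorted(specific),
                     specific_celltype=specific)
    return deltas, truth


def gen_gwas_summary(genotypes: GenotypeMatrix, causal_variant: str,
                     effect: float = 0.5, n_gwas: int = 10_000,
                     h2_noise: float = 1.0, seed: int = 0) -> pd.DataFrame:
    """GWAS summary statistics with one planted causal variant.

    Marginal effects follow from LD with the causal variant: for variant j,
    beta_j = effect * corr(g_j, g_causal), se = h2_noise/sqrt(n_gwas), with
    sampling noise added to beta.
    """
    rng = np.random.default_rng(child_seed(seed, "gwas"))
    X = genotypes.dosages.to_numpy(dtype=float)
    Xs = (X - X.mean(axis=0)) / np.where(X.std(axis=0) == 0, 1, X.std(axis=0))
    gi = list(genotypes.dosages.columns).index(causal_variant)
    corr = (Xs.T @ Xs[:, gi]) / X.shape[0]
    se = h2_noise / np.sqrt(n_gwas)
    beta = effect * corr + rng.normal(scale=se, size=corr.size)
    z = beta / se
    from scipy import stats as _st

    p = 2 * _st.norm.sf(np.abs(z))
    return pd.DataFrame({
        "variant_id": genotypes.dosages.columns,
        "chrom": genotypes.variants["chrom"].to_numpy(),
        "pos": genotypes.variants["pos"].to_numpy(),
        "beta": beta, "se": se, "p": p, "N": n_gwas,
    })
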