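"""In-silico mutagenesis: variant effects through cell-cluster models.

A variant's chromatin-level footprint is the difference between the feature
grids computed for the alternative and reference alleles.  Feeding that delta
through each cluster's linear expression model yields a per-cluster effect;
a one-tailed test on absolute effects (focal cell type's clusters vs all other
clusters) scores cell-type specificity, and thresholding + ranking selects the
putative cell type-specific functional regulatory variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .feature_model import ExpressionModel, FeatureGrid

__all__ = [
    "DeltaVector",
    "VariantEffect",
    "SpecificityResult",
    "FunctionalVariantSet",
    "compute_delta",
    "project_effect",
    "effect_matrix",
    "specificity_test",
    "specificity_table",
    "select_functional_variants",
    "classify_cluster_vs_tissue",
    "mean_effect_by_celltype",
]

_SNV_ALLELES = {"A", "C", "G", "T"}


@dataclass
class DeltaVector:
    """Flattened alt-minus-ref chromatin feature difference for one variant."""

    variant_id: str
    gene_id: str
    values: np.ndarray
    ref: str = "A"
    alt: str = "C"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"delta for {self.variant_id} is non-finite")


@dataclass
class VariantEffect:
    variant_id: str
    cluster_id: str
    effect: float


@dataclass
class SpecificityResult:
    variant_id: str
    celltype: str
    t_stat: float
    p_one_sided: float
    mean_abs_focal: float
    mean_abs_other: float
    n_focal: int
    n_other: int
    approximate: bool = False  # single-cluster z-score fallback


@dataclass
class FunctionalVariantSet:
    celltype: str
    variant_ids: list[str] = field(default_factory=list)
    abs_floor: float = 0.5
    top_k: int = 2000


def compute_delta(ref_grid: FeatureGrid, alt_grid: FeatureGrid,
                  variant_id: str = "variant", ref: str = "A", alt: str = "C",
                  ) -> DeltaVector:
    """Elementwise alt - ref feature difference, flattened in layout order.

    Only biallelic SNVs are supported; indel alleles are rejected.
    """
    for allele, name in ((ref, "ref"), (alt, "alt")):
        if allele.upper() not in _SNV_ALLELES:
            raise ValueError(
                f"{name} allele {allele!r} is not a single nucleotide; "
                "only biallelic SNVs are supported"
            )
    if ref_grid.gene_id != alt_grid.gene_id:
        raise ValueError("ref and alt grids belong to different genes")
    if ref_grid.values.shape != alt_grid.values.shape:
        raise ValueError("ref and alt grids have mismatched layouts")
    delta = (alt_grid.values - ref_grid.values).ravel()
    return DeltaVector(variant_id=variant_id, gene_id=ref_grid.gene_id,
                       values=delta, ref=ref, alt=alt)


def project_effect(delta: DeltaVector, model: ExpressionModel) -> VariantEffect:
    """Predicted expression shift: model weights dotted with the delta.

    The intercept is excluded, so a zero delta has exactly zero effect; for a
    linear model this equals prediction(alt) - prediction(ref).
    """
    if delta.values.shape[0] != model.weights.shape[0]:
        raise ValueError(
            f"delta length {delta.values.shape[0]} != model weight length "
            f"{model.weights.shape[0]}"
        )
    return VariantEffect(variant_id=delta.variant_id,
                         cluster_id=model.cluster_id,
                         effect=float(model.weights @ delta.values))


def effect_matrix(deltas: list[DeltaVector],
                  models: list[ExpressionModel]) -> pd.DataFrame:
    """Variant-by-cluster table of projected effects."""
    W = np.stack([m.weights for m in models])  # clusters x p
    D = np.stack([d.values for d in deltas])   # variants x p
    return pd.DataFrame(D @ W.T,
                        index=[d.variant_id for d in deltas],
                        columns=[m.cluster_id for m in models])


def specificity_test(effects: pd.Series | dict,
                     cluster_celltypes: dict,
                     focal: str,
                     variant_id: str = "variant") -> SpecificityResult:
    """One-tailed test: are absolute effects higher in the focal cell type?

    Welch two-sample t-test on |effect|, clusters of the focal cell type vs
    all other clusters, alternative = focal greater.  A focal cell type with a
    single cluster falls back to a z-score of its |effect| against the
    other-cluster distribution and is flagged approximate.
    """
    effects = pd.Series(effects, dtype=float)
    celltypes = effects.index.map(lambda c: cluster_celltypes[c])
    if len(effects) < 2:
        raise ValueError("need at least 2 cluster effects")
    focal_mask = np.asarray(celltypes == focal)
    if not focal_mask.any():
        raise ValueError(f"focal cell type {focal!r} has no clusters")
    a = np.abs(effects.values[focal_mask])
    b = np.abs(effects.values[~focal_mask])
    if b.size == 0:
        raise ValueError("no non-focal clusters to compare against")
    if a.size >= 2:
        t, p = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
        approx = False
    else:
        sd = b.std(ddof=1) if b.size > 1 else 0.0
        if sd == 0:
            t = np.inf if a[0] > b.mean() else -np.inf
        else:
            t = (a[0] - b.mean()) / sd
        p = float(stats.norm.sf(t))
        approx = True
    return SpecificityResult(
        variant_id=variant_id, celltype=focal, t_stat=float(t),
        p_one_sided=float(p), mean_abs_focal=float(a.mean()),
        mean_abs_other=float(b.mean()), n_focal=int(a.size),
        n_other=int(b.size), approximate=approx,
    )


def specificity_table(effects: pd.DataFrame, cluster_celltypes: dict,
                      focal: str) -> pd.DataFrame:
    """Run :func:`specificity_test` for every variant row of an effect table."""
    rows = []
    for vid, row in effects.iterrows():
        r = specificity_test(row, cluster_celltypes, focal, variant_id=str(vid))
        rows.append({
            "variant_id": r.variant_id, "celltype": r.celltype,
            "t_stat": r.t_stat, "p_one_sided": r.p_one_sided,
            "mean_abs_focal": r.mean_abs_focal,
            "mean_abs_other": r.mean_abs_other,
            "approximate": r.approximate,
        })
    return pd.DataFrame(rows).set_index("variant_id")


def select_functional_variants(results: pd.DataFrame,
                               effects: pd.DataFrame,
                               cluster_celltypes: dict,
                               focal: str,
                               abs_floor: float = 0.5,
                               top_k: int = 2000) -> FunctionalVariantSet:
    """Select the putative cell type-specific functional regulatory variants.

    Eligible variants have max |effect| across the focal cell type's clusters
    above ``abs_floor``; they are ranked by ascending one-sided p (ties broken
    by larger t, then variant id) and truncated to ``top_k``.
    """
    if abs_floor < 0 or top_k < 1:
        raise ValueError("abs_floor must be >= 0 and top_k >= 1")
    focal_clusters = [c for c, ct in cluster_celltypes.items()
                      if ct == focal and c in effects.columns]
    max_abs = effects[focal_clusters].abs().max(axis=1)
    eligible = results.loc[results.index.intersection(max_abs.index)]
    eligible = eligible[max_abs.reindex(eligible.index) > abs_floor]
    ranked = (eligible.rename_axis("variant_id").reset_index()
              .sort_values(by=["p_one_sided", "t_stat", "variant_id"],
                           ascending=[True, False, True], kind="mergesort"))
    chosen = list(ranked["variant_id"].iloc[:top_k])
    return FunctionalVariantSet(celltype=focal, variant_ids=chosen,
                                abs_floor=abs_floor, top_k=top_k)


def classify_cluster_vs_tissue(cluster_effects: pd.Series,
                               tissue_effects: pd.Series,
                               sd_multiplier: float = 1.96) -> pd.Series:
    """Split variants into category 1/2 by cluster-vs-tissue effect excess.

    Category 2: |cluster effect| exceeds |tissue effect| by more than
    ``sd_multiplier`` standard deviations of that difference across all
    variants in the tissue; category 1 otherwise.
    """
    cluster_effects, tissue_effects = cluster_effects.align(tissue_effects,
                                                            join="inner")
    if len(cluster_effects) < 3:
        raise ValueError("need >= 3 paired variants to estimate the SD")
    diff = cluster_effects.abs() - tissue_effects.abs()
    sd = diff.std(ddof=1)
    if sd == 0:
        return pd.Series(1, index=diff.index)
    return pd.Series(np.where(diff > sd_multiplier * sd, 2, 1),
                     index=diff.index)


def mean_effect_by_celltype(effects: pd.Series, cluster_celltypes: dict,
                            min_clusters: int = 2) -> pd.Series:
    """Mean predicted effect per cell type, across its clusters.

    Cell types with fewer than ``min_clusters`` clusters are omitted.
    """
    if min_clusters < 1:
        raise ValueError("min_clusters must be >= 1")
    ct = pd.Series({c: cluster_celltypes[c] for c in effects.index})
    grouped = effects.groupby(ct)
    counts = grouped.size()
    means = grouped.mean()
    return means[counts >= min_clusters]
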