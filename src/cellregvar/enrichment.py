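"""Resampling and enrichment statistics.

Covers the statistical machinery used to benchmark variant predictions:
matched null-set construction (chromosome / MAF / TSS-distance strata),
bootstrap fold differences, GSEA-like permutation enrichment with a
normalized enrichment score, Fisher exact enrichment in annotated regions,
and recovery-curve AUC enrichment with row z-scoring and Ward clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

__all__ = [
    "MatchedNullSpec",
    "FoldDifferenceResult",
    "PermutationEnrichment",
    "build_matched_nulls",
    "fold_difference",
    "permutation_enrichment",
    "fisher_enrichment",
    "auc_recovery",
    "zscore_and_cluster",
]


@dataclass
class MatchedNullSpec:
    """How null variants are matched to targets.

    match_keys are column names of the variant tables; continuous keys
    (e.g. MAF, TSS distance) must be pre-binned or have bin edges supplied
    in ``bin_edges``.
    """

    match_keys: tuple[str, ...] = ("chrom", "maf_bin", "tss_dist_bin")
    bin_edges: dict[str, np.ndarray] = field(default_factory=dict)
    n_sets: int = 10_000
    seed: int = 0


def _stratum_labels(table: pd.DataFrame, spec: MatchedNullSpec) -> pd.Series:
    parts = []
    for key in spec.match_keys:
        if key in spec.bin_edges:
            binned = np.digitize(table[key].to_numpy(dtype=float),
                                 spec.bin_edges[key])
            parts.append(pd.Series(binned, index=table.index).astype(str))
        else:
            parts.append(table[key].astype(str))
    out = parts[0]
    for p in parts[1:]:
        out = out + "|" + p
    return out


def build_matched_nulls(targets: pd.DataFrame, pool: pd.DataFrame,
                        spec: MatchedNullSpec) -> list[list[str]]:
    """Draw null variant sets matched to the targets stratum by stratum.

    Each of ``spec.n_sets`` null sets has one pool variant per target, drawn
    (with replacement across sets) from pool variants sharing all match-key
    bins with that target.  Tables are indexed by variant id.
    """
    overlap = targets.index.intersection(pool.index)
    if len(overlap):
        raise ValueError(f"pool must be disjoint from targets; shared: "
                         f"{list(overlap)[:5]}")
    t_strata = _stratum_labels(targets, spec)
    p_strata = _stratum_labels(pool, spec)
    pool_by_stratum = {s: pool.index[p_strata == s].to_numpy()
                       for s in t_strata.unique()}
    for s, members in pool_by_stratum.items():
        if members.size == 0:
            raise ValueError(f"no pool variants in stratum {s!r}")
    rng = np.random.default_rng(spec.seed)
    sets = []
    strata_per_target = t_strata.to_numpy()
    for _ in range(spec.n_sets):
        draw = [pool_by_stratum[s][rng.integers(len(pool_by_stratum[s]))]
                for s in strata_per_target]
        sets.append(draw)
    return sets


@dataclass
class FoldDifferenceResult:
    fold: float
    ci_low: float
    ci_high: float
    n_boot: int


def fold_difference(target_values: np.ndarray,
                    null_sets: list[np.ndarray],
                    n_boot: int = 10_000, seed: int = 0,
                    ) -> FoldDifferenceResult:
    """Fold difference of mean |target| over mean |null|, with bootstrap CI.

    The point estimate pools all null sets; the 95% CI is the 2.5/97.5
    percentile of the fold recomputed over bootstrap resamples of the null
    sets (sets resampled with replacement).
    """
    t = np.abs(np.asarray(target_values, dtype=float))
    if t.size == 0:
        raise ValueError("no target values")
    null_arrays = [np.abs(np.asarray(s, dtype=float)) for s in null_sets]
    pooled_mean = float(np.mean(np.concatenate(null_arrays)))
    if pooled_mean == 0:
        raise ValueError("null mean is zero; fold undefined")
    fold = float(t.mean() / pooled_mean)
    rng = np.random.default_rng(seed)
    set_means = np.array([s.mean() for s in null_arrays])
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(len(set_means), size=len(set_means))
        boots[b] = t.mean() / set_means[pick].mean()
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return FoldDifferenceResult(fold=fold, ci_low=float(lo), ci_high=float(hi),
                                n_boot=n_boot)


@dataclass
class PermutationEnrichment:
    observed: float
    permuted: np.ndarray
    p: float
    nes: float


def _running_sum_stat(n: int, hit_positions: np.ndarray) -> float:
    """Unweighted KS-like running-sum maximum deviation of a hit set in a
    ranked list (positions are 0-based ranks, best first)."""
    n_hits = hit_positions.size
    inc = 1.0 / n_hits
    dec = 1.0 / (n - n_hits)
    # running sum only changes at hits; max occurs right after some hit
    pos = np.sort(hit_positions)
    hits_before = np.arange(1, n_hits + 1)
    misses_before = pos + 1 - hits_before
    running_at_hits = hits_before * inc - misses_before * dec
    return float(np.max(running_at_hits))


def permutation_enrichment(ranked_ids: list[str], hit_set: set[str],
                           n_perm: int = 10_000, seed: int = 0,
                           ) -> PermutationEnrichment:
    """GSEA-like permutation enrichment of a hit set in a ranked list.

    The statistic is the maximum deviation of the running sum that steps up
    at hits and down elsewhere; permutations draw uniform same-size hit sets;
    p = (1 + #{perm >= obs}) / (n_perm + 1); NES = observed / mean(permuted).
    """
    hits = [i for i, v in enumerate(ranked_ids) if v in hit_set]
    if not hits:
        raise ValueError("hit set is empty or disjoint from the ranking")
    extra = hit_set - set(ranked_ids)
    if extra:
        raise ValueError(f"hits outside the ranked universe: "
                         f"{sorted(extra)[:5]}")
    n = len(ranked_ids)
    k = len(hits)
    if k >= n:
        raise ValueError("hit set must be a proper subset of the ranking")
    obs = _running_sum_stat(n, np.asarray(hits))
    rng = np.random.default_rng(seed)
    perm = np.empty(n_perm)
    for b in range(n_perm):
        perm[b] = _running_sum_stat(n, rng.choice(n, size=k, replace=False))
    p = (1 + np.sum(perm >= obs)) / (n_perm + 1)
    nes = obs / perm.mean() if perm.mean() != 0 else np.nan
    return PermutationEnrichment(observed=obs, permuted=perm, p=float(p),
                                 nes=float(nes))


def fisher_enrichment(n_hit_in: int, n_hit_out: int,
                      n_ctrl_in: int, n_ctrl_out: int,
                      ) -> dict:
    """Two-sided Fisher exact test on a 2x2 (annotation x hit/control) table.

    The p-value is always the exact hypergeometric one; the odds ratio uses
    a Haldane 0.5 correction when a cell is zero (flagged).
    """
    table = np.array([[n_hit_in, n_hit_out], [n_ctrl_in, n_ctrl_out]])
    if (table < 0).any():
        raise ValueError("cell counts must be nonnegative")
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    corrected = False
    if (table == 0).any():
        corrected = True
        t = table + 0.5
        odds = (t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0])
    return {"odds_ratio": float(odds), "p": float(p),
            "haldane_corrected": corrected}


def auc_recovery(ranked_regions: list[str], overlap_set: set[str],
                 top_fraction: float = 0.05) -> float:
    """Recovery-curve AUC of an overlap set in a ranked region list.

    Walking down the top ``top_fraction`` of the ranking, the recovery curve
    counts how many overlap regions have been seen; its area is normalized by
    the maximum achievable area (all overlaps at the very top) so the score
    lies in [0, 1].  Empty overlap gives 0.
    """
    if not overlap_set:
        return 0.0
    extra = overlap_set - set(ranked_regions)
    if extra:
        raise ValueError(f"overlap outside the ranking: {sorted(extra)[:5]}")
    n = len(ranked_regions)
    k = max(1, int(np.ceil(top_fraction * n)))
    m = len(overlap_set)
    is_hit = np.fromiter((r in overlap_set for r in ranked_regions[:k]),
                         dtype=float, count=k)
    curve = np.cumsum(is_hit)
    area = curve.sum()
    max_area = np.minimum(np.arange(1, k + 1), m).sum()
    return float(area / max_area)


def zscore_and_cluster(auc_grid: pd.DataFrame) -> dict:
    """Row z-score an AUC grid and order rows/columns by Ward clustering.

    Rows are standardized to mean 0, sd 1 (constant rows become zeros and are
    flagged); hierarchical clustering uses the Ward variance criterion and a
    deterministic leaf order.  Returns z grid, linkages, row/column orders,
    and the list of zero-variance rows.
    """
    if auc_grid.shape[0] < 2 or auc_grid.shape[1] < 2:
        raise ValueError("need at least a 2x2 grid")
    vals = auc_grid.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    flat_rows = list(auc_grid.index[(sd == 0).ravel()])
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mu) / safe_sd
    zdf = pd.DataFrame(z, index=auc_grid.index, columns=auc_grid.columns)
    row_link = hierarchy.ward(z)
    col_link = hierarchy.ward(z.T)
    row_order = list(auc_grid.index[hierarchy.leaves_list(
        hierarchy.optimal_leaf_ordering(row_link, z))])
    col_order = list(auc_grid.columns[hierarchy.leaves_list(
        hierarchy.optimal_leaf_ordering(col_link, z.T))])
    return {"z": zdf, "row_linkage": row_link, "col_linkage": col_link,
            "row_order": row_order, "col_order": col_order,
            "zero_variance_rows": flat_rows}
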