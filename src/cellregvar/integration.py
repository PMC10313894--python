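"""LD computation and merging of predicted functional variants with QTLs.

LD is the squared Pearson correlation of genotype dosages (composite LD, as
computed on unphased data).  A predicted functional variant is supported by
the population data when it is in high LD (r^2 above a threshold) with a
candidate top eQTL or ieQTL (relaxed FDR screen); the merged record carries
the candidate's gene, giving a variant-to-gene link.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "LdMatrix",
    "IntegrationRecord",
    "compute_ld",
    "select_candidate_qtls",
    "merge_variants",
    "ld_blocks",
    "ld_block_max_compare",
    "finemap_classifier_benchmark",
]


@dataclass
class LdMatrix:
    """Pairwise r^2 between variants (NaN outside the window or for
    constant-dosage variants)."""

    r2: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.r2.index.equals(self.r2.columns):
            raise ValueError("LD matrix must be square with matching labels")

    def get(self, a: str, b: str) -> float:
        return float(self.r2.loc[a, b])


def compute_ld(dosages: pd.DataFrame, positions: pd.Series | None = None,
               window_bp: float | None = None) -> LdMatrix:
    """Squared Pearson correlation of dosage vectors.

    Missing dosages are mean-imputed per variant.  When ``positions`` and
    ``window_bp`` are given, pairs farther apart than ``window_bp`` are set
    to NaN (not computed in spirit, masked in practice).  Constant variants
    yield NaN rows/columns.
    """
    X = dosages.to_numpy(dtype=float).copy()
    if X.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    col_mean = np.nanmean(X, axis=0)
    nan_mask = np.isnan(X)
    if nan_mask.any():
        X[nan_mask] = np.take(col_mean, np.where(nan_mask)[1])
    sd = X.std(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = (X - X.mean(axis=0)) / sd
    r = (Z.T @ Z) / X.shape[0]
    r2 = r ** 2
    r2[sd == 0, :] = np.nan
    r2[:, sd == 0] = np.nan
    np.fill_diagonal(r2, np.where(sd == 0, np.nan, 1.0))
    out = pd.DataFrame(r2, index=dosages.columns, columns=dosages.columns)
    if window_bp is not None and positions is not None:
        pos = positions.reindex(dosages.columns).to_numpy(dtype=float)
        dist = np.abs(pos[:, None] - pos[None, :])
        out = out.mask(dist > window_bp)
    return LdMatrix(out)


def select_candidate_qtls(qtl: pd.DataFrame, fdr_ceiling: float = 0.4,
                          fdr_col: str = "pval_adj_bh") -> pd.DataFrame:
    """Relaxed screen for candidate top (i)eQTLs: FDR strictly below the
    ceiling."""
    if fdr_col not in qtl.columns:
        raise ValueError(f"missing FDR column {fdr_col!r}")
    return qtl[qtl[fdr_col] < fdr_ceiling]


@dataclass
class IntegrationRecord:
    functional_variant: str
    qtl_variant: str
    r2: float
    gene_id: str
    source: str  # "eQTL" or "ieQTL"
    fdr: float
    celltype: str


def merge_variants(functional_ids: list[str], candidates: pd.DataFrame,
                   ld: LdMatrix, r2_floor: float = 0.8,
                   celltype: str = "") -> list[IntegrationRecord]:
    """Link each functional variant to every candidate top QTL with
    r^2 strictly above ``r2_floor``.

    ``candidates`` rows need columns variant_id, gene_id, source, and an FDR
    column (pval_adj_bh).  Variants absent from the LD matrix are skipped.
    """
    records = []
    universe = set(ld.r2.index)
    for fv in sorted(functional_ids):
        if fv not in universe:
            continue
        for _, row in candidates.iterrows():
            qv = row["variant_id"]
            if qv not in universe:
                continue
            r2 = ld.get(fv, qv)
            if np.isfinite(r2) and r2 > r2_floor:
                records.append(IntegrationRecord(
                    functional_variant=fv, qtl_variant=qv, r2=r2,
                    gene_id=row["gene_id"], source=row.get("source", "eQTL"),
                    fdr=float(row.get("pval_adj_bh", np.nan)),
                    celltype=celltype))
    for rec in records:  # contract: no record violates the thresholds
        assert rec.r2 > r2_floor
    return records


def ld_blocks(ld: LdMatrix, seed_variant: str, block_r2: float = 0.6,
              ) -> list[str]:
    """Single-linkage connected component at r^2 > block_r2 around a seed."""
    r2 = ld.r2
    members = {seed_variant}
    frontier = [seed_variant]
    while frontier:
        v = frontier.pop()
        linked = r2.columns[(r2.loc[v] > block_r2).fillna(False)]
        for u in linked:
            if u not in members:
                members.add(u)
                frontier.append(u)
    return sorted(members)


def ld_block_max_compare(predictions: pd.Series, eqtl: pd.DataFrame,
                         ld: LdMatrix, top_variant_per_gene: pd.Series,
                         block_r2: float = 0.6) -> tuple[pd.DataFrame, float]:
    """Per gene, compare the strongest prediction and eQTL signal in one
    LD block.

    For each gene the block is grown by single linkage (r^2 > block_r2)
    around its top eQTL variant; the block maxima of |prediction| and of
    |beta/se| are paired, and their Spearman correlation across genes is
    returned alongside the per-gene table.
    """
    rows = []
    for gene, top in top_variant_per_gene.items():
        if top not in ld.r2.index:
            continue
        block = ld_blocks(ld, top, block_r2)
        preds = predictions.reindex(block).dropna()
        sub = eqtl[eqtl["variant_id"].isin(block)]
        if preds.empty or sub.empty:
            continue
        z = (sub["beta"] / sub["se"]).abs()
        rows.append({"gene_id": gene,
                     "max_abs_prediction": float(preds.abs().max()),
                     "max_abs_z": float(z.max())})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        rho = np.nan
    else:
        rho = float(stats.spearmanr(table["max_abs_prediction"],
                                    table["max_abs_z"]).statistic)
    return table, rho


def finemap_classifier_benchmark(positives: list[str], ld: LdMatrix,
                                 predictions: pd.Series, pip: pd.Series,
                                 pip_ceiling: float = 0.01,
                                 link_r2: float = 0.6,
                                 seed: int = 0) -> float:
    """AUROC of a logistic classifier separating fine-mapped variants from
    matched LD-linked negatives.

    For each positive, one negative is sampled (seeded) from its LD-linked
    variants (r^2 > link_r2) with posterior inclusion probability below
    ``pip_ceiling``; a single-feature logistic model on |prediction| is
    scored by AUROC.  Positives with no eligible negative are dropped.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(seed)
    feats, labels = [], []
    for pos in positives:
        if pos not in ld.r2.index or pos not in predictions.index:
            continue
        linked = ld.r2.columns[(ld.r2.loc[pos] > link_r2).fillna(False)]
        eligible = [v for v in linked
                    if v != pos and v in predictions.index
                    and pip.get(v, 1.0) < pip_ceiling]
        if not eligible:
            continue
        neg = eligible[rng.integers(len(eligible))]
        feats.extend([abs(predictions[pos]), abs(predictions[neg])])
        labels.extend([1, 0])
    if len(set(labels)) < 2:
        raise ValueError("no usable positive/negative pairs")
    X = np.asarray(feats)[:, None]
    y = np.asarray(labels)
    clf = LogisticRegression().fit(X, y)
    return float(roc_auc_score(y, clf.predict_proba(X)[:, 1]))
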