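"""Cell cluster interaction-eQTL mapping in bulk cohorts.

Bulk expression is screened with TPM/count filters, TMM-normalized and
rank-transformed; estimated cell-cluster fractions are screened and
rank-transformed; every cis variant (MAF-filtered, within +/-1 Mb of the TSS)
is tested for a genotype-by-fraction interaction with ordinary least squares:

    expression ~ b1 * dosage:fraction + b2 * dosage + b3 * fraction + covariates

Top-variant p-values are Bonferroni-corrected by the effective number of
independent cis variants (eigenvalue-based) and Benjamini-Hochberg adjusted
across genes.  ieQTLs whose genotype main effect keeps one sign but shrinks
from low- to high-fraction samples are flagged as negatively correlated —
signals likely originating in other cell types.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GenotypeMatrix",
    "InteractionFit",
    "IeqtlRecord",
    "filter_genes",
    "tmm_normalize",
    "inverse_normal_transform",
    "filter_fractions",
    "fit_interaction_model",
    "map_cis_ieqtls",
    "effective_tests",
    "adjust_pvalues",
    "classify_negative_ieqtl",
    "compute_maf",
]


@dataclass
class GenotypeMatrix:
    """Sample-by-variant dosage matrix with variant coordinates.

    dosages: DataFrame, samples in rows, variants in columns, values in [0, 2].
    variants: DataFrame indexed by variant id with columns chrom, pos (1-based).
    """

    dosages: pd.DataFrame
    variants: pd.DataFrame

    def __post_init__(self) -> None:
        missing = self.dosages.columns.difference(self.variants.index)
        if len(missing):
            raise ValueError(f"variants without coordinates: {list(missing)[:5]}")

    @property
    def maf(self) -> pd.Series:
        return compute_maf(self.dosages)


def compute_maf(dosages: pd.DataFrame) -> pd.Series:
    """Minor allele frequency per variant: min(mean/2, 1 - mean/2)."""
    freq = dosages.mean(axis=0) / 2.0
    return pd.concat([freq, 1 - freq], axis=1).min(axis=1)


def filter_genes(tpm: pd.DataFrame, counts: pd.DataFrame,
                 tpm_floor: float = 0.1, count_floor: float = 6,
                 sample_frac: float = 0.2) -> list[str]:
    """Expression screen: keep genes with TPM >= tpm_floor in >= sample_frac
    of samples AND raw reads >= count_floor in >= sample_frac of samples."""
    if not tpm.index.equals(counts.index):
        diff = tpm.index.symmetric_difference(counts.index)
        raise ValueError(f"TPM and count tables disagree on genes: {list(diff)[:5]}")
    n = tpm.shape[1]
    ok_tpm = (tpm >= tpm_floor).sum(axis=1) >= sample_frac * n
    ok_cnt = (counts >= count_floor).sum(axis=1) >= sample_frac * n
    return list(tpm.index[ok_tpm & ok_cnt])


def _tmm_factor(obs: np.ndarray, ref: np.ndarray,
                logratio_trim: float = 0.3, abs_trim: float = 0.05) -> float:
    """Trimmed mean of M-values between one sample and the reference."""
    n_obs, n_ref = obs.sum(), ref.sum()
    keep = (obs > 0) & (ref > 0)
    obs, ref = obs[keep], ref[keep]
    if obs.size == 0:
        return 1.0
    m = np.log2((obs / n_obs) / (ref / n_ref))      # log-ratio
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))  # abs expression
    # inverse of the delta-method variance of M is the precision weight
    v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    n = m.size
    lo_m = np.floor(n * logratio_trim) + 1
    hi_m = n - np.floor(n * logratio_trim)
    lo_a = np.floor(n * abs_trim) + 1
    hi_a = n - np.floor(n * abs_trim)
    rm = stats.rankdata(m, method="average")
    ra = stats.rankdata(a, method="average")
    keep2 = (rm >= lo_m) & (rm <= hi_m) & (ra >= lo_a) & (ra <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    return float(2 ** f)


def tmm_normalize(counts: pd.DataFrame,
                  ) -> tuple[pd.Series, pd.DataFrame]:
    """Trimmed-mean-of-M-values library normalization.

    The reference sample is the one whose upper-quartile (of nonzero CPM) is
    closest to the mean upper-quartile; factors are rescaled to geometric
    mean 1.  Returns (size factors indexed by sample, normalized table of
    counts / (library size * factor), in counts-per-million scale).
    """
    if counts.shape[1] < 2:
        raise ValueError("TMM requires at least 2 samples")
    if (counts.values < 0).any():
        raise ValueError("counts must be nonnegative")
    lib = counts.sum(axis=0)
    if (lib == 0).any():
        bad = list(lib.index[lib == 0])
        raise ValueError(f"all-zero samples: {bad}")
    uq = counts.quantile(0.75, axis=0) / lib
    ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(dtype=float)
    factors = pd.Series(
        {s: _tmm_factor(counts[s].to_numpy(dtype=float), ref)
         for s in counts.columns})
    factors /= np.exp(np.log(factors).mean())  # geometric mean 1
    eff_lib = lib * factors
    normalized = counts / eff_lib * 1e6
    return factors, normalized


def inverse_normal_transform(values, ties: str = "average") -> np.ndarray:
    """Rank-based inverse normal transform: v_i -> Phi^-1((rank_i - 0.5)/n).

    Tied values share the average rank; an all-tied vector maps to zeros.
    NaNs are preserved and excluded from ranking.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    mask = np.isfinite(v)
    x = v[mask]
    if x.size == 0:
        return out
    if np.all(x == x[0]):
        out[mask] = 0.0
        return out
    if x.size < 3:
        raise ValueError("inverse normal transform needs >= 3 values")
    ranks = stats.rankdata(x, method=ties)
    out[mask] = stats.norm.ppf((ranks - 0.5) / x.size)
    return out


def filter_fractions(scores: pd.DataFrame, score_floor: float = 1.0,
                     sample_frac: float = 0.2) -> list[str]:
    """Keep cell clusters whose absolute score exceeds ``score_floor`` in
    strictly more than ``sample_frac`` of samples (clusters in columns)."""
    if (scores.values < 0).any():
        raise ValueError("absolute scores must be nonnegative")
    n = scores.shape[0]
    ok = (scores > score_floor).sum(axis=0) > sample_frac * n
    return list(scores.columns[ok])


@dataclass
class InteractionFit:
    beta1: float  # genotype x fraction interaction
    beta2: float  # genotype main effect
    beta3: float  # fraction main effect
    se1: float
    se2: float
    se3: float
    t1: float
    p_interaction: float
    df_resid: int


def _ols(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    """OLS with normal-equation covariance; raises on rank deficiency."""
    n, k = X.shape
    q, r = np.linalg.qr(X)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(n, k) * np.finfo(float).eps if diag.size else 0.0
    if (diag <= tol).any():
        bad = list(np.where(diag <= tol)[0])
        raise ValueError(f"design matrix is rank deficient in columns {bad}")
    beta = np.linalg.solve(r, q.T @ y)
    resid = y - X @ beta
    df = n - k
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    rinv = np.linalg.inv(r)
    cov = sigma2 * (rinv @ rinv.T)
    return beta, np.sqrt(np.diag(cov)), df


def fit_interaction_model(y, g, f, covariates=None,
                          two_sided: bool = True) -> InteractionFit:
    """OLS fit of expression ~ 1 + g + f + g*f [+ covariates].

    The reported p-value belongs to the interaction coefficient's t statistic
    with df = n - rank; two-sided by default.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    cols = [np.ones_like(y), g, f, g * f]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        cols.extend(C.T)
    X = np.column_stack(cols)
    beta, se, df = _ols(X, y)
    t1 = beta[3] / se[3]
    if two_sided:
        p = 2 * stats.t.sf(abs(t1), df)
    else:
        p = stats.t.sf(t1, df)
    return InteractionFit(beta1=float(beta[3]), beta2=float(beta[1]),
                          beta3=float(beta[2]), se1=float(se[3]),
                          se2=float(se[1]), se3=float(se[2]), t1=float(t1),
                          p_interaction=float(p), df_resid=df)


@dataclass
class IeqtlRecord:
    gene_id: str
    cluster_id: str
    variant_id: str
    fit: InteractionFit
    n_cis_variants: int
    m_eff: int
    pval_emt: float = np.nan
    pval_adj_bh: float = np.nan
    negative_flag: bool | None = None


def cis_window_variants(genotypes: GenotypeMatrix, chrom: str, tss: int,
                        window_bp: float = 1e6,
                        maf_floor: float = 0.05) -> list[str]:
    """Variants within the closed interval [tss - window, tss + window] on the
    gene's chromosome that pass the MAF filter (MAF >= maf_floor)."""
    v = genotypes.variants
    in_win = (v["chrom"].astype(str) == str(chrom)) & \
             (v["pos"] >= tss - window_bp) & (v["pos"] <= tss + window_bp)
    ids = v.index[in_win]
    maf = compute_maf(genotypes.dosages[ids])
    return list(maf.index[maf >= maf_floor])


def map_cis_ieqtls(gene_id: str, chrom: str, tss: int, y,
                   genotypes: GenotypeMatrix, fraction, covariates=None,
                   window_bp: float = 1e6, maf_floor: float = 0.05,
                   ) -> tuple[pd.DataFrame, IeqtlRecord | None]:
    """Test every cis variant of one gene; return all fits and the top record.

    Top variant = smallest interaction p, ties broken by larger |t| and then
    smaller position.  Returns (per-variant table, record) or (empty, None)
    when the cis-window is empty after filtering.
    """
    ids = cis_window_variants(genotypes, chrom, tss, window_bp, maf_floor)
    if not ids:
        return pd.DataFrame(), None
    rows = []
    for vid in ids:
        fit = fit_interaction_model(y, genotypes.dosages[vid].to_numpy(),
                                    fraction, covariates)
        rows.append({"variant_id": vid,
                     "pos": int(genotypes.variants.loc[vid, "pos"]),
                     "beta1": fit.beta1, "beta2": fit.beta2,
                     "beta3": fit.beta3, "se1": fit.se1, "t1": fit.t1,
                     "p_interaction": fit.p_interaction})
    table = pd.DataFrame(rows).set_index("variant_id")
    order = table.assign(abs_t=table["t1"].abs()).sort_values(
        by=["p_interaction", "abs_t", "pos"],
        ascending=[True, False, True], kind="mergesort")
    top_id = order.index[0]
    top_fit = fit_interaction_model(y, genotypes.dosages[top_id].to_numpy(),
                                    fraction, covariates)
    m = effective_tests(genotypes.dosages[ids])
    record = IeqtlRecord(gene_id=gene_id, cluster_id="", variant_id=top_id,
                         fit=top_fit, n_cis_variants=len(ids), m_eff=m)
    return table, record


def effective_tests(cis_dosages: pd.DataFrame, var_explained: float = 0.99,
                    window: int = 200) -> int:
    """Effective number of independent variants in a cis-window.

    The variant correlation matrix is eigen-decomposed in consecutive windows
    of ``window`` variants; per window the effective count is the smallest k
    whose top-k eigenvalues reach ``var_explained`` of the trace.  The summed
    count is capped at the number of variants.
    """
    G = cis_dosages.to_numpy(dtype=float)
    n_var = G.shape[1]
    if n_var == 0:
        raise ValueError("no variants")
    total = 0
    for start in range(0, n_var, window):
        block = G[:, start:start + window]
        sd = block.std(axis=0)
        keep = sd > 0
        m_block = block.shape[1]
        if not keep.any():
            total += 1
            continue
        corr = np.corrcoef(block[:, keep], rowvar=False)
        corr = np.atleast_2d(corr)
        evals = np.sort(np.linalg.eigvalsh(corr))[::-1]
        cum = np.cumsum(evals)
        k = int(np.searchsorted(cum, var_explained * evals.sum()) + 1)
        total += min(k, m_block)
    return int(min(total, n_var))


def adjust_pvalues(top_p: pd.Series, m_eff: pd.Series,
                   ) -> pd.DataFrame:
    """Per-gene multiple-testing correction.

    pval_emt = min(1, top interaction p * effective cis tests) per gene;
    pval_adj_bh = Benjamini-Hochberg step-up over pval_emt across genes.
    """
    top_p, m_eff = top_p.align(m_eff, join="inner")
    emt = np.minimum(1.0, top_p * m_eff)
    _, bh, _, _ = multipletests(emt, method="fdr_bh")
    return pd.DataFrame({"pval_emt": emt, "pval_adj_bh": bh}, index=top_p.index)


def classify_negative_ieqtl(y, g, f, covariates=None, n_bins: int = 4,
                            min_per_bin: int = 10) -> bool | None:
    """Flag ieQTLs whose genotype effect shrinks from low to high fractions.

    Samples are split into ``n_bins`` fraction-quantile bins; y ~ g (+C) is
    fit per bin.  The flag is True iff every bin-level genotype effect shares
    one sign and the top bin's |effect| is below the bottom bin's.  Returns
    None (undetermined) when any bin is smaller than ``min_per_bin``.
    """
    y = np.asarray(y, dtype=float)
    g = np.asarray(g, dtype=float)
    f = np.asarray(f, dtype=float)
    qs = np.quantile(f, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(qs, f, side="right") - 1, 0, n_bins - 1)
    effects = []
    for b in range(n_bins):
        m = bins == b
        if m.sum() < min_per_bin:
            return None
        cols = [np.ones(int(m.sum())), g[m]]
        if covariates is not None:
            C = np.asarray(covariates, dtype=float)
            if C.ndim == 1:
                C = C[:, None]
            cols.extend(C[m].T)
        X = np.column_stack(cols)
        beta, _, _ = _ols(X, y[m])
        effects.append(beta[1])
    effects = np.asarray(effects)
    same_sign = np.all(effects > 0) or np.all(effects < 0)
    return bool(same_sign and abs(effects[-1]) < abs(effects[0]))
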